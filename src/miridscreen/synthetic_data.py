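"""Synthetic assemblies, hit tables, annotations and pooled pileups with known
ground truth.

Every downstream stage of the pipeline is testable without external data: the
generator emulates a host assembly with planted bacterial scaffolds from
labelled families, planted LGT insertions flanked by host genes with
transcription evidence, near-duplicate scaffolds, N-gap runs, telomeric and
tandem arrays, and pooled pileups whose allele frequencies follow a neutral
site-frequency spectrum at a stated per-site theta.

All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats_io import (
    ExpressionInterval,
    GeneModel,
    Hit,
    ScaffoldRecord,
    SiteCounts,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------

@dataclass
class LgtSpec:
    donor_family: str
    insert_length: int
    expressed: bool = True


@dataclass
class DupSpec:
    source_index: int  # index into the host scaffolds
    substitutions: int = 0
    reverse_complement: bool = False


@dataclass
class RepeatSpec:
    motif: str
    copies: int
    placement: str = "random"  # or "end"


@dataclass
class PoolSpec:
    """Conditions of the neutral pooled-sequencing simulation.

    ``theta`` is the per-site population mutation rate, ``pool_n`` the number
    of chromosomes in the pool (40 chromosomes: the study pool of females with
    the pool size the diversity tooling was run at), ``coverage`` the read
    depth per site and ``error_rate`` a symmetric per-read substitution rate.
    """

    theta: float = 0.01
    pool_n: int = 40
    coverage: int = 50
    error_rate: float = 0.0
    length: int = 1_000_000
    indel_rate: float = 0.0
    scaffold_id: str = "pool_region"


@dataclass
class SimParams:
    seed: int = 0
    n_host: int = 30
    host_length: tuple[int, int] = (8000, 40000)
    gc: float = 0.38
    contaminants: dict[str, int] = field(default_factory=dict)
    contaminant_length: tuple[int, int] = (2000, 20000)
    contaminant_truth_fraction: float = 0.9
    lgt: list[LgtSpec] = field(default_factory=list)
    dup: list[DupSpec] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)  # (length, count)
    repeats: list[RepeatSpec] = field(default_factory=list)
    genes_per_host: int = 2
    fragment_length: int = 1000  # screening fragment grid for gene placement


@dataclass
class LgtTruth:
    scaffold_id: str
    start: int
    end: int
    donor_family: str
    expressed: bool


@dataclass
class TruthTable:
    """Everything the generator planted, keyed for later recovery checks."""

    roles: dict[str, dict] = field(default_factory=dict)
    lgt_intervals: list[LgtTruth] = field(default_factory=list)
    gap_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    repeat_arrays: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    # (scaffold, motif, start, end, copies)
    contaminant_fraction: float = 0.9

    def contaminant_ids(self) -> set[str]:
        return {s for s, r in self.roles.items() if r["kind"] == "contaminant"}

    def duplicate_ids(self) -> set[str]:
        return {s for s, r in self.roles.items() if r["kind"] == "duplicate"}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roles": self.roles,
            "lgt_intervals": [vars(t) for t in self.lgt_intervals],
            "gap_intervals": self.gap_intervals,
            "repeat_arrays": self.repeat_arrays,
            "contaminant_fraction": self.contaminant_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            roles=payload["roles"],
            lgt_intervals=[LgtTruth(**t) for t in payload["lgt_intervals"]],
            gap_intervals=[tuple(g) for g in payload["gap_intervals"]],
            repeat_arrays=[tuple(r) for r in payload["repeat_arrays"]],
            contaminant_fraction=payload["contaminant_fraction"],
        )


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _family_transition_matrix(family: str, seed: int) -> np.ndarray:
    """A stable per-family first-order Markov transition matrix.

    Gives each synthetic bacterial family a distinct k-mer composition so that
    top-taxon calls are learnable by a composition-aware search.
    """
    fam_seed = zlib.crc32(family.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([seed & 0x7FFFFFFF, fam_seed])
    mat = rng.dirichlet(np.full(4, 1.5), size=4)
    return mat


def _markov_seq(rng: np.random.Generator, length: int, mat: np.ndarray) -> str:
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.integers(4)
    # cumulative rows for inverse-CDF sampling
    cum = np.cumsum(mat, axis=1)
    u = rng.random(length)
    for i in range(1, length):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return _BASES[states].tobytes().decode()


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    if n_subs > len(seq):
        raise ValueError("more substitutions than positions")
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        current = arr[p]
        choices = [b for b in b"ACGT" if bytes([b]) != current]
        arr[p] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# truth assembly
# ---------------------------------------------------------------------------

def build_truth_assembly(
    params: SimParams,
) -> tuple[list[ScaffoldRecord], list[GeneModel], list[ExpressionInterval], TruthTable]:
    """Generate an assembly, gene models, expression coverage and truth table.

    Host scaffolds are i.i.d. bases at the requested GC; contaminant scaffolds
    come from per-family Markov pools; each LGT insert is placed inside a host
    scaffold between two generated gene models, with expression coverage over
    the insert iff its ``expressed`` flag is set; duplicates are copies (or
    reverse complements) of a source scaffold with exactly the requested
    substitutions.
    """
    rng = np.random.default_rng(params.seed)
    records: list[ScaffoldRecord] = []
    genes: list[GeneModel] = []
    expression: list[ExpressionInterval] = []
    truth = TruthTable(contaminant_fraction=params.contaminant_truth_fraction)

    # hosts
    lo, hi = params.host_length
    for i in range(params.n_host):
        length = int(rng.integers(lo, hi + 1))
        rec = ScaffoldRecord(f"host_{i:04d}", _random_seq(rng, length, params.gc))
        records.append(rec)
        truth.roles[rec.id] = {"kind": "host"}

    host_records = list(records)

    # LGT insertions: replace a central slice of a host scaffold with donor
    # sequence and plant flanking genes plus expression evidence.  Flanking
    # genes are placed clear of the screening fragment grid so that a fused
    # candidate (whose span is fragment-aligned) falls wholly between them.
    frag = params.fragment_length
    lgt_hosts: set[str] = set()
    for k, spec in enumerate(params.lgt):
        host_idx = k % len(host_records)
        rec = host_records[host_idx]
        flank_needed = 2 * frag + 3600  # fragment slack + a gene on each side
        if spec.insert_length + flank_needed > len(rec.seq):
            raise ValueError(
                f"LGT insert of {spec.insert_length} bp does not fit in "
                f"{rec.id} ({len(rec.seq)} bp)"
            )
        mid = len(rec.seq) // 2
        start = mid - spec.insert_length // 2
        end = start + spec.insert_length
        mat = _family_transition_matrix(spec.donor_family, params.seed)
        insert = _markov_seq(rng, spec.insert_length, mat)
        rec.seq = rec.seq[:start] + insert + rec.seq[end:]
        lgt_hosts.add(rec.id)
        truth.roles[rec.id] = {"kind": "lgt_host", "donor": spec.donor_family}
        truth.lgt_intervals.append(
            LgtTruth(rec.id, start, end, spec.donor_family, spec.expressed)
        )
        grid_lo = (start // frag) * frag
        grid_hi = -(-end // frag) * frag
        left = GeneModel(rec.id, max(0, grid_lo - 1500),
                         max(1, grid_lo - 200), "+",
                         f"{rec.id}_lgt{k}_left", "host-like")
        right = GeneModel(rec.id, min(len(rec.seq) - 1, grid_hi + 200),
                          min(len(rec.seq), grid_hi + 1500), "-",
                          f"{rec.id}_lgt{k}_right", "host-like")
        genes.extend([left, right])
        if spec.expressed:
            expression.append(ExpressionInterval(rec.id, start, end, 12.0))

    # background gene models on the remaining hosts (exercise annotation)
    for rec in host_records:
        if rec.id in lgt_hosts:
            continue
        for _ in range(params.genes_per_host):
            if len(rec.seq) < 2000:
                continue
            g_start = int(rng.integers(0, len(rec.seq) - 1000))
            g_end = g_start + int(rng.integers(300, 1000))
            g_end = min(g_end, len(rec.seq))
            genes.append(
                GeneModel(rec.id, g_start, g_end, "+",
                          f"{rec.id}_g{len(genes)}", "host-like")
            )

    # contaminants
    clo, chi = params.contaminant_length
    for family in sorted(params.contaminants):
        mat = _family_transition_matrix(family, params.seed)
        for j in range(params.contaminants[family]):
            length = int(rng.integers(clo, chi + 1))
            rec = ScaffoldRecord(
                f"contam_{family}_{j:03d}", _markov_seq(rng, length, mat)
            )
            records.append(rec)
            truth.roles[rec.id] = {"kind": "contaminant", "family": family}

    # N-gap runs planted into host scaffolds (length preserved)
    for gap_len, count in params.gaps:
        for _ in range(count):
            rec = host_records[int(rng.integers(len(host_records)))]
            if gap_len + 2 >= len(rec.seq):
                continue
            pos = int(rng.integers(1, len(rec.seq) - gap_len - 1))
            rec.seq = rec.seq[:pos] + "N" * gap_len + rec.seq[pos + gap_len:]
            truth.gap_intervals.append((rec.id, pos, pos + gap_len))

    # tandem / telomeric repeat arrays (length preserved, slice replaced)
    for spec in params.repeats:
        rec = host_records[int(rng.integers(len(host_records)))]
        array = spec.motif * spec.copies
        if len(array) + 2 >= len(rec.seq):
            raise ValueError("repeat array longer than host scaffold")
        if spec.placement == "end":
            pos = len(rec.seq) - len(array)
        else:
            pos = int(rng.integers(1, len(rec.seq) - len(array) - 1))
        rec.seq = rec.seq[:pos] + array + rec.seq[pos + len(array):]
        truth.repeat_arrays.append(
            (rec.id, spec.motif, pos, pos + len(array), spec.copies)
        )

    # near/exact duplicates of host scaffolds
    for spec in params.dup:
        src = host_records[spec.source_index]
        seq = src.seq
        if spec.reverse_complement:
            seq = revcomp(seq)
        seq = _substitute(rng, seq, spec.substitutions)
        rec = ScaffoldRecord(f"dup_of_{src.id}_{spec.substitutions}", seq)
        records.append(rec)
        truth.roles[rec.id] = {
            "kind": "duplicate",
            "source": src.id,
            "edits": spec.substitutions,
            "reverse_complement": spec.reverse_complement,
        }

    return records, genes, expression, truth


# ---------------------------------------------------------------------------
# hit-table fabrication (stands in for running an aligner)
# ---------------------------------------------------------------------------

def fabricate_hit_table(
    records: Sequence[ScaffoldRecord],
    truth: TruthTable,
    noise: tuple[float, float] = (0.0, 50.0),
    seed: int = 0,
    fragment_length: int = 1000,
) -> list[Hit]:
    """Fabricate a screening hit table consistent with the planted truth.

    Contaminant scaffolds receive bacterial hits tiling at least their truth
    fraction of length with bitscores in [80, 500] and the true family label;
    each planted LGT interval receives bacterial hits with bitscores in
    [80, 500] and no eukaryote hit; host background receives spurious hits at
    the noise rate with bitscores at or below the noise ceiling (default 50,
    i.e. below the recording threshold).
    """
    rate, max_bitscore = noise
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in records}
    hits: list[Hit] = []
    lgt_by_scaffold: dict[str, list[LgtTruth]] = {}
    for t in truth.lgt_intervals:
        lgt_by_scaffold.setdefault(t.scaffold_id, []).append(t)

    for rec in records:
        role = truth.roles.get(rec.id, {"kind": "host"})
        if role["kind"] == "contaminant":
            family = role["family"]
            span = int(np.ceil(truth.contaminant_fraction * len(rec.seq)))
            span = min(span, len(rec.seq))
            pos = 0
            while pos < span:
                end = min(pos + fragment_length, span, len(rec.seq))
                if end <= pos:
                    break
                subject = f"{family}_sp{int(rng.integers(1, 4))}"
                hits.append(
                    Hit(rec.id, pos, end, subject, family,
                        float(rng.uniform(80, 500)), "bacterial",
                        fragment_index=pos // fragment_length)
                )
                pos = end
            continue
        for t in lgt_by_scaffold.get(rec.id, []):
            frag_lo = t.start // fragment_length
            frag_hi = (t.end - 1) // fragment_length
            for frag in range(frag_lo, frag_hi + 1):
                s = max(t.start, frag * fragment_length)
                e = min(t.end, (frag + 1) * fragment_length)
                hits.append(
                    Hit(rec.id, s, e, f"{t.donor_family}_donor", t.donor_family,
                        float(rng.uniform(80, 500)), "bacterial",
                        fragment_index=frag)
                )
        if rate > 0:
            n_frags = max(1, -(-len(rec.seq) // fragment_length))
            n_noise = rng.poisson(rate * n_frags)
            for _ in range(n_noise):
                frag = int(rng.integers(n_frags))
                fs = frag * fragment_length
                fe = min(fs + fragment_length, len(rec.seq))
                if fe - fs < 40:
                    continue
                s = int(rng.integers(fs, fe - 30))
                e = s + int(rng.integers(20, min(200, fe - s)))
                hits.append(
                    Hit(rec.id, s, e, "noise_sp", "",
                        float(rng.uniform(10, max_bitscore)), "bacterial",
                        fragment_index=frag)
                )
    return hits


# ---------------------------------------------------------------------------
# pooled pileup simulation
# ---------------------------------------------------------------------------

def harmonic_number(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i, the Watterson normalizer for n chromosomes."""
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass
class PoolPileup:
    """Dense per-site read counts for one simulated region (columnar)."""

    scaffold_id: str
    pos: np.ndarray          # (L,) int64, 0-based
    ref: np.ndarray          # (L,) int8 codes into ACGT
    counts: np.ndarray       # (L, 4) int32 in ACGT order
    indel_events: np.ndarray  # (L,) int16
    masked: np.ndarray | None = None  # (L,) bool

    def __len__(self) -> int:
        return len(self.pos)

    def to_sites(self) -> list[SiteCounts]:
        bases = "ACGT"
        return [
            SiteCounts(
                self.scaffold_id, int(p), bases[r],
                int(c[0]), int(c[1]), int(c[2]), int(c[3]), int(ind),
            )
            for p, r, c, ind in zip(self.pos, self.ref, self.counts,
                                    self.indel_events)
        ]


def simulate_pool_pileup(
    pool_spec: PoolSpec, seed: int = 0
) -> tuple[PoolPileup, dict[int, float]]:
    """Simulate a neutral pooled pileup.

    The number of segregating sites is Poisson(theta * a1 * L) with
    a1 = sum_{i=1}^{pool_n - 1} 1/i; each SNP's population frequency is drawn
    proportional to 1/i for derived count i in {1..pool_n-1}; read counts at
    each site are Binomial(coverage, sample frequency) with a symmetric error
    rate applied; non-SNP sites are monomorphic for the reference.

    Returns the pileup plus the map of true derived-allele frequencies by
    position.
    """
    if pool_spec.theta <= 0:
        raise ValueError("theta must be positive")
    if pool_spec.pool_n < 2:
        raise ValueError("pool_n must be at least 2")
    if pool_spec.coverage < 1:
        raise ValueError("coverage must be at least 1")
    rng = np.random.default_rng(seed)
    L = pool_spec.length
    n = pool_spec.pool_n
    cov = pool_spec.coverage
    a1 = harmonic_number(n)

    ref = rng.integers(0, 4, size=L, dtype=np.int8)
    counts = np.zeros((L, 4), dtype=np.int32)
    counts[np.arange(L), ref] = cov

    n_snps = int(rng.poisson(pool_spec.theta * a1 * L))
    n_snps = min(n_snps, L)
    snp_pos = np.sort(rng.choice(L, size=n_snps, replace=False))
    weights = 1.0 / np.arange(1, n)
    weights /= weights.sum()
    derived_count = rng.choice(np.arange(1, n), size=n_snps, p=weights)
    freqs = derived_count / n
    derived_base = (ref[snp_pos] + rng.integers(1, 4, size=n_snps)) % 4

    derived_reads = rng.binomial(cov, freqs)
    counts[snp_pos, ref[snp_pos]] = cov - derived_reads
    counts[snp_pos, derived_base] += derived_reads.astype(np.int32)

    if pool_spec.error_rate > 0:
        e = pool_spec.error_rate
        for b in range(4):
            flips = rng.binomial(counts[:, b], e)
            if not flips.any():
                continue
            counts[:, b] -= flips
            # distribute flips evenly among the other three bases
            remaining = flips
            others = [o for o in range(4) if o != b]
            for j, o in enumerate(others):
                if j < 2:
                    take = rng.binomial(remaining, 1.0 / (3 - j))
                else:
                    take = remaining
                counts[:, o] += take
                remaining = remaining - take

    indel_events = np.zeros(L, dtype=np.int16)
    if pool_spec.indel_rate > 0:
        indel_events[:] = rng.random(L) < pool_spec.indel_rate

    pileup = PoolPileup(
        scaffold_id=pool_spec.scaffold_id,
        pos=np.arange(L, dtype=np.int64),
        ref=ref,
        counts=counts,
        indel_events=indel_events,
    )
    true_freqs = {int(p): float(f) for p, f in zip(snp_pos, freqs)}
    return pileup, true_freqs


def scrub_motif(records: Sequence[ScaffoldRecord], motif: str) -> None:
    """Remove incidental occurrences of a motif (any rotation, either strand)
    from background sequence, in place.

    Used to build controlled copy-number experiments where the planted arrays
    are the only occurrences: a random background of length L otherwise
    carries on the order of L/100 chance matches to a 5 bp motif family.
    Each occurrence has its middle base deterministically cycled until the
    sequence is clean.
    """
    comp = str.maketrans("ACGT", "TGCA")
    words = set()
    for m in (motif, motif.translate(comp)[::-1]):
        for i in range(len(m)):
            words.add(m[i:] + m[:i])
    cycle = {"A": "C", "C": "G", "G": "T", "T": "A"}
    p = len(motif)
    for rec in records:
        seq = list(rec.seq)
        changed = True
        while changed:
            changed = False
            for i in range(len(seq) - p + 1):
                if "".join(seq[i:i + p]) in words:
                    mid = i + p // 2
                    if seq[mid] in cycle:
                        seq[mid] = cycle[seq[mid]]
                        changed = True
        rec.seq = "".join(seq)


# ---------------------------------------------------------------------------
# read simulation for motif counting
# ---------------------------------------------------------------------------

def simulate_reads_with_motifs(
    records: Sequence[ScaffoldRecord],
    coverage: float,
    read_len: int = 100,
    seed: int = 0,
) -> list[ScaffoldRecord]:
    """Sample uniform reads from both strands of a genome.

    The expected total read bp equals coverage x genome size; motif
    occurrences in the read set scale as coverage x occurrences in the genome.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    genome_size = sum(len(r.seq) for r in records)
    if read_len > genome_size:
        raise ValueError("read length exceeds genome size")
    rng = np.random.default_rng(seed)
    eligible = [r for r in records if len(r.seq) >= read_len]
    if not eligible:
        raise ValueError("no scaffold is at least one read long")
    weights = np.array([len(r.seq) - read_len + 1 for r in eligible], dtype=float)
    weights /= weights.sum()
    n_reads = int(round(coverage * genome_size / read_len))
    scaffold_idx = rng.choice(len(eligible), size=n_reads, p=weights)
    reads: list[ScaffoldRecord] = []
    for i, si in enumerate(scaffold_idx):
        rec = eligible[si]
        start = int(rng.integers(0, len(rec.seq) - read_len + 1))
        seq = rec.seq[start:start + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(ScaffoldRecord(f"read_{i:07d}", seq))
    return reads
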