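"""Tandem-repeat motif discovery, telomere-candidate ranking and read-based
repeat copy-number estimation.

Motif occurrences are counted non-overlapping, left to right, matching any
rotation of the motif or of its reverse complement (tandem arrays are phase-
and strand-arbitrary in reads).  The tandem detector is an exact-match run
scanner: for each period p up to the maximum, maximal runs with
s[x] = s[x - p] are reported at their minimal period.  It is stricter than
alignment-based tandem finders and underestimates degenerate arrays.

Copy numbers per haploid genome follow the read-scaling argument: with
sequencing coverage c = total read bp / genome size, a motif seen k times in
the reads occurs about k / c times per haploid genome; dividing by twice the
haploid chromosome number gives copies per chromosome end.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import Hit, ScaffoldRecord

log = logging.getLogger("miridscreen")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RepeatRecord:
    canonical_motif: str
    period: int
    sequence_id: str
    start: int
    end: int
    copies: float


@dataclass
class KaryotypeParams:
    n_haploid: int = 16  # 2n = 32 chromosomes

    def __post_init__(self) -> None:
        if self.n_haploid < 1:
            raise ValueError("n_haploid must be >= 1")

    @property
    def ends(self) -> int:
        return 2 * self.n_haploid


# ---------------------------------------------------------------------------
# motif canonicalization and counting
# ---------------------------------------------------------------------------

def rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonical_motif(motif: str) -> str:
    """Lexicographically least rotation over both strands; idempotent."""
    return min(rotations(motif) + rotations(revcomp(motif)))


def motif_word_set(motif: str) -> frozenset[str]:
    return frozenset(rotations(motif) + rotations(revcomp(motif)))


def count_motif(reads: Iterable[ScaffoldRecord], motif: str) -> int:
    """Count non-overlapping occurrences of any rotation of the motif or of
    its reverse complement, scanning left to right."""
    if len(motif) < 2:
        raise ValueError("motif must be at least 2 bp")
    if set(motif.upper()) - set("ACGT"):
        raise ValueError(f"motif has non-ACGT characters: {motif!r}")
    words = motif_word_set(motif.upper())
    p = len(motif)
    total = 0
    for rec in reads:
        seq = rec.seq
        i = 0
        limit = len(seq) - p
        while i <= limit:
            if seq[i:i + p] in words:
                total += 1
                i += p
            else:
                i += 1
    return total


def copy_number(
    occurrences: int, total_read_bp: int, genome_size_bp: int
) -> float:
    """Copies per haploid genome from read occurrences and coverage."""
    if total_read_bp <= 0 or genome_size_bp <= 0:
        raise ValueError("read bp and genome size must be positive")
    coverage = total_read_bp / genome_size_bp
    if coverage == 0:
        raise ValueError("zero coverage")
    return occurrences / coverage


def per_chromosome_end(
    copies: float, karyotype: KaryotypeParams | None = None
) -> tuple[float, int]:
    """Copies per chromosome end: copies / (2 x haploid chromosome number).

    Returns the value at one decimal place and its rounded integer.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    karyotype = karyotype or KaryotypeParams()
    value = copies / karyotype.ends
    return round(value, 1), round(value)


# ---------------------------------------------------------------------------
# tandem repeat discovery (exact-run detector)
# ---------------------------------------------------------------------------

def _minimal_period(region: str) -> int:
    """Smallest q with region[i] == region[i-q] for all i >= q (KMP border)."""
    n = len(region)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and region[i] != region[k]:
            k = fail[k - 1]
        if region[i] == region[k]:
            k += 1
        fail[i] = k
    return n - fail[n - 1]


def discover_tandem_repeats(
    sequences: Iterable[ScaffoldRecord],
    max_period: int = 25,
    min_copies: float = 3,
    min_len: int = 12,
) -> list[RepeatRecord]:
    """Find maximal exact tandem runs of period <= ``max_period``.

    A run of period p is reported if it spans at least ``min_copies`` copies
    and ``min_len`` bp, and only at its minimal period (a poly-A region
    appears once, at period 1, not again at periods 2 or 4).  Motifs are
    canonicalized over rotation and strand.  Runs containing N are skipped.
    """
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    out: list[RepeatRecord] = []
    for rec in sequences:
        seq = rec.seq
        n = len(seq)
        reported: set[tuple[int, int]] = set()
        for p in range(1, min(max_period, n // 2) + 1):
            i = p
            while i < n:
                if seq[i] != seq[i - p]:
                    i += 1
                    continue
                run_start = i
                while i < n and seq[i] == seq[i - p]:
                    i += 1
                region_start = run_start - p
                region_end = i
                region = seq[region_start:region_end]
                if "N" in region:
                    continue
                if _minimal_period(region) != p:
                    continue
                copies = len(region) / p
                if copies < min_copies or len(region) < min_len:
                    continue
                key = (region_start, region_end)
                if key in reported:
                    continue
                reported.add(key)
                out.append(
                    RepeatRecord(
                        canonical_motif=canonical_motif(region[:p]),
                        period=p,
                        sequence_id=rec.id,
                        start=region_start,
                        end=region_end,
                        copies=copies,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# telomere-candidate ranking
# ---------------------------------------------------------------------------

def _expanded_hamming(a: str, b: str) -> int:
    """Best Hamming distance between rotations of two motifs, expanded to a
    common length (the lcm of the periods) so different periods compare."""
    import math as _math

    la, lb = len(a), len(b)
    lcm = la * lb // _math.gcd(la, lb)
    ax = (a * (lcm // la))
    best = lcm + 1
    for rot in rotations(b):
        bx = rot * (lcm // lb)
        d = sum(x != y for x, y in zip(ax, bx))
        best = min(best, d)
    return best


def motif_distance(motif: str, ancestral: str) -> int:
    """Distance of a motif to the ancestral motif over rotations and strands."""
    return min(
        _expanded_hamming(motif, ancestral),
        _expanded_hamming(motif, revcomp(ancestral)),
    )


def rank_telomere_candidates(
    records: Sequence[RepeatRecord],
    ancestral_motif: str = "TTAGG",
    max_distance: int = 2,
) -> pd.DataFrame:
    """Rank candidate telomeric motifs by genome copy number.

    Repeat records are aggregated by canonical motif; motifs within
    ``max_distance`` (best Hamming distance over rotations and strands,
    periods expanded to a common length) of the ancestral motif are kept and
    ranked by total copies descending.
    """
    copies: dict[str, float] = defaultdict(float)
    periods: dict[str, int] = {}
    for r in records:
        copies[r.canonical_motif] += r.copies
        periods[r.canonical_motif] = r.period
    rows = []
    for motif in sorted(copies):
        d = motif_distance(motif, ancestral_motif)
        if d > max_distance:
            continue
        rows.append(
            {
                "motif": motif,
                "period": periods[motif],
                "total_copies": copies[motif],
                "distance_to_ancestral": d,
            }
        )
    df = pd.DataFrame(
        rows, columns=["motif", "period", "total_copies", "distance_to_ancestral"]
    )
    return df.sort_values(
        ["total_copies", "motif"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# repeat presence on the assembly
# ---------------------------------------------------------------------------

def repeat_assembly_stats(
    records: Sequence[ScaffoldRecord],
    motif: str | None = None,
    hits: Sequence[Hit] | None = None,
    unit_length: int | None = None,
    coverage_cutoff: float = 0.70,
) -> tuple[int, float, float]:
    """How much of the assembly carries a repeat.

    For a short ``motif``, scaffolds are scanned exactly (a full-unit match
    always covers 100% of the unit, satisfying any cutoff).  For a long
    repeat consensus, pass its ``hits`` on the assembly and the consensus
    ``unit_length``; a scaffold counts iff at least one hit covers at least
    ``coverage_cutoff`` of the unit.

    Returns (scaffolds with the repeat, percent of scaffolds to 3 d.p.,
    percent of genome bp matched).
    """
    total_scaffolds = len(records)
    total_bp = sum(len(r.seq) for r in records)
    matched_bp = 0
    with_repeat: set[str] = set()
    if motif is not None:
        for rec in records:
            k = count_motif([rec], motif)
            if k:
                with_repeat.add(rec.id)
                matched_bp += k * len(motif)
    elif hits is not None:
        if not unit_length:
            raise ValueError("unit_length required with hit input")
        for h in hits:
            if (h.end - h.start) >= coverage_cutoff * unit_length:
                with_repeat.add(h.scaffold_id)
                matched_bp += h.end - h.start
    else:
        raise ValueError("either motif or hits must be given")
    n = len(with_repeat)
    pct_scaffolds = round(100.0 * n / total_scaffolds, 3) if total_scaffolds else 0.0
    pct_bp = 100.0 * matched_bp / total_bp if total_bp else 0.0
    return n, pct_scaffolds, pct_bp


def pct_scaffolds(n_with_repeat: int, total_scaffolds: int) -> float:
    """Percent of scaffolds carrying a repeat, to 3 decimal places."""
    return round(100.0 * n_with_repeat / total_scaffolds, 3)
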