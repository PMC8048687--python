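"""Assembly statistics, gap stripping, duplicate-scaffold detection, length
filtering and flow-cytometry genome-size arithmetic.

Contigs are scaffold segments split at runs of >= 10 N; gap stripping removes
runs strictly longer than 10 bp.  Duplicate detection runs in two modes:
exact (identical to an earlier scaffold or its reverse complement, mirroring
standard dedupe behaviour) and near (minimizer-sketch candidate pairs verified
by banded edit distance, reported at >= 95% identity within 100 edits by
default — the residual-haplotig screen).
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .formats_io import ScaffoldRecord

log = logging.getLogger("miridscreen")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    total_bp: int
    n_scaffolds: int
    scaffold_n50: int
    contig_n50: int
    largest_scaffold: int
    total_bp_in_scaffolds_ge_50kb: int
    n_per_100kbp: float
    pct_n: float


_GAP_SPLIT = re.compile("N{10,}")
_GAP_STRIP = re.compile("N{11,}")


def n50(lengths: Sequence[int]) -> int:
    """Length L such that sequences >= L sum to at least half the total."""
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]


def split_contigs(seq: str, min_gap: int = 10) -> list[str]:
    """Split a scaffold into contigs at N-runs of at least ``min_gap``."""
    pattern = re.compile("N{%d,}" % min_gap)
    return [part for part in pattern.split(seq) if part]


def assembly_stats(records: Sequence[ScaffoldRecord]) -> AssemblyStats:
    if not records:
        raise ValueError("empty assembly")
    lengths = [len(r.seq) for r in records]
    total = sum(lengths)
    contig_lengths = [
        len(c) for r in records for c in split_contigs(r.seq)
    ]
    n_count = sum(r.seq.count("N") for r in records)
    rate = n_count / total * 100_000
    return AssemblyStats(
        total_bp=total,
        n_scaffolds=len(records),
        scaffold_n50=n50(lengths),
        contig_n50=n50(contig_lengths) if contig_lengths else 0,
        largest_scaffold=max(lengths),
        total_bp_in_scaffolds_ge_50kb=sum(x for x in lengths if x >= 50_000),
        n_per_100kbp=round(rate, 2),
        pct_n=round(rate / 1000, 2),
    )


def n_rate_to_pct(n_per_100kbp: float) -> float:
    """Convert an N's-per-100-kbp rate to percent of the genome (2 d.p.)."""
    return round(n_per_100kbp / 1000, 2)


# ---------------------------------------------------------------------------
# gap stripping
# ---------------------------------------------------------------------------

def percent_reduction(old_bp: int, new_bp: int) -> float:
    """100 x (old - new) / old, rounded to one decimal place."""
    return round(100.0 * (old_bp - new_bp) / old_bp, 1)


def strip_gaps(
    records: Sequence[ScaffoldRecord], min_run: int = 11
) -> tuple[list[ScaffoldRecord], int, float]:
    """Delete every maximal N-run of length >= ``min_run`` (default: runs
    strictly longer than 10 bp); shorter runs are kept.

    Returns (reduced records, reduced total bp, percent reduction).
    """
    pattern = re.compile("N{%d,}" % min_run)
    reduced = [ScaffoldRecord(r.id, pattern.sub("", r.seq)) for r in records]
    reduced = [r for r in reduced if r.seq]
    old_bp = sum(len(r.seq) for r in records)
    new_bp = sum(len(r.seq) for r in reduced)
    return reduced, new_bp, percent_reduction(old_bp, new_bp)


# ---------------------------------------------------------------------------
# duplicate detection
# ---------------------------------------------------------------------------

@dataclass
class DupParams:
    mode: str = "exact"            # exact | near
    min_identity: float = 0.95
    max_edits: int = 100
    sketch_k: int = 15
    sketch_window: int = 25
    min_shared_minimizers: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_edits < 0:
            raise ValueError("max_edits must be >= 0")
        if self.mode not in ("exact", "near"):
            raise ValueError(f"unknown duplicate mode: {self.mode}")


@dataclass
class DupPair:
    id_a: str
    id_b: str
    edits: int
    identity: float
    reverse_complement: bool


def _minimizers(seq: str, k: int, w: int) -> set[int]:
    """Canonical (strand-min) k-mer minimizers over windows of w k-mers."""
    if len(seq) < k:
        return set()
    enc = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T; N breaks k-mers
    vals = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(len(vals), -1, dtype=np.int64)
    for byte, code in enc.items():
        codes[vals == byte] = code
    n_kmers = len(seq) - k + 1
    fwd = np.zeros(n_kmers, dtype=np.int64)
    rev = np.zeros(n_kmers, dtype=np.int64)
    valid = np.ones(n_kmers, dtype=bool)
    for off in range(k):
        c = codes[off:off + n_kmers]
        valid &= c >= 0
        fwd = fwd * 4 + np.where(c >= 0, c, 0)
        rc = np.where(c >= 0, 3 - c, 0)
        rev = rev + rc * (4 ** off)
    canon = np.minimum(fwd, rev)
    # simple mixing so minimizers are not biased toward poly-A
    canon = (canon * 2654435761) % (2 ** 31 - 1)
    canon[~valid] = np.iinfo(np.int64).max
    out: set[int] = set()
    if n_kmers <= w:
        m = int(canon.min())
        if m != np.iinfo(np.int64).max:
            out.add(m)
        return out
    view = np.lib.stride_tricks.sliding_window_view(canon, w)
    mins = view.min(axis=1)
    for m in np.unique(mins):
        if m != np.iinfo(np.int64).max:
            out.add(int(m))
    return out


def find_duplicates(
    records: Sequence[ScaffoldRecord], params: DupParams | None = None
) -> list[list[str]] | list[DupPair]:
    """Find duplicate scaffolds.

    Exact mode returns groups (representative first-seen id first) of
    scaffolds identical to an earlier scaffold or its reverse complement.

    Near mode proposes candidate pairs by shared-minimizer sketches and
    verifies them by banded edit distance (band = ``max_edits``); a pair is
    reported iff edits <= max_edits and identity = 1 - edits/len(shorter) is
    at least ``min_identity``.  The identity denominator is the shorter
    sequence, symmetric in pair order.
    """
    params = params or DupParams()
    if params.mode == "exact":
        groups: dict[str, list[str]] = {}
        for r in records:
            key = min(r.seq, revcomp(r.seq))
            groups.setdefault(key, []).append(r.id)
        return [ids for ids in groups.values() if len(ids) > 1]

    sketches = {
        r.id: _minimizers(r.seq, params.sketch_k, params.sketch_window)
        for r in records
    }
    by_id = {r.id: r for r in records}
    index: dict[int, list[str]] = defaultdict(list)
    for rid, sk in sketches.items():
        for m in sk:
            index[m].append(rid)
    shared: Counter = defaultdict(int)
    for m, ids in index.items():
        if len(ids) < 2 or len(ids) > 50:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                shared[(ids[i], ids[j])] += 1
    pairs: list[DupPair] = []
    for (id_a, id_b), count in sorted(shared.items()):
        smaller_sketch = min(len(sketches[id_a]), len(sketches[id_b])) or 1
        if count < min(params.min_shared_minimizers, smaller_sketch):
            continue
        a, b = by_id[id_a].seq, by_id[id_b].seq
        if abs(len(a) - len(b)) > params.max_edits:
            continue
        res = edlib.align(a, b, mode="NW", task="distance", k=params.max_edits)
        edits = res["editDistance"]
        rc = False
        res_rc = edlib.align(a, revcomp(b), mode="NW", task="distance",
                             k=params.max_edits)
        if res_rc["editDistance"] >= 0 and (
            edits < 0 or res_rc["editDistance"] < edits
        ):
            edits, rc = res_rc["editDistance"], True
        if edits < 0:
            continue
        identity = 1 - edits / min(len(a), len(b))
        if edits <= params.max_edits and identity >= params.min_identity:
            pairs.append(DupPair(id_a, id_b, edits, identity, rc))
    return pairs


def remove_exact_duplicates(
    records: Sequence[ScaffoldRecord],
) -> tuple[list[ScaffoldRecord], list[str]]:
    """Drop scaffolds identical (either strand) to an earlier one."""
    groups = find_duplicates(records, DupParams(mode="exact"))
    removed = {rid for grp in groups for rid in grp[1:]}
    kept = [r for r in records if r.id not in removed]
    return kept, sorted(removed)


# ---------------------------------------------------------------------------
# length filtering and external-size arithmetic
# ---------------------------------------------------------------------------

def pct_retained(kept_bp: int, total_bp: int) -> float:
    return round(100.0 * kept_bp / total_bp, 2)


def filter_by_length(
    records: Sequence[ScaffoldRecord], min_len: int = 10_000
) -> tuple[list[ScaffoldRecord], float]:
    """Keep scaffolds of at least ``min_len`` bp; also return the percent of
    total bp retained (2 d.p.).

    Used before windowed diversity analyses so that window sliding is not
    inflated on scaffolds smaller than the window size.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in records if len(r.seq) >= min_len]
    total = sum(len(r.seq) for r in records)
    kept_bp = sum(len(r.seq) for r in kept)
    return kept, pct_retained(kept_bp, total if total else 1)


def flow_cytometry_size(
    sample_signal: float, standard_signal: float, standard_size_mbp: float = 175.0
) -> float:
    """Genome size (Mbp) from fluorescence relative to a 175 Mbp standard."""
    if standard_signal <= 0:
        raise ValueError("standard_signal must be positive")
    if sample_signal == 0:
        log.warning("sample signal is zero; estimated size is 0 Mbp")
    return standard_size_mbp * sample_signal / standard_signal


def duplicate_class_total(class_counts: Sequence[int]) -> int:
    """Total duplicated-orthologue count from per-multiplicity class counts
    (e.g. two-copy, triplicate, quadruple classes)."""
    return int(sum(class_counts))
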