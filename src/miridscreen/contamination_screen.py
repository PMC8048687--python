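"""Bacterial-contamination screening of assembly scaffolds.

Each scaffold is notionally broken into 1 kbp fragments and searched against a
bacterial reference database; the screen itself operates on the resulting hit
table.  Per scaffold it records the number of bacterial matches above the
recording threshold (bitscore > 50), the interval-union coverage, the hit
width (distance between the leftmost and rightmost bacterial hit, proportional
to scaffold size) and the subject with the greatest number of matches.
Scaffolds whose proportional hit width reaches the cut-off (>= 0.40 by
default) are called contaminant.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import Hit, ScaffoldRecord


@dataclass
class ScreenParams:
    fragment_length: int = 1000
    min_hit_bitscore: float = 50.0   # strict >
    width_cutoff: float = 0.40       # inclusive >=
    word_size: int = 11              # used only by the toy search

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        if not (0 < self.width_cutoff <= 1):
            raise ValueError("width_cutoff must be in (0, 1]")


@dataclass
class ContamMetrics:
    scaffold_id: str
    length: int
    n_matches: int = 0
    covered_bp: int = 0
    covered_prop: float = 0.0
    hit_width_bp: int = 0
    hit_width_prop: float = 0.0
    top_taxon: str = ""
    top_family: str = ""
    top_taxon_tie: bool = False
    call: str = ""


def fragment_scaffold(
    length: int, fragment_length: int = 1000
) -> list[tuple[int, tuple[int, int]]]:
    """Break a scaffold of the given length into consecutive fragments.

    The final fragment carries the remainder and may be shorter; the union of
    the fragment intervals is the whole scaffold.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    if length < 1:
        raise ValueError("scaffold length must be >= 1")
    out = []
    idx = 0
    for start in range(0, length, fragment_length):
        out.append((idx, (start, min(start + fragment_length, length))))
        idx += 1
    return out


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    tree = IntervalTree.from_tuples((s, e) for s, e in intervals if e > s)
    tree.merge_overlaps(strict=False)
    return sum(iv.end - iv.begin for iv in tree)


def qualifying_hits(hits: Iterable[Hit], params: ScreenParams) -> list[Hit]:
    """Bacterial hits above the recording threshold (strict >)."""
    return [
        h for h in hits
        if h.db == "bacterial" and h.bitscore > params.min_hit_bitscore
    ]


def scaffold_metrics(
    hits: Sequence[Hit],
    scaffold_id: str,
    scaffold_length: int,
    params: ScreenParams | None = None,
) -> ContamMetrics:
    """Screening statistics for one scaffold from its bacterial hits.

    Hits at or below the recording bitscore threshold are discarded first.
    The top taxon is the subject with the most matches; ties break
    lexicographically by subject id and are flagged.
    """
    params = params or ScreenParams()
    m = ContamMetrics(scaffold_id=scaffold_id, length=scaffold_length)
    kept = []
    for h in qualifying_hits(hits, params):
        if h.scaffold_id != scaffold_id:
            raise ValueError(f"hit on {h.scaffold_id} passed for {scaffold_id}")
        if h.end > scaffold_length:
            raise ValueError(
                f"hit [{h.start},{h.end}) outside scaffold {scaffold_id} "
                f"of length {scaffold_length}"
            )
        kept.append(h)
    if not kept:
        return m
    m.n_matches = len(kept)
    m.covered_bp = union_length(h.interval for h in kept)
    m.covered_prop = m.covered_bp / scaffold_length
    left = min(h.start for h in kept)
    right = max(h.end for h in kept)
    m.hit_width_bp = right - left
    m.hit_width_prop = m.hit_width_bp / scaffold_length
    by_subject = Counter(h.subject_id for h in kept)
    top_count = max(by_subject.values())
    tied = sorted(s for s, c in by_subject.items() if c == top_count)
    m.top_taxon = tied[0]
    m.top_taxon_tie = len(tied) > 1
    fam = next(h.family for h in kept if h.subject_id == m.top_taxon)
    m.top_family = fam
    return m


def classify_contaminants(
    metrics: Sequence[ContamMetrics], params: ScreenParams | None = None
) -> tuple[list[ContamMetrics], list[str]]:
    """Set the contaminant/clean call; return metrics plus the removal list.

    A scaffold is a contaminant iff its proportional hit width is at or above
    the cut-off (inclusive).
    """
    params = params or ScreenParams()
    removal: list[str] = []
    for m in metrics:
        if m.hit_width_prop >= params.width_cutoff:
            m.call = "contaminant"
            removal.append(m.scaffold_id)
        else:
            m.call = "clean"
    return list(metrics), removal


def screen_assembly(
    records: Sequence[ScaffoldRecord],
    hits: Sequence[Hit],
    params: ScreenParams | None = None,
) -> tuple[list[ContamMetrics], list[str]]:
    """Run the whole screen over an assembly: metrics then classification."""
    params = params or ScreenParams()
    by_scaffold: dict[str, list[Hit]] = defaultdict(list)
    for h in hits:
        by_scaffold[h.scaffold_id].append(h)
    metrics = [
        scaffold_metrics(by_scaffold.get(r.id, []), r.id, len(r.seq), params)
        for r in records
    ]
    return classify_contaminants(metrics, params)


def split_assembly(
    records: Sequence[ScaffoldRecord], removal: Iterable[str]
) -> tuple[list[ScaffoldRecord], list[ScaffoldRecord]]:
    """Partition records into (kept, removed) by the removal list."""
    removed_ids = set(removal)
    kept = [r for r in records if r.id not in removed_ids]
    removed = [r for r in records if r.id in removed_ids]
    return kept, removed


# ---------------------------------------------------------------------------
# per-family summary (symbiont / contaminant accounting)
# ---------------------------------------------------------------------------

def family_summary(
    hits: Sequence[Hit], params: ScreenParams | None = None
) -> pd.DataFrame:
    """Per-family bp totals and scaffold counts from qualifying hits.

    ``total_bp`` is the sum over scaffolds of the interval-union length of
    that family's qualifying hits; ``n_scaffolds_affected`` counts scaffolds
    with at least one qualifying hit of the family.  A scaffold with hits from
    several families counts once per family, so the scaffold column may sum to
    more than the number of distinct scaffolds.  Empty family labels are
    binned as "Others".  Rows are sorted by total_bp descending, with a final
    "Total" row of column sums.
    """
    params = params or ScreenParams()
    per_family_scaffold: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for h in qualifying_hits(hits, params):
        family = h.family or "Others"
        per_family_scaffold[(family, h.scaffold_id)].append(h.interval)
    bp: Counter[str] = Counter()
    scaffolds: dict[str, set[str]] = defaultdict(set)
    for (family, scaffold_id), intervals in per_family_scaffold.items():
        bp[family] += union_length(intervals)
        scaffolds[family].add(scaffold_id)
    rows = [
        {"family": fam, "total_bp": bp[fam],
         "n_scaffolds_affected": len(scaffolds[fam])}
        for fam in bp
    ]
    df = pd.DataFrame(rows, columns=["family", "total_bp", "n_scaffolds_affected"])
    df = df.sort_values(["total_bp", "family"], ascending=[False, True],
                        ignore_index=True)
    return add_totals_row(df)


def add_totals_row(df: pd.DataFrame) -> pd.DataFrame:
    """Append the column-sum 'Total' row to a per-family summary table."""
    body = df[df["family"] != "Total"]
    total = pd.DataFrame(
        [{
            "family": "Total",
            "total_bp": int(body["total_bp"].sum()),
            "n_scaffolds_affected": int(body["n_scaffolds_affected"].sum()),
        }]
    )
    return pd.concat([body, total], ignore_index=True)


# ---------------------------------------------------------------------------
# optional toy search (seed-and-extend stand-in for a real aligner)
# ---------------------------------------------------------------------------

# Raw ungapped segment scores are used directly against bitscore thresholds,
# re-scaled by this constant (raw +1/-2 scoring roughly tracks BLASTn bitscores
# for the short exact matches fabricated here).
TOY_BITSCORE_SCALE = 1.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def toy_search(
    queries: Sequence[ScaffoldRecord],
    subjects: Sequence[tuple[ScaffoldRecord, str, str]],
    params: ScreenParams | None = None,
    xdrop: int = 10,
) -> list[Hit]:
    """Exact word-seeded, ungapped-extended search at toy scale.

    ``subjects`` are (record, family, db) triples.  Seeds are exact
    ``word_size``-mers on both strands; extension is ungapped with match +1 /
    mismatch -2 until the running score drops ``xdrop`` below its maximum.
    The reported bitscore is the raw segment score times
    :data:`TOY_BITSCORE_SCALE`.  Deterministic; not meant for real databases.
    """
    params = params or ScreenParams()
    w = params.word_size
    index: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    # word -> (subject index, position, strand)
    for si, (srec, _fam, _db) in enumerate(subjects):
        for strand, seq in ((0, srec.seq), (1, _revcomp(srec.seq))):
            for p in range(len(seq) - w + 1):
                word = seq[p:p + w]
                if "N" in word:
                    continue
                index[word].append((si, p, strand))

    hits: list[Hit] = []
    for q in queries:
        best: dict[tuple[int, int, int], tuple[int, int, int]] = {}
        # (subject, strand, diagonal) -> (score, qstart, qend)
        for qp in range(len(q.seq) - w + 1):
            word = q.seq[qp:qp + w]
            for si, sp, strand in index.get(word, ()):
                srec, fam, db = subjects[si]
                sseq = srec.seq if strand == 0 else _revcomp(srec.seq)
                score = w
                # extend right
                best_score, best_right = score, qp + w
                i, j = qp + w, sp + w
                while i < len(q.seq) and j < len(sseq):
                    score += 1 if q.seq[i] == sseq[j] else -2
                    i += 1
                    j += 1
                    if score > best_score:
                        best_score, best_right = score, i
                    if score <= best_score - xdrop:
                        break
                # extend left
                score = best_score
                best_left = qp
                i, j = qp - 1, sp - 1
                while i >= 0 and j >= 0:
                    score += 1 if q.seq[i] == sseq[j] else -2
                    if score > best_score:
                        best_score, best_left = score, i
                    if score <= best_score - xdrop:
                        break
                    i -= 1
                    j -= 1
                key = (si, strand, qp - sp)
                prev = best.get(key)
                if prev is None or best_score > prev[0]:
                    best[key] = (best_score, best_left, best_right)
        for (si, strand, _diag), (score, qs, qe) in sorted(best.items()):
            srec, fam, db = subjects[si]
            hits.append(
                Hit(q.id, qs, qe, srec.id, fam,
                    score * TOY_BITSCORE_SCALE, db,
                    fragment_index=qs // params.fragment_length,
                    reverse=strand == 1)
            )
    return hits
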