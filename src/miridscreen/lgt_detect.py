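"""Lateral-gene-transfer candidate detection by the dual-database rule.

Scaffolds are fragmented into 1 kbp pieces; a piece with a bacterial hit above
the recording threshold is screened against a eukaryote transcript database.
Pieces with a bacterial bitscore strictly above 75 and no eukaryote hit at any
reported score are candidates; maximal runs of adjacent candidate pieces on a
scaffold are fused into one candidate region, which is then annotated with its
nearest flanking gene models, any overlapping gene, and transcription
evidence.  The automatic pipeline never discards a candidate on its own:
curation verdicts come from an operator-supplied file.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .formats_io import (
    ExpressionInterval,
    GeneModel,
    Hit,
    ScaffoldRecord,
    mean_depth,
)


@dataclass
class PieceScreen:
    """Dual-database screening result for one 1 kbp fragment."""

    scaffold_id: str
    fragment_index: int
    start: int
    end: int
    best_bacterial_bitscore: float = 0.0
    best_bacterial_subject: str = ""
    best_bacterial_family: str = ""
    best_eukaryote_bitscore: float = 0.0  # 0 = no eukaryote hit


@dataclass
class LgtCandidate:
    scaffold_id: str
    start: int
    end: int
    fragments: list[int]
    best_subject: str = ""
    best_bitscore: float = 0.0
    best_family: str = ""
    flank_left: str | None = None
    flank_left_label: str = "none"
    flank_right: str | None = None
    flank_right_label: str = "none"
    overlapping_gene: str | None = None
    expressed: bool = False
    mean_expression: float = 0.0
    curation_status: str = "candidate"


def build_piece_screens(
    hits: Sequence[Hit],
    scaffold_lengths: Mapping[str, int],
    fragment_length: int = 1000,
    record_min_bitscore: float = 50.0,
) -> list[PieceScreen]:
    """Summarize hits into per-fragment dual-database screens.

    Only fragments with at least one bacterial hit above the recording
    threshold (strict >) yield a piece, mirroring the screen's flow where the
    eukaryote search is run only for positive bacterial pieces.
    """
    grouped: dict[tuple[str, int], list[Hit]] = defaultdict(list)
    for h in hits:
        grouped[(h.scaffold_id, h.fragment_index)].append(h)
    pieces: list[PieceScreen] = []
    for (scaffold_id, frag), piece_hits in sorted(grouped.items()):
        bact = [h for h in piece_hits if h.db == "bacterial"]
        euk = [h for h in piece_hits if h.db == "eukaryote"]
        recorded = [h for h in bact if h.bitscore > record_min_bitscore]
        if not recorded:
            continue
        best_bact = max(recorded, key=lambda h: h.bitscore)
        length = scaffold_lengths.get(scaffold_id)
        start = frag * fragment_length
        end = start + fragment_length
        if length is not None:
            end = min(end, length)
        pieces.append(
            PieceScreen(
                scaffold_id=scaffold_id,
                fragment_index=frag,
                start=start,
                end=end,
                best_bacterial_bitscore=best_bact.bitscore,
                best_bacterial_subject=best_bact.subject_id,
                best_bacterial_family=best_bact.family,
                best_eukaryote_bitscore=(
                    max(h.bitscore for h in euk) if euk else 0.0
                ),
            )
        )
    return pieces


def screen_pieces(
    pieces: Sequence[PieceScreen],
    bact_min: float = 75.0,
    euk_max: float = 0.0,
) -> list[PieceScreen]:
    """Keep pieces with bacterial bitscore strictly above ``bact_min`` and
    eukaryote bitscore at most ``euk_max`` (default 0, i.e. no eukaryote hit).
    """
    return [
        p for p in pieces
        if p.best_bacterial_bitscore > bact_min
        and p.best_eukaryote_bitscore <= euk_max
    ]


def fuse_adjacent(
    pieces: Sequence[PieceScreen], max_gap_fragments: int = 0
) -> list[LgtCandidate]:
    """Fuse maximal runs of adjacent candidate pieces into candidates.

    Pieces must share a scaffold and have consecutive fragment indices
    (tolerating up to ``max_gap_fragments`` missing fragments in between) to
    fuse; the candidate's best subject is the highest-bitscore member.
    """
    ordered = sorted(pieces, key=lambda p: (p.scaffold_id, p.fragment_index))
    candidates: list[LgtCandidate] = []
    run: list[PieceScreen] = []

    def flush() -> None:
        if not run:
            return
        best = max(run, key=lambda p: p.best_bacterial_bitscore)
        candidates.append(
            LgtCandidate(
                scaffold_id=run[0].scaffold_id,
                start=run[0].start,
                end=run[-1].end,
                fragments=[p.fragment_index for p in run],
                best_subject=best.best_bacterial_subject,
                best_bitscore=best.best_bacterial_bitscore,
                best_family=best.best_bacterial_family,
            )
        )

    for p in ordered:
        if (
            run
            and p.scaffold_id == run[-1].scaffold_id
            and p.fragment_index - run[-1].fragment_index <= 1 + max_gap_fragments
        ):
            run.append(p)
        else:
            flush()
            run = [p]
    flush()
    return candidates


def annotate_candidates(
    candidates: Sequence[LgtCandidate],
    genes: Sequence[GeneModel],
    expression: Sequence[ExpressionInterval],
    min_expr_depth: float = 1.0,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[LgtCandidate]:
    """Attach curation context: flanking genes, overlaps and expression.

    The left/right flank is the nearest gene model wholly left/right of the
    candidate interval (none at a scaffold edge); a candidate is expressed iff
    the mean expression depth over its interval reaches ``min_expr_depth``.
    Curation status stays ``candidate``; discard labels are applied only from
    an operator-supplied curation file (see :func:`apply_curation`).
    """
    genes_by_scaffold: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        if scaffold_lengths is not None:
            length = scaffold_lengths.get(g.scaffold_id)
            if length is not None and (g.start < 0 or g.end > length):
                raise ValueError(
                    f"gene model {g.gene_id} outside scaffold {g.scaffold_id}"
                )
        genes_by_scaffold[g.scaffold_id].append(g)

    for cand in candidates:
        local = genes_by_scaffold.get(cand.scaffold_id, [])
        left = [g for g in local if g.end <= cand.start]
        right = [g for g in local if g.start >= cand.end]
        overlapping = [
            g for g in local if g.start < cand.end and g.end > cand.start
        ]
        if left:
            g = max(left, key=lambda g: g.end)
            cand.flank_left, cand.flank_left_label = g.gene_id, g.label or "none"
        if right:
            g = min(right, key=lambda g: g.start)
            cand.flank_right, cand.flank_right_label = g.gene_id, g.label or "none"
        if overlapping:
            cand.overlapping_gene = overlapping[0].gene_id
        cand.mean_expression = mean_depth(
            expression, cand.scaffold_id, cand.start, cand.end
        )
        cand.expressed = cand.mean_expression >= min_expr_depth
    return list(candidates)


def apply_curation(
    candidates: Sequence[LgtCandidate], curation_path: str | Path
) -> list[LgtCandidate]:
    """Apply operator curation verdicts from a TSV of
    (scaffold, start, end, status)."""
    verdicts: dict[tuple[str, int, int], str] = {}
    with open(curation_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            verdicts[(cols[0], int(cols[1]), int(cols[2]))] = cols[3]
    for cand in candidates:
        status = verdicts.get((cand.scaffold_id, cand.start, cand.end))
        if status:
            cand.curation_status = status
    return list(candidates)


def detect_lgt(
    records: Sequence[ScaffoldRecord],
    hits: Sequence[Hit],
    genes: Sequence[GeneModel] = (),
    expression: Sequence[ExpressionInterval] = (),
    bact_min: float = 75.0,
    euk_max: float = 0.0,
    max_gap_fragments: int = 0,
    min_expr_depth: float = 1.0,
    fragment_length: int = 1000,
) -> list[LgtCandidate]:
    """End-to-end LGT candidate calling on a (kept) assembly.

    Runs on the scaffolds given: by the pipeline's order-of-operations
    contract this is the assembly after contaminant removal, so no candidate
    is emitted on a removed scaffold.
    """
    lengths = {r.id: len(r.seq) for r in records}
    ids = set(lengths)
    relevant = [h for h in hits if h.scaffold_id in ids]
    pieces = build_piece_screens(relevant, lengths, fragment_length)
    kept = screen_pieces(pieces, bact_min=bact_min, euk_max=euk_max)
    candidates = fuse_adjacent(kept, max_gap_fragments=max_gap_fragments)
    return annotate_candidates(
        candidates, genes, expression,
        min_expr_depth=min_expr_depth, scaffold_lengths=lengths,
    )
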