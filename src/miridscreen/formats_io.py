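"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally.  Formats that are 1-based
inclusive on disk (BLAST-style tabular, GFF3, classic pileup) are converted at
this boundary and nowhere else.

Sequence normalization: residues are uppercased, ``U`` maps to ``T`` and any
other IUPAC ambiguity code collapses to ``N`` (real assemblies contain them;
the screens treat them as unmatchable).
"""

from __future__ import annotations

import json
import logging
import typing
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("miridscreen")

ALPHABET = frozenset("ACGTN")
_AMBIGUITY = "RYSWKMBDHV"
_COLLAPSE = str.maketrans({c: "N" for c in _AMBIGUITY})

HIT_TABLE_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore db family"
).split()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldRecord:
    """One assembly sequence; the unit of screening."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Hit:
    """One homology match on a scaffold, in scaffold coordinates.

    ``db`` tags which reference database produced the match (``bacterial`` or
    ``eukaryote``); ``family`` is the subject's taxon family label (may be
    empty).  ``fragment_index`` records which fragment of the fragmented
    scaffold the hit derives from.
    """

    scaffold_id: str
    start: int
    end: int
    subject_id: str
    family: str
    bitscore: float
    db: str
    fragment_index: int = 0
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"hit on {self.scaffold_id}: bad interval [{self.start},{self.end})"
            )
        if self.bitscore < 0:
            raise ValueError(f"hit on {self.scaffold_id}: negative bitscore")
        if self.db not in ("bacterial", "eukaryote"):
            raise ValueError(f"hit on {self.scaffold_id}: unknown db {self.db!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SiteCounts:
    """Per-site read counts from a pooled alignment."""

    scaffold_id: str
    pos: int  # 0-based
    ref: str
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    indel_events: int = 0
    masked: bool = False

    @property
    def coverage(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def counts(self) -> dict[str, int]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}


@dataclass
class GeneModel:
    """A gene model from a GFF3 file, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    label: str = ""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, collapse ambiguity codes to N.

    Returns the normalized sequence and the number of collapsed residues.
    """
    up = raw.upper().replace("U", "T")
    seq = up.translate(_COLLAPSE)
    n_collapsed = sum(up.count(c) for c in _AMBIGUITY)
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq, n_collapsed


def read_fasta(path: str | Path) -> list[ScaffoldRecord]:
    """Read a FASTA file into normalized :class:`ScaffoldRecord` objects."""
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    n_collapsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id: {rec.id}")
        seen.add(rec.id)
        seq, nc = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty record: {rec.id}")
        n_collapsed += nc
        records.append(ScaffoldRecord(rec.id, seq))
    if n_collapsed:
        log.info("collapsed %d ambiguity residues to N", n_collapsed)
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# hit tables (12 standard BLAST tabular columns + db + family)
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path, fragment_length: int = 1000) -> list[Hit]:
    """Read a 14-column tab-separated hit table.

    Query coordinates are 1-based inclusive on disk; reversed intervals
    (qstart > qend) are normalized to (min, max) with the ``reverse`` flag set.
    """
    hits: list[Hit] = []
    n_reversed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 14:
                raise ValueError(
                    f"line {lineno}: expected 14 columns, found {len(cols)}"
                )
            try:
                bitscore = float(cols[11])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-numeric bitscore {cols[11]!r}"
                ) from None
            qstart, qend = int(cols[6]), int(cols[7])
            reverse = qstart > qend
            if reverse:
                qstart, qend = qend, qstart
                n_reversed += 1
            start = qstart - 1
            hits.append(
                Hit(
                    scaffold_id=cols[0],
                    start=start,
                    end=qend,
                    subject_id=cols[1],
                    family=cols[13],
                    bitscore=bitscore,
                    db=cols[12],
                    fragment_index=start // fragment_length,
                    reverse=reverse,
                )
            )
    if n_reversed:
        log.info("normalized %d reversed hit intervals", n_reversed)
    return hits


def write_hit_table(hits: Iterable[Hit], path: str | Path) -> None:
    """Write hits back as 1-based inclusive tabular rows (inverse of reading)."""
    with open(path, "w") as fh:
        for h in hits:
            qstart, qend = h.start + 1, h.end
            if h.reverse:
                qstart, qend = qend, qstart
            length = h.end - h.start
            row = [
                h.scaffold_id, h.subject_id, "100.00", str(length), "0", "0",
                str(qstart), str(qend), "1", str(length), "0.0",
                f"{h.bitscore:g}", h.db, h.family,
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# pileup / counts TSV
# ---------------------------------------------------------------------------

COUNTS_TSV_HEADER = (
    "scaffold", "pos", "ref", "A", "C", "G", "T", "coverage", "indel_events",
)


def decode_pileup_bases(ref: str, bases: str) -> tuple[dict[str, int], int, int]:
    """Decode a classic pileup base string.

    ``.``/``,`` count toward the reference base; ``ACGTacgt`` toward that base;
    ``+<n><seq>``/``-<n><seq>`` increment the indel-event counter and their
    inserted/deleted residues are skipped; ``^`` (plus the mapping-quality
    character) and ``$`` are skipped; ``*`` and ``N`` placeholders are read
    placeholders that count toward depth but not toward any base.

    Returns (base counts, indel events, decoded read symbols).
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    ref = ref.upper()
    indels = 0
    decoded = 0
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret plus mapping quality character
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            length = int(bases[i + 1 : j])
            indels += 1
            i = j + length
            continue
        if ch in ".,":
            if ref in counts:
                counts[ref] += 1
            decoded += 1
        elif ch.upper() in counts:
            counts[ch.upper()] += 1
            decoded += 1
        elif ch in "*Nn":
            decoded += 1
        i += 1
    return counts, indels, decoded


def read_pileup(path: str | Path) -> list[SiteCounts]:
    """Read either classic 6-column pileup text or the 9-column counts TSV.

    The counts TSV declares itself with a header line; its positions are
    0-based.  Classic pileup positions are 1-based and converted.
    """
    sites: list[SiteCounts] = []
    with open(path) as fh:
        first = fh.readline()
        if not first:
            return sites
        if first.rstrip("\n").split("\t")[: len(COUNTS_TSV_HEADER)] == list(
            COUNTS_TSV_HEADER
        ):
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                sites.append(
                    SiteCounts(
                        scaffold_id=cols[0],
                        pos=int(cols[1]),
                        ref=cols[2],
                        a=int(cols[3]),
                        c=int(cols[4]),
                        g=int(cols[5]),
                        t=int(cols[6]),
                        indel_events=int(cols[8]),
                    )
                )
            return sites
        for lineno, line in enumerate([first] + fh.readlines(), start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {lineno}: expected 6 pileup columns")
            chrom, pos1, ref, depth, bases = cols[0], cols[1], cols[2], cols[3], cols[4]
            counts, indels, decoded = decode_pileup_bases(ref, bases)
            if decoded != int(depth):
                log.warning(
                    "line %d: declared depth %s but decoded %d reads; "
                    "decoded counts win",
                    lineno, depth, decoded,
                )
            sites.append(
                SiteCounts(
                    scaffold_id=chrom,
                    pos=int(pos1) - 1,
                    ref=ref.upper(),
                    a=counts["A"],
                    c=counts["C"],
                    g=counts["G"],
                    t=counts["T"],
                    indel_events=indels,
                )
            )
    return sites


def write_counts_tsv(sites: Iterable[SiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_TSV_HEADER) + "\n")
        for s in sites:
            fh.write(
                f"{s.scaffold_id}\t{s.pos}\t{s.ref}\t{s.a}\t{s.c}\t{s.g}\t{s.t}"
                f"\t{s.coverage}\t{s.indel_events}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models (read-only) and expression coverage
# ---------------------------------------------------------------------------

def read_gff_genes(
    path: str | Path, featuretypes: Sequence[str] = ("gene",)
) -> list[GeneModel]:
    """Read gene models from a GFF3 file (1-based inclusive -> half-open)."""
    import gffutils

    genes: list[GeneModel] = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype not in featuretypes:
            continue
        attrs = feat.attributes
        gene_id = attrs.get("ID", [f"{feat.seqid}:{feat.start}"])[0]
        label = attrs.get("class", attrs.get("label", [""]))[0]
        genes.append(
            GeneModel(
                scaffold_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                gene_id=gene_id,
                label=label,
            )
        )
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.label:
                attrs += f";class={g.label}"
            fh.write(
                f"{g.scaffold_id}\tminidscreen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


@dataclass
class ExpressionInterval:
    """BED-like per-interval expression depth, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    depth: float


def read_expression(path: str | Path) -> list[ExpressionInterval]:
    out: list[ExpressionInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            out.append(
                ExpressionInterval(cols[0], int(cols[1]), int(cols[2]), float(cols[3]))
            )
    return out


def write_expression(track: Iterable[ExpressionInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fh.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{iv.depth:g}\n")


def mean_depth(track: Sequence[ExpressionInterval], scaffold_id: str,
               start: int, end: int) -> float:
    """Mean expression depth over [start, end) on one scaffold."""
    if end <= start:
        return 0.0
    total = 0.0
    for iv in track:
        if iv.scaffold_id != scaffold_id:
            continue
        overlap = min(end, iv.end) - max(start, iv.start)
        if overlap > 0:
            total += overlap * iv.depth
    return total / (end - start)


# ---------------------------------------------------------------------------
# generic report serialization (TSV / JSON) for dataclass records
# ---------------------------------------------------------------------------

def _to_cell(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping representation
    if isinstance(value, (list, tuple)):
        return json.dumps(list(value))
    return str(value)


def _from_cell(text: str, ftype: object) -> object:
    origin = typing.get_origin(ftype)
    if text == "NA":
        return None
    if ftype is bool or ftype == "bool":
        return text == "true"
    if ftype is int or ftype == "int":
        return int(text)
    if ftype is float or ftype == "float":
        return float(text)
    if origin in (list, tuple):
        return json.loads(text)
    if ftype is str or ftype == "str":
        return text
    # optional / unions: try json then raw
    try:
        return json.loads(text)
    except (json.JSONDecodeError, TypeError):
        return text


def write_report(records: Sequence[object], path: str | Path,
                 format: str = "tsv", record_type: type | None = None) -> None:
    """Serialize dataclass records to TSV or JSON with deterministic columns.

    Floats are written with full (shortest round-tripping) precision, stated
    in the TSV header comment; output round-trips through
    :func:`read_report`.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format: {format}")
    if record_type is None and records:
        record_type = type(records[0])
    cols = [f.name for f in fields(record_type)] if record_type else []
    if format == "json":
        payload = [
            {c: getattr(r, c) for c in cols} for r in records
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    with open(path, "w") as fh:
        fh.write("# floats: full precision (repr)\n")
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(_to_cell(getattr(r, c)) for c in cols) + "\n")


def read_report(path: str | Path, record_type: type,
                format: str = "tsv") -> list[object]:
    """Read records written by :func:`write_report` back into dataclasses."""
    assert is_dataclass(record_type)
    hints = typing.get_type_hints(record_type)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        out = []
        for row in payload:
            kwargs = {}
            for f in fields(record_type):
                if f.name in row:
                    v = row[f.name]
                    if isinstance(v, list) and typing.get_origin(hints[f.name]) is tuple:
                        v = tuple(v)
                    kwargs[f.name] = v
            out.append(record_type(**kwargs))
        return out
    out = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            cells = line.split("\t")
            kwargs = {
                name: _from_cell(cell, hints[name])
                for name, cell in zip(header, cells)
            }
            out.append(record_type(**kwargs))
    return out
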