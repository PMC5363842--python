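"""Readers and writers for the text formats the pipeline touches.

Supported on input: BED (3–6 columns, kept verbatim as 0-based half-open),
GTF and RepeatMasker ``.out`` (1-based inclusive, converted to the internal
0-based half-open convention as ``(start-1, end)``), FASTA, and bedGraph
(consumed by :mod:`kzfptools.profiles`). On output: BED, FASTA, TSV and
Newick. All conversion happens here and nowhere else.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

from .intervals import GenomicInterval, RepeatAnnotation, SequenceRecord

_DIALECTS = ("BED", "GTF", "RepeatMasker")

# standard 15-column RepeatMasker .out layout (whitespace-separated):
# score div del ins query qbegin qend qleft strand repname class/family
# rbegin rend rleft id
RM_QUERY_COL = 4
RM_BEGIN_COL = 5
RM_END_COL = 6
RM_STRAND_COL = 8
RM_NAME_COL = 9
RM_CLASSFAM_COL = 10


class ParseError(ValueError):
    """Malformed line in a recognised dialect; message carries line number."""


def _as_stream(source) -> TextIO:
    if isinstance(source, str):
        return _io.StringIO(source)
    return source


def parse_intervals(stream, dialect: str = "BED"):
    """Parse an annotation stream into internal coordinates.

    Parameters
    ----------
    stream : text stream or str
        The file content in the named dialect.
    dialect : {"BED", "GTF", "RepeatMasker"}

    Returns
    -------
    list of GenomicInterval (BED, GTF) or RepeatAnnotation (RepeatMasker).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    stream = _as_stream(stream)
    parse_line = {
        "BED": _parse_bed_line,
        "GTF": _parse_gtf_line,
        "RepeatMasker": _parse_rm_line,
    }[dialect]
    out = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if dialect == "BED" and line.startswith(("track", "browser", "#")):
            continue
        if dialect == "GTF" and line.startswith("#"):
            continue
        if dialect == "RepeatMasker" and not line.lstrip()[:1].isdigit():
            continue  # the two header lines (and any rerun banner)
        try:
            rec = parse_line(line)
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{dialect} line {lineno}: {exc}") from exc
        if rec is not None:
            out.append(rec)
    return out


def _parse_bed_line(line: str) -> GenomicInterval:
    fields = line.split("\t")
    if len(fields) < 3:
        raise ValueError(f"expected >=3 tab-separated columns, got {len(fields)}")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    strand = fields[5] if len(fields) > 5 else "."
    if end <= start:
        raise ValueError(f"end {end} <= start {start}")
    return GenomicInterval(chrom, start, end, strand, name)


def _parse_gtf_line(line: str) -> GenomicInterval:
    fields = line.split("\t")
    if len(fields) < 8:
        raise ValueError(f"expected >=8 tab-separated columns, got {len(fields)}")
    chrom = fields[0]
    start1, end1 = int(fields[3]), int(fields[4])
    start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
    if end <= start:
        raise ValueError(f"end {end1} < start {start1} after conversion")
    strand = fields[6] if fields[6] in ("+", "-") else "."
    name = None
    if len(fields) > 8:
        for token in fields[8].split(";"):
            token = token.strip()
            if token.startswith(("gene_id", "transcript_id")):
                name = token.split(" ", 1)[1].strip().strip('"')
                break
    return GenomicInterval(chrom, start, end, strand, name)


def _parse_rm_line(line: str) -> RepeatAnnotation:
    fields = line.split()
    if len(fields) < RM_CLASSFAM_COL + 1:
        raise ValueError(f"expected >={RM_CLASSFAM_COL + 1} columns, got {len(fields)}")
    chrom = fields[RM_QUERY_COL]
    start1, end1 = int(fields[RM_BEGIN_COL]), int(fields[RM_END_COL])
    start, end = start1 - 1, end1
    if end <= start:
        raise ValueError(f"end {end1} < start {start1} after conversion")
    strand = "+" if fields[RM_STRAND_COL] == "+" else "-"  # 'C' = complement
    subfamily = fields[RM_NAME_COL]
    classfam = fields[RM_CLASSFAM_COL]
    rep_class, _, rep_family = classfam.partition("/")
    return RepeatAnnotation(
        interval=GenomicInterval(chrom, start, end, strand, subfamily),
        rep_class=rep_class,
        rep_family=rep_family or rep_class,
        subfamily=subfamily,
    )


def parse_fasta(stream) -> list[SequenceRecord]:
    """Read FASTA; folds wrapped lines, preserves case.

    Raises on empty sequence bodies and on duplicate ids — both indicate a
    corrupted export rather than a deliberate input.
    """
    stream = _as_stream(stream)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence body for record {rec.id!r}")
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=seq))
    return records


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def serialize(objects, fmt: str) -> str:
    """Serialise homogeneous objects to text.

    fmt="BED"    : GenomicInterval list, 6-column, 0-based half-open.
    fmt="FASTA"  : SequenceRecord list, 60-column wrap.
    fmt="TSV"    : pandas DataFrame (header row included).
    fmt="Newick" : a tree exposing ``to_newick()`` (see kzfptools.phylo).
    """
    if fmt == "BED":
        return serialize_bed(objects)
    if fmt == "FASTA":
        return serialize_fasta(objects)
    if fmt == "TSV":
        try:
            return objects.to_csv(sep="\t", index=False)
        except AttributeError as exc:
            raise TypeError("TSV serialisation expects a pandas DataFrame") from exc
    if fmt == "Newick":
        try:
            return objects.to_newick()
        except AttributeError as exc:
            raise TypeError("Newick serialisation expects a tree object") from exc
    raise ValueError(f"unknown format {fmt!r}")


def serialize_bed(intervals: Iterable[GenomicInterval]) -> str:
    lines = []
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"BED serialisation expects GenomicInterval, got {type(iv)}")
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def serialize_fasta(records: Iterable[SequenceRecord], width: int = 60) -> str:
    parts = []
    for rec in records:
        if not isinstance(rec, SequenceRecord):
            raise TypeError(f"FASTA serialisation expects SequenceRecord, got {type(rec)}")
        body = "\n".join(
            rec.residues[i : i + width] for i in range(0, len(rec.residues), width)
        )
        parts.append(f">{rec.id}\n{body}")
    return "\n".join(parts) + ("\n" if parts else "")
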