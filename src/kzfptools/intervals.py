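"""Genomic coordinate primitives and interval-set arithmetic.

Every coordinate in this package is 0-based, half-open (``[start, end)``),
on a named chromosome. Conversions from 1-based formats (GTF, RepeatMasker)
happen only at the I/O boundary (:mod:`kzfptools.io`). Chromosome names are
compared by exact string equality; no ``chr`` prefix normalisation is done,
so mixed naming surfaces as empty overlaps rather than silent aliasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-annotated genomic span, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty, matched verbatim).
    start, end : int
        0-based half-open span; ``0 <= start < end`` is enforced.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name : str, optional
        Free-text label carried through BED round trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def oriented_strand(self) -> str:
        """Strand to use where orientation is required.

        Unstranded features are treated as ``+``; a warning is logged once
        per call site because the upstream tracks are expected to carry
        strand annotation.
        """
        if self.strand == ".":
            logger.warning(
                "unstranded interval %s:%d-%d treated as '+'",
                self.chrom, self.start, self.end,
            )
            return "+"
        return self.strand

    def five_prime(self) -> int:
        """Coordinate of the 5' end (start on +, end on −)."""
        return self.start if self.oriented_strand() == "+" else self.end

    def three_prime(self) -> int:
        return self.end if self.oriented_strand() == "+" else self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


@dataclass(frozen=True)
class RepeatAnnotation:
    """A RepeatMasker-style repeat call: class / family / subfamily."""

    interval: GenomicInterval
    rep_class: str
    rep_family: str
    subfamily: str

    def __post_init__(self) -> None:
        for attr in ("rep_class", "rep_family", "subfamily"):
            if not getattr(self, attr):
                raise ValueError(f"{attr} must be a non-empty string")


@dataclass(frozen=True)
class Transcript:
    """A transcript with its exon structure.

    Exons are stored sorted 5'→3' by strand, must not overlap, and must lie
    within the transcript interval on the same chromosome and strand.
    """

    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    id: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: at least one exon required")
        object.__setattr__(self, "exons", tuple(self.exons))
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(f"transcript {self.id}: exon chrom/strand mismatch")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"transcript {self.id}: exon outside transcript span")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        expected = genomic if self.interval.oriented_strand() == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValueError(f"transcript {self.id}: exons not sorted 5'->3'")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Interval-set arithmetic (per chromosome, strand-blind)
# ---------------------------------------------------------------------------

def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint spans (strand dropped)."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        ivs = sorted(_by_chrom(intervals)[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Number of distinct bases covered (input is merged first)."""
    return sum(len(iv) for iv in merge_intervals(intervals)) if intervals else 0


def _boolean_op(a, b, keep) -> list[GenomicInterval]:
    """Sweep-line boolean combination of two merged interval sets."""
    out: list[GenomicInterval] = []
    a_by, b_by = _by_chrom(merge_intervals(a) if a else []), _by_chrom(merge_intervals(b) if b else [])
    for chrom in sorted(set(a_by) | set(b_by)):
        events: list[tuple[int, int, int]] = []  # (pos, delta_a, delta_b)
        for iv in a_by.get(chrom, []):
            events += [(iv.start, 1, 0), (iv.end, -1, 0)]
        for iv in b_by.get(chrom, []):
            events += [(iv.start, 0, 1), (iv.end, 0, -1)]
        events.sort()
        in_a = in_b = 0
        seg_start = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            if seg_start is not None and keep(in_a > 0, in_b > 0) and pos > seg_start:
                out.append(GenomicInterval(chrom, seg_start, pos))
            while i < len(events) and events[i][0] == pos:
                in_a += events[i][1]
                in_b += events[i][2]
                i += 1
            seg_start = pos
    return merge_intervals(out) if out else []


def subtract_intervals(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Bases covered by ``a`` but not ``b`` (both merged internally)."""
    return _boolean_op(a, b, lambda x, y: x and not y)


def intersect_intervals(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Bases covered by both sets."""
    return _boolean_op(a, b, lambda x, y: x and y)


class IntervalIndex:
    """Sorted-array overlap index over a merged interval set.

    Supports O(log n) "does [s, e) overlap anything" queries via
    ``numpy.searchsorted`` over the merged span boundaries — the workhorse
    behind permutation-null counting, where millions of such queries occur.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals) if intervals else []:
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom], dtype=np.int64)
            self._ends[chrom] = np.asarray(self._ends[chrom], dtype=np.int64)

    def overlaps_any(self, chrom: str, start, end) -> np.ndarray:
        """Vectorised: for arrays start/end on one chromosome, whether each
        query interval overlaps ≥1 bp of the indexed set."""
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(start.shape, dtype=bool)
        s, e = self._starts[chrom], self._ends[chrom]
        # candidate: last indexed interval starting before the query end
        idx = np.searchsorted(s, end, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(start.shape, dtype=bool)
        hit[ok] = e[idx[ok]] > start[ok]
        return hit

    def count_overlapping(self, intervals: Sequence[GenomicInterval]) -> int:
        by = _by_chrom(intervals)
        n = 0
        for chrom, ivs in by.items():
            n += int(
                self.overlaps_any(
                    chrom,
                    [iv.start for iv in ivs],
                    [iv.end for iv in ivs],
                ).sum()
            )
        return n

    def gap_to_nearest(self, iv: GenomicInterval) -> float:
        """Minimal edge-to-edge gap to any indexed interval on the same
        chromosome; 0 when overlapping, ``inf`` on an empty chromosome."""
        if iv.chrom not in self._starts:
            return float("inf")
        s, e = self._starts[iv.chrom], self._ends[iv.chrom]
        if bool(self.overlaps_any(iv.chrom, iv.start, iv.end)[0]):
            return 0.0
        left = e[e <= iv.start]
        right = s[s >= iv.end]
        gaps = []
        if left.size:
            gaps.append(iv.start - left.max())
        if right.size:
            gaps.append(right.min() - iv.end)
        return float(min(gaps)) if gaps else float("inf")
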