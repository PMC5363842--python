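"""Strand-aware coverage metaprofiles and fold-change response calls.

A metaprofile averages a signal track over many elements on a common
coordinate frame: a fixed upstream flank at 1-bp resolution, the element
body rescaled to a fixed number of bins, and a fixed downstream flank.
Defaults follow the element-centred RNA-seq views used throughout the
analysis: 1.5 kb upstream, 3.5 kb downstream, 95% confidence band as
mean ± 1.96·SE.

Differential response between two conditions is a declared fold-change
classifier (|log2 FC| ≥ 1 plus a minimum-signal filter), a deliberately
simple stand-in for count-model differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex, _by_chrom


class CoverageTrack:
    """Piecewise-constant per-base signal with bedGraph semantics.

    Intervals are 0-based half-open and must not overlap within a
    chromosome; uncovered positions read as 0. ``library_size`` is the
    total signal (value × length summed), used for counts-per-million
    normalisation.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        lib = 0.0
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            if (values < 0).any():
                raise ValueError("coverage values must be non-negative")
            self._data[chrom] = (starts, ends, values)
            lib += float((values * (ends - starts)).sum())
        self.library_size = lib

    @classmethod
    def from_bedgraph(cls, text: str) -> "CoverageTrack":
        data: dict[str, list[list]] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"bedGraph line {lineno}: expected 4 columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            data.setdefault(chrom, [[], [], []])
            data[chrom][0].append(s)
            data[chrom][1].append(e)
            data[chrom][2].append(v)
        return cls({c: tuple(np.asarray(x) for x in cols) for c, cols in data.items()})

    def to_bedgraph(self) -> str:
        lines = []
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                lines.append(f"{chrom}\t{s}\t{e}\t{v:g}")
        return "\n".join(lines) + ("\n" if lines else "")

    def per_base(self, chrom: str, start: int, end: int, cpm: bool = False) -> np.ndarray:
        """Signal at every base of [start, end); positions before 0 are NaN
        (masked); positions beyond the last covered interval read 0."""
        out = np.zeros(end - start)
        if start < 0:
            out[: -start] = np.nan
        if chrom in self._data:
            starts, ends, values = self._data[chrom]
            lo = np.searchsorted(ends, start, side="right")
            hi = np.searchsorted(starts, end, side="left")
            for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
                a, b = max(s, start), min(e, end)
                if b > a:
                    out[a - start : b - start] = v
        if cpm and self.library_size > 0:
            valid = ~np.isnan(out)
            out[valid] = out[valid] * 1e6 / self.library_size
        return out

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        """Pointwise sum of two tracks (used by the linearity property)."""
        data = {}
        for chrom in set(self._data) | set(other._data):
            bounds = set()
            for trk in (self, other):
                if chrom in trk._data:
                    s, e, _ = trk._data[chrom]
                    bounds.update(s.tolist())
                    bounds.update(e.tolist())
            edges = np.array(sorted(bounds), dtype=np.int64)
            starts, ends = edges[:-1], edges[1:]
            vals = np.zeros(len(starts))
            for trk in (self, other):
                if chrom in trk._data:
                    for i, (a, b) in enumerate(zip(starts, ends)):
                        vals[i] += trk.per_base(chrom, int(a), int(b))[0]
            keep = vals != 0
            data[chrom] = (starts[keep], ends[keep], vals[keep])
        return CoverageTrack(data)


@dataclass(frozen=True)
class MetaProfile:
    grid: np.ndarray  # position labels: negative flank, body bins, positive flank
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_elements: int
    flank_up: int
    flank_down: int
    body_bins: int


def _element_profile(
    track: CoverageTrack,
    el: GenomicInterval,
    flank_up: int,
    flank_down: int,
    body_bins: int,
    chrom_lengths: dict[str, int] | None,
    cpm: bool,
) -> np.ndarray:
    strand = el.oriented_strand()
    if strand == "+":
        lo, hi = el.start - flank_up, el.end + flank_down
    else:
        lo, hi = el.start - flank_down, el.end + flank_up
    sig = track.per_base(el.chrom, lo, hi, cpm=cpm)
    if chrom_lengths is not None and el.chrom in chrom_lengths:
        over = hi - chrom_lengths[el.chrom]
        if over > 0:
            sig[len(sig) - over :] = np.nan
    if strand == "-":
        sig = sig[::-1]
    up = sig[:flank_up]
    body = sig[flank_up : flank_up + len(el)]
    down = sig[flank_up + len(el) :]
    # body length-normalised: average per bin over near-equal chunks
    chunks = np.array_split(body, body_bins)
    body_binned = np.array([np.nanmean(c) if len(c) else np.nan for c in chunks])
    return np.concatenate([up, body_binned, down])


def metaprofile(
    elements: list[GenomicInterval],
    track: CoverageTrack,
    flank_up: int = 1500,
    flank_down: int = 3500,
    body_bins: int = 100,
    chrom_lengths: dict[str, int] | None = None,
    normalize: bool = True,
) -> MetaProfile:
    """Average signal over elements on a strand-oriented common frame.

    Windows extending past a chromosome end are truncated (masked), not an
    error. CI is the pointwise normal approximation mean ± 1.96·sd/√n.
    """
    if not elements:
        raise ValueError("metaprofile requires at least one element")
    mat = np.vstack(
        [
            _element_profile(
                track, el, flank_up, flank_down, body_bins, chrom_lengths, normalize
            )
            for el in elements
        ]
    )
    n_valid = (~np.isnan(mat)).sum(axis=0)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN grid positions
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    sd = np.where(n_valid > 1, sd, 0.0)
    se = np.where(n_valid > 0, sd / np.sqrt(np.maximum(n_valid, 1)), 0.0)
    grid = np.concatenate(
        [np.arange(-flank_up, 0), np.arange(body_bins), np.arange(body_bins, body_bins + flank_down)]
    )
    return MetaProfile(
        grid=grid,
        mean=mean,
        ci_low=mean - 1.96 * se,
        ci_high=mean + 1.96 * se,
        n_elements=len(elements),
        flank_up=flank_up,
        flank_down=flank_down,
        body_bins=body_bins,
    )


@dataclass(frozen=True)
class ResponseCall:
    element: str
    mean_a: float
    mean_b: float
    log2fc: float
    response: str  # up / down / unchanged


def classify_response(
    counts_a,
    counts_b,
    labels=None,
    lfc_threshold: float = 1.0,
    min_signal: float = 0.0,
    pseudocount: float = 1.0,
) -> list[ResponseCall]:
    """Fold-change response classes between conditions A and B.

    log2FC = log2((b + pseudocount) / (a + pseudocount)); "up" when
    log2FC ≥ threshold and max(a, b) ≥ min_signal, symmetric for "down",
    otherwise "unchanged".
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition vectors must have equal length")
    if labels is None:
        labels = [f"el{i}" for i in range(len(a))]
    if len(labels) != len(a):
        raise ValueError("labels length mismatch")
    lfc = np.log2((b + pseudocount) / (a + pseudocount))
    out = []
    for lab, ai, bi, f in zip(labels, a, b, lfc):
        if f >= lfc_threshold and max(ai, bi) >= min_signal:
            cls = "up"
        elif f <= -lfc_threshold and max(ai, bi) >= min_signal:
            cls = "down"
        else:
            cls = "unchanged"
        out.append(ResponseCall(lab, float(ai), float(bi), float(f), cls))
    return out


def element_signal(track: CoverageTrack, elements: list[GenomicInterval], cpm: bool = True) -> np.ndarray:
    """Mean per-base signal over each element (NaN-masked positions ignored)."""
    return np.array(
        [np.nanmean(track.per_base(e.chrom, e.start, e.end, cpm=cpm)) for e in elements]
    )


def per_cluster_category_fc(
    calls: list[ResponseCall],
    memberships: dict[str, tuple[int, str]],
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-cluster, per-category mean log2FC plus the overall cluster mean.

    ``memberships`` maps element label → (cluster id, category); categories
    with fewer than ``min_n`` members in a cluster are omitted, and the
    overall mean ("all") is taken across the retained elements only.
    """
    rows = []
    by_cluster: dict[int, dict[str, list[float]]] = {}
    for c in calls:
        if c.element not in memberships:
            continue
        cid, cat = memberships[c.element]
        by_cluster.setdefault(cid, {}).setdefault(cat, []).append(c.log2fc)
    for cid in sorted(by_cluster):
        retained: list[float] = []
        for cat in sorted(by_cluster[cid]):
            vals = by_cluster[cid][cat]
            if len(vals) < min_n:
                continue
            retained.extend(vals)
            rows.append(
                {
                    "cluster": cid,
                    "category": cat,
                    "n": len(vals),
                    "mean_log2fc": float(np.mean(vals)),
                }
            )
        if retained:
            rows.append(
                {
                    "cluster": cid,
                    "category": "all",
                    "n": len(retained),
                    "mean_log2fc": float(np.mean(retained)),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "category", "n", "mean_log2fc"])


DISTANCE_BINS = ("overlap", "<5kb", "<20kb", ">=20kb")


def stratify_by_peak_distance(
    elements: list[GenomicInterval],
    peaks: list[GenomicInterval],
    near: int = 5000,
    far: int = 20000,
) -> tuple[dict[GenomicInterval, str], pd.DataFrame]:
    """Exclusive distance-to-peak categories per element.

    Assignment order: overlap → <5 kb → <20 kb → ≥20 kb, with strict
    inequalities on the bounds (a gap of exactly 5000 bp falls in the
    <20 kb bin). Elements on peak-free chromosomes land in the ≥20 kb bin.
    """
    idx = IntervalIndex(peaks)
    assignment: dict[GenomicInterval, str] = {}
    for el in elements:
        gap = idx.gap_to_nearest(el)
        if gap == 0:
            b = "overlap"
        elif gap < near:
            b = "<5kb"
        elif gap < far:
            b = "<20kb"
        else:
            b = ">=20kb"
        assignment[el] = b
    summary = pd.DataFrame(
        [
            {"bin": b, "n": sum(1 for v in assignment.values() if v == b)}
            for b in DISTANCE_BINS
        ]
    )
    return assignment, summary


def compare_cluster_vs_isolated(
    calls: list[ResponseCall], in_cluster: set[str]
) -> dict:
    """Rank-sum comparison of log2FC between in-cluster and isolated elements."""
    a = [c.log2fc for c in calls if c.element in in_cluster]
    b = [c.log2fc for c in calls if c.element not in in_cluster]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "in_cluster_log2fc": np.asarray(a),
        "isolated_log2fc": np.asarray(b),
        "statistic": float(stat),
        "p_value": float(p),
    }
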