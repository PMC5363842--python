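"""Permutation nulls and composition summaries.

Observed feature/region coincidence is compared against nulls built by
shuffling either side within its own chromosome (lengths and chromosome
assignments preserved, overlaps among shuffled objects permitted). The
empirical p-value uses the add-one estimator
``(1 + #{null >= observed}) / (n_shuffles + 1)``, which can never reach 0
at a finite number of shuffles.

Also here: exact hypergeometric tests of repeat-subfamily over-representation
inside clusters, peak composition by annotation category, and the
differential-acetylation summaries (KO-not-WT nucleotide fraction, per-
subfamily KO/WT ratios, per-cluster peak density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import Cluster, shuffle_within_chromosome
from .intervals import (
    GenomicInterval,
    IntervalIndex,
    RepeatAnnotation,
    _by_chrom,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)

EXCLUDED_REPEAT_CLASSES = frozenset(
    {"Satellite", "Simple_repeat", "Low_complexity", "Unknown"}
)


@dataclass(frozen=True)
class ShuffleResult:
    observed: int
    null_counts: tuple[int, ...]
    expected: float
    empirical_p: float
    n_shuffles: int
    seed: int


@dataclass(frozen=True)
class SubfamilyEnrichment:
    subfamily: str
    count_region: int
    count_genome: int
    prop_region: float
    prop_genome: float
    p: float
    significant: bool


def shuffle_enrichment(
    regions: list[GenomicInterval],
    features: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    n_shuffles: int = 100,
    mode: str = "shuffle_regions",
    seed: int = 0,
) -> ShuffleResult:
    """Empirical enrichment of features in regions against a shuffle null.

    ``mode="shuffle_regions"`` repositions the regions (the 100× cluster
    shuffle); ``mode="shuffle_features"`` repositions the features (the
    10'000× peak shuffle). The statistic is the number of features
    overlapping ≥1 bp of any region.
    """
    if mode not in ("shuffle_regions", "shuffle_features"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    observed = IntervalIndex(regions).count_overlapping(features)
    null_counts = []
    if mode == "shuffle_regions":
        for _ in range(n_shuffles):
            shuf = shuffle_within_chromosome(regions, chrom_lengths, rng)
            null_counts.append(IntervalIndex(shuf).count_overlapping(features))
    else:
        idx = IntervalIndex(regions)
        feats_by = _by_chrom(features)
        lengths = {
            chrom: np.array([len(iv) for iv in ivs], dtype=np.int64)
            for chrom, ivs in feats_by.items()
        }
        for chrom, lens in lengths.items():
            if (lens > chrom_lengths[chrom]).any():
                raise ValueError(f"feature longer than chromosome {chrom}")
        for _ in range(n_shuffles):
            n = 0
            for chrom, lens in lengths.items():
                starts = rng.integers(0, chrom_lengths[chrom] - lens + 1)
                n += int(idx.overlaps_any(chrom, starts, starts + lens).sum())
            null_counts.append(n)
    null_arr = np.asarray(null_counts)
    p = (1 + int((null_arr >= observed).sum())) / (n_shuffles + 1)
    return ShuffleResult(
        observed=observed,
        null_counts=tuple(null_counts),
        expected=float(null_arr.mean()),
        empirical_p=p,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def subfamily_enrichment(
    clusters: list[Cluster],
    repeats: list[RepeatAnnotation],
    alpha: float = 0.01,
) -> list[SubfamilyEnrichment]:
    """One-sided exact test of subfamily over-representation inside clusters.

    For each subfamily a 2×2 table (inside/outside clusters × this
    subfamily/all other repeats) is scored with the hypergeometric
    distribution; the reported proportions are fractions of repeats inside
    the cluster regions and genome-wide.
    """
    if not repeats:
        raise ValueError("subfamily_enrichment requires a non-empty repeat list")
    spans = IntervalIndex([c.span for c in clusters])
    in_region = np.array(
        [bool(spans.overlaps_any(r.interval.chrom, r.interval.start, r.interval.end)[0]) for r in repeats]
    )
    subfams = np.array([r.subfamily for r in repeats])
    n_total = len(repeats)
    n_in = int(in_region.sum())
    out = []
    for sf in sorted(set(subfams)):
        is_sf = subfams == sf
        k_in = int((is_sf & in_region).sum())
        k_tot = int(is_sf.sum())
        # P(X >= k_in) drawing n_in repeats from n_total with k_tot marked
        p = float(stats.hypergeom.sf(k_in - 1, n_total, k_tot, n_in))
        out.append(
            SubfamilyEnrichment(
                subfamily=sf,
                count_region=k_in,
                count_genome=k_tot,
                prop_region=k_in / n_in if n_in else 0.0,
                prop_genome=k_tot / n_total,
                p=p,
                significant=p < alpha,
            )
        )
    return out


@dataclass(frozen=True)
class PeakComposition:
    counts: dict[str, int]
    fractions: dict[str, float]
    selected_subfamilies: tuple[str, ...]


def peak_composition(
    peaks: list[GenomicInterval],
    units: list[GenomicInterval],
    repeats: list[RepeatAnnotation],
    min_subfamily_hits: int = 100,
) -> PeakComposition:
    """Assign each peak to one category: KZFP/rGU > selected TE > other.

    Selected TEs exclude the Satellite / Simple_repeat / Low_complexity /
    Unknown classes and any subfamily with fewer than ``min_subfamily_hits``
    members among the supplied (cluster-restricted) repeats. A peak
    overlapping several selected TEs goes to the subfamily with the largest
    overlap, ties to the leftmost TE.
    """
    subfam_counts: dict[str, int] = {}
    for r in repeats:
        if r.rep_class in EXCLUDED_REPEAT_CLASSES:
            continue
        subfam_counts[r.subfamily] = subfam_counts.get(r.subfamily, 0) + 1
    selected = {sf for sf, n in subfam_counts.items() if n >= min_subfamily_hits}

    unit_idx = IntervalIndex(units)
    sel_repeats_by = _by_chrom(
        [r.interval for r in repeats if r.subfamily in selected and r.rep_class not in EXCLUDED_REPEAT_CLASSES]
    )
    sel_lookup = {
        (r.interval.chrom, r.interval.start, r.interval.end): r.subfamily
        for r in repeats
        if r.subfamily in selected and r.rep_class not in EXCLUDED_REPEAT_CLASSES
    }

    counts: dict[str, int] = {"KZFP/rGU": 0, "other": 0}
    for sf in sorted(selected):
        counts[sf] = 0
    for pk in peaks:
        if bool(unit_idx.overlaps_any(pk.chrom, pk.start, pk.end)[0]):
            counts["KZFP/rGU"] += 1
            continue
        best = None  # (overlap, -start) maximised
        for riv in sel_repeats_by.get(pk.chrom, []):
            ov = min(pk.end, riv.end) - max(pk.start, riv.start)
            if ov > 0:
                key = (ov, -riv.start)
                if best is None or key > best[0]:
                    best = (key, riv)
            _ = ov
        if best is not None:
            counts[sel_lookup[(best[1].chrom, best[1].start, best[1].end)]] += 1
        else:
            counts["other"] += 1
    n = len(peaks)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return PeakComposition(
        counts=counts, fractions=fractions, selected_subfamilies=tuple(sorted(selected))
    )


def differential_acetylation_summary(
    peaks_wt: list[GenomicInterval],
    peaks_ko: list[GenomicInterval],
    clusters: list[Cluster],
    promoters: list[GenomicInterval] | None = None,
    repeats: list[RepeatAnnotation] | None = None,
    min_te: int = 3,
):
    """Summaries of acetylation gained upon KO within cluster regions.

    Returns a dict with:

    ``ko_only_fraction``
        Fraction of cluster-span bases covered by KO peaks but not WT peaks.
    ``ko_only_fraction_no_promoter``
        Same, after discarding peaks that overlap a supplied promoter.
    ``subfamily_ko_wt_ratio``
        DataFrame, one row per subfamily with ≥ ``min_te`` members inside
        clusters: members hit by ≥1 KO peak / members hit by ≥1 WT peak
        (NaN when the denominator is 0).
    ``cluster_peak_density``
        DataFrame of per-cluster peak counts normalised by span length,
        per condition.
    """
    spans = [c.span for c in clusters]
    span_bases = total_length(spans)
    wt_m = merge_intervals(peaks_wt) if peaks_wt else []
    ko_m = merge_intervals(peaks_ko) if peaks_ko else []

    def ko_only_fraction(wt, ko):
        ko_only = subtract_intervals(ko, wt)
        in_span = intersect_intervals(ko_only, spans)
        return total_length(in_span) / span_bases if span_bases else 0.0

    result = {"ko_only_fraction": ko_only_fraction(wt_m, ko_m)}

    if promoters:
        prom_idx = IntervalIndex(promoters)

        def drop_promoter(peaks):
            return [
                p
                for p in peaks
                if not bool(prom_idx.overlaps_any(p.chrom, p.start, p.end)[0])
            ]

        result["ko_only_fraction_no_promoter"] = ko_only_fraction(
            merge_intervals(drop_promoter(peaks_wt)) if peaks_wt else [],
            merge_intervals(drop_promoter(peaks_ko)) if peaks_ko else [],
        )
    else:
        result["ko_only_fraction_no_promoter"] = result["ko_only_fraction"]

    if repeats is not None:
        span_idx = IntervalIndex(spans)
        wt_idx, ko_idx = IntervalIndex(peaks_wt), IntervalIndex(peaks_ko)
        rows = []
        in_cluster = [
            r
            for r in repeats
            if bool(span_idx.overlaps_any(r.interval.chrom, r.interval.start, r.interval.end)[0])
        ]
        by_sf: dict[str, list[RepeatAnnotation]] = {}
        for r in in_cluster:
            by_sf.setdefault(r.subfamily, []).append(r)
        for sf in sorted(by_sf):
            members = by_sf[sf]
            if len(members) < min_te:
                continue
            n_ko = sum(
                bool(ko_idx.overlaps_any(m.interval.chrom, m.interval.start, m.interval.end)[0])
                for m in members
            )
            n_wt = sum(
                bool(wt_idx.overlaps_any(m.interval.chrom, m.interval.start, m.interval.end)[0])
                for m in members
            )
            rows.append(
                {
                    "subfamily": sf,
                    "n_members": len(members),
                    "n_ko": n_ko,
                    "n_wt": n_wt,
                    "ko_wt_ratio": n_ko / n_wt if n_wt else np.nan,
                }
            )
        result["subfamily_ko_wt_ratio"] = pd.DataFrame(
            rows, columns=["subfamily", "n_members", "n_ko", "n_wt", "ko_wt_ratio"]
        )

    dens_rows = []
    for c in clusters:
        for cond, peaks in (("WT", peaks_wt), ("KO", peaks_ko)):
            n = IntervalIndex([c.span]).count_overlapping(peaks)
            dens_rows.append(
                {
                    "cluster": c.id,
                    "condition": cond,
                    "n_peaks": n,
                    "density_per_bp": n / len(c.span),
                }
            )
    result["cluster_peak_density"] = pd.DataFrame(
        dens_rows, columns=["cluster", "condition", "n_peaks", "density_per_bp"]
    )
    return result
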