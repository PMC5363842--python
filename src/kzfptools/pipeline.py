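"""End-to-end demo pipeline on a synthetic genome.

Runs the full analysis — simulate, annotate ORFs, chain clusters, test TE
enrichment, build the consensus tree, call retrocopies, profile signal —
and writes every result as deterministic text (BED/TSV/FASTA/Newick/JSON).
With a fixed seed two runs produce byte-identical output trees.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignParams
from .clusters import build_clusters, overlap_fisher
from .enrichment import differential_acetylation_summary, shuffle_enrichment, subfamily_enrichment
from .fingerprint import detect_retrocopy, find_repeated_blocks, find_tandem_duplications
from .intervals import GenomicInterval, SequenceRecord
from .io import serialize_bed, serialize_fasta
from .phylo import cluster_consensus_tree
from .profiles import classify_response, compare_cluster_vs_isolated, element_signal, metaprofile
from .simulate import (
    GenomeConfig,
    TruthTable,
    simulate_annotations,
    simulate_sequences,
    simulate_signal,
    truth_transcripts,
)
from .znf import Fingerprint, scan_kzfp_orfs


def run_pipeline(
    config: GenomeConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    n_shuffles: int = 200,
) -> dict:
    """Run the whole analysis on one simulated genome; return a summary dict.

    When ``outdir`` is given, all intermediate tables and sequences are
    written there as text.
    """
    config = config or GenomeConfig(seed=seed)
    units, krab_hits, repeats, truth = simulate_annotations(config, seed=seed)
    genome = simulate_sequences(config, truth, seed=seed)
    peaks, tracks = simulate_signal(config, truth, seed=seed)

    # --- ORF annotation ------------------------------------------------------
    orfs = []
    for chrom_rec in genome:
        orfs.extend(scan_kzfp_orfs(chrom_rec))
    detected = [o.interval for o in orfs]
    expected = truth.objects[truth.objects["kind"].isin(["unit", "retrocopy"])]
    n_expected = len(expected)
    matched = _match_orfs(orfs, truth)
    sensitivity = matched / n_expected if n_expected else 0.0
    precision = matched / len(orfs) if orfs else 0.0

    # --- clusters (on the annotated units: pseudogenized units still count) --
    clusters, isolated = build_clusters(units)

    # --- enrichment ----------------------------------------------------------
    enr = subfamily_enrichment(clusters, repeats, alpha=0.01)
    shuf = shuffle_enrichment(
        [c.span for c in clusters],
        [r.interval for r in repeats if r.rep_family in ("ERVK", "ERV1")],
        config.chrom_lengths,
        n_shuffles=n_shuffles,
        mode="shuffle_regions",
        seed=seed,
    )
    table, odds, fisher_p = overlap_fisher(
        [u for u in units], peaks["WT"], window=10_000,
        chrom_lengths=config.chrom_lengths, seed=seed,
    )
    diff = differential_acetylation_summary(
        peaks["WT"], peaks["KO"], clusters, repeats=repeats, min_te=3
    )

    # --- consensus phylogeny --------------------------------------------------
    chrom_seq = {rec.id: rec.residues for rec in genome}
    cluster_seqs = {}
    for c in clusters:
        recs = []
        for m in c.members:
            s = chrom_seq[m.chrom][m.start : m.end]
            recs.append(SequenceRecord(m.name or f"{m.chrom}:{m.start}", s))
        cluster_seqs[f"cluster_{c.id}"] = recs
    consensuses, dmat, tree = cluster_consensus_tree(cluster_seqs, AlignParams())

    # --- fingerprints ---------------------------------------------------------
    fp_rows = []
    for o in orfs:
        fp = o.fingerprint
        fp_rows.append(
            {
                "orf": f"{o.interval.chrom}:{o.interval.start}-{o.interval.end}",
                "n_znf": o.n_znf,
                "fingerprint": fp.to_text(),
                "n_tandem_runs": len(find_tandem_duplications(fp)),
                "n_repeated_blocks": len(find_repeated_blocks(fp)),
            }
        )
    fp_df = pd.DataFrame(fp_rows)

    # --- retrocopies ----------------------------------------------------------
    donors, candidates = truth_transcripts(config, truth, genome)
    retro_calls = [detect_retrocopy(t, seq, donors) for t, seq in candidates]
    retro_truth = set(truth.of_kind("retrocopy")["name"])
    retro_called = {c.candidate for c in retro_calls if c.verdict}
    retro_sens = len(retro_called & retro_truth) / len(retro_truth) if retro_truth else 0.0
    retro_fp = len(retro_called - retro_truth)

    # --- expression response --------------------------------------------------
    unit_names = [u.name for u in units]
    sig_wt = element_signal(tracks["WT"], units, cpm=False)
    sig_ko = element_signal(tracks["KO"], units, cpm=False)
    calls = classify_response(sig_wt, sig_ko, labels=unit_names, min_signal=5.0)
    in_cluster = set(
        truth.of_kind("unit").query("cluster_id > 0")["name"]
    )
    cmp = compare_cluster_vs_isolated(calls, in_cluster)
    prof = metaprofile(units, tracks["KO"], chrom_lengths=config.chrom_lengths)

    summary = {
        "n_units_planted": len(units),
        "n_orfs_detected": len(orfs),
        "orf_sensitivity": sensitivity,
        "orf_precision": precision,
        "n_clusters": len(clusters),
        "n_isolated": len(isolated),
        "top_enriched_subfamily": max(enr, key=lambda e: e.prop_region - e.prop_genome).subfamily,
        "n_significant_subfamilies": sum(e.significant for e in enr),
        "shuffle_observed": shuf.observed,
        "shuffle_expected": shuf.expected,
        "shuffle_empirical_p": shuf.empirical_p,
        "fisher_odds_ratio": odds,
        "fisher_p": fisher_p,
        "ko_only_fraction": diff["ko_only_fraction"],
        "tree_newick": tree.to_newick(),
        "retrocopy_sensitivity": retro_sens,
        "retrocopy_false_positives": retro_fp,
        "n_up_in_ko": sum(1 for c in calls if c.response == "up"),
        "cluster_vs_isolated_p": cmp["p_value"],
        "mean_log2fc_in_cluster": float(np.mean(cmp["in_cluster_log2fc"])),
        "mean_log2fc_isolated": float(np.mean(cmp["isolated_log2fc"])),
        "metaprofile_peak": float(np.nanmax(prof.mean)),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "genome.fa").write_text(serialize_fasta(genome))
        (outdir / "units.bed").write_text(serialize_bed(units))
        (outdir / "orfs.bed").write_text(serialize_bed(detected))
        (outdir / "krab_hits.bed").write_text(serialize_bed(krab_hits))
        for cond in ("WT", "KO"):
            (outdir / f"peaks_{cond}.bed").write_text(serialize_bed(peaks[cond]))
            (outdir / f"coverage_{cond}.bedgraph").write_text(tracks[cond].to_bedgraph())
        cluster_df = pd.DataFrame(
            [
                {
                    "id": c.id,
                    "chrom": c.chrom,
                    "start": c.span.start,
                    "end": c.span.end,
                    "n_members": c.n_members,
                    "members": ",".join(m.name or "" for m in c.members),
                }
                for c in clusters
            ]
        )
        (outdir / "clusters.tsv").write_text(cluster_df.to_csv(sep="\t", index=False))
        enr_df = pd.DataFrame([vars(e) for e in enr])
        (outdir / "subfamily_enrichment.tsv").write_text(enr_df.to_csv(sep="\t", index=False))
        (outdir / "consensus.fa").write_text(
            serialize_fasta([SequenceRecord(c.id, c.residues) for c in consensuses])
        )
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        (outdir / "fingerprints.tsv").write_text(fp_df.to_csv(sep="\t", index=False))
        retro_df = pd.DataFrame([vars(c) for c in retro_calls])
        (outdir / "retrocopies.tsv").write_text(retro_df.to_csv(sep="\t", index=False))
        calls_df = pd.DataFrame([vars(c) for c in calls])
        (outdir / "response_calls.tsv").write_text(calls_df.to_csv(sep="\t", index=False))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return summary


def _match_orfs(orfs, truth: TruthTable) -> int:
    """Planted units/retrocopies recovered by a detected ORF (finger-array
    containment and matching fingerprint count are not required here; an
    ORF counts as a match when it overlaps the planted locus on the same
    chromosome)."""
    expected = truth.objects[truth.objects["kind"].isin(["unit", "retrocopy"])]
    n = 0
    for r in expected.itertuples():
        lo = int(r.locus_start) if r.kind == "unit" else int(r.start)
        hi = int(r.locus_end) if r.kind == "unit" else int(r.end)
        if any(o.interval.chrom == r.chrom and o.interval.start < hi and lo < o.interval.end for o in orfs):
            n += 1
    return n
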