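"""Synthetic genomes with planted KZFP/rGU structure and full ground truth.

The generator emulates the genome organisation the analysis assumes:

* chromosomes carrying clusters of ≥8 repeat-anchored units lying <500 kb
  apart, plus isolated units that never satisfy the chaining rule;
* each unit locus encoding, in one reading frame, a KRAB-A segment
  followed (without stop codon) by a tandem array of C2H2 fingers joined
  by TGEKPY linkers; the KRAB annotation falls upstream of the finger
  array within the configured distance;
* an ERVK/ERV1-biased transposable-element mix inside cluster spans
  against a flatter background mix;
* intron-containing donor genes and their intronless, poly-A-tailed
  retrocopies placed on another chromosome;
* WT/KO peak sets (repressor-style peaks lost in KO, activation-style
  peaks gained over cluster TEs) and negative-binomial coverage per
  condition, with cluster elements upregulated in the KO.

Every planted object has exactly one row in the truth table, and all
randomness flows from a single seed: fixed seed ⇒ byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RepeatAnnotation, SequenceRecord, Transcript
from .profiles import CoverageTrack
from .znf import default_krab_model

# one codon per amino acid (a common-codon reverse-translation table)
CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "CGG", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

#: Repeat subfamily -> (class, family). ERVK/ERV1 LTR families dominate the
#: in-cluster mix, mirroring the composition bias the enrichment stage must
#: detect.
TE_TAXONOMY = {
    "IAPEz": ("LTR", "ERVK"),
    "RLTR10": ("LTR", "ERVK"),
    "RLTR19": ("LTR", "ERVK"),
    "RLTR4_Mm": ("LTR", "ERV1"),
    "MuRRS": ("LTR", "ERV1"),
    "MTA_Mm": ("LTR", "ERVL-MaLR"),
    "B1_Mm": ("SINE", "Alu"),
    "L1Md_F2": ("LINE", "L1"),
}

TRIPLET_POOL = (
    "RER", "QSN", "DSK", "HTN", "QGN", "RDE", "TSH", "VSN", "ESR", "KQA",
)


@dataclass(frozen=True)
class ClusterSpec:
    chrom: str
    n_units: int = 10
    gap_range: tuple[int, int] = (5_000, 40_000)  # inter-unit gap, bp (<500 kb)
    start_offset: int = 60_000


@dataclass(frozen=True)
class GenomeConfig:
    """Study conditions for the synthetic genome.

    Defaults plant 3 clusters of 10 units, 20 isolated units (in sub-cluster
    groups of 5) and 5 retrocopies, with a 70% ERVK/ERV1 TE mix inside
    clusters against a flat background.
    """

    chrom_lengths: dict = field(
        default_factory=lambda: {
            "chr1": 1_200_000,
            "chr2": 1_200_000,
            "chr3": 1_200_000,
            "chr4": 3_500_000,
            "chr5": 1_000_000,
        }
    )
    cluster_specs: tuple = (
        ClusterSpec("chr1"),
        ClusterSpec("chr2"),
        ClusterSpec("chr3"),
    )
    n_isolated_units: int = 20
    isolated_chrom: str = "chr4"
    isolated_group_size: int = 5  # groups below the cluster min_size
    isolated_intra_gap: int = 60_000
    isolated_inter_gap: int = 600_000
    retrocopy_chrom: str = "chr5"
    n_retrocopies: int = 5
    te_mix_in_cluster: dict = field(
        default_factory=lambda: {
            "IAPEz": 0.30, "RLTR10": 0.15, "RLTR19": 0.10, "RLTR4_Mm": 0.15,
            "MuRRS": 0.05, "MTA_Mm": 0.10, "B1_Mm": 0.10, "L1Md_F2": 0.05,
        }
    )
    te_mix_background: dict = field(
        default_factory=lambda: {
            "IAPEz": 0.05, "RLTR10": 0.05, "RLTR19": 0.05, "RLTR4_Mm": 0.05,
            "MuRRS": 0.05, "MTA_Mm": 0.15, "B1_Mm": 0.30, "L1Md_F2": 0.30,
        }
    )
    n_te_per_cluster: int = 30
    n_te_background: int = 200
    te_length_range: tuple[int, int] = (300, 4_000)
    n_znf_range: tuple[int, int] = (3, 8)
    krab_gap_range: tuple[int, int] = (60, 3_000)  # KRAB end -> finger array, bp
    intron_length: int = 201  # donor genes; in-frame, stop-free
    polya_length: int = 16
    mutation_rate: float = 0.01
    peak_width: int = 500
    wt_te_peak_prob: float = 0.8  # ERVK/ERV1 cluster TEs bound in WT
    ko_te_activation_fraction: float = 0.5
    coverage_model: dict = field(
        default_factory=lambda: {
            "up_in_ko": {"WT": 50.0, "KO": 200.0},  # 4x gain upon KO
            "unchanged": {"WT": 50.0, "KO": 50.0},
        }
    )
    dispersion: float = 0.1  # NB dispersion; 0 => deterministic means
    coverage_bin: int = 50  # bp; one NB draw per bin along each element
    seed: int = 0

    def to_yaml(self) -> str:
        """Serialise the config as YAML (keys mirror the field names)."""
        import yaml
        from dataclasses import asdict

        d = asdict(self)
        d["cluster_specs"] = [asdict(s) for s in self.cluster_specs]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GenomeConfig":
        import yaml

        d = yaml.safe_load(text) or {}
        if "cluster_specs" in d:
            d["cluster_specs"] = tuple(
                ClusterSpec(
                    chrom=s["chrom"],
                    n_units=s.get("n_units", 10),
                    gap_range=tuple(s.get("gap_range", (5_000, 40_000))),
                    start_offset=s.get("start_offset", 60_000),
                )
                for s in d["cluster_specs"]
            )
        for key in ("te_length_range", "n_znf_range", "krab_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for mix in (self.te_mix_in_cluster, self.te_mix_background):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("TE mix probabilities must sum to 1")
            unknown = set(mix) - set(TE_TAXONOMY)
            if unknown:
                raise ValueError(f"unknown TE subfamilies {sorted(unknown)}")
        if self.n_isolated_units < 0 or self.n_retrocopies < 0:
            raise ValueError("counts must be >= 0")
        if self.intron_length % 3:
            raise ValueError("intron_length must be a codon multiple")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth for every planted object, one row each."""

    objects: pd.DataFrame  # units, krab hits, TEs, retrocopies, clusters
    config: GenomeConfig

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.objects[self.objects["kind"] == kind].reset_index(drop=True)

    def intervals(self, kind: str) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.name)
            for r in self.of_kind(kind).itertuples()
        ]


def _reverse_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def _finger_dna(triplet: str) -> str:
    spacer = ["G", "K", "A", "F", "S", triplet[0], "R", "S", triplet[1], "E", "L", triplet[2]]
    aa = "C" + "AE" + "C" + "".join(spacer) + "H" + "IRT" + "H" + "TGEKPY"
    return _reverse_translate(aa)


def _intron(length: int) -> str:
    # GT...AG, codon-aligned, stop-free in every phase (interior has no A)
    body = ("CGT" * length)[: length - 5]
    return "GT" + body + "CAG"


def _unit_layout(n_znf: int, krab_gap: int, is_donor: bool, cfg: GenomeConfig, rng):
    """Sequence and sense-relative coordinates for one unit locus."""
    krab_dna = _reverse_translate(default_krab_model().consensus)
    gap_codons = krab_gap // 3
    gap_dna = CODON["G"] * gap_codons
    triplets = [TRIPLET_POOL[rng.integers(0, len(TRIPLET_POOL))] for _ in range(n_znf)]
    array_dna = "".join(_finger_dna(t) for t in triplets)
    stop = "TAA"
    if is_donor:
        half = (gap_codons // 2) * 3
        seq = krab_dna + gap_dna[:half] + _intron(cfg.intron_length) + gap_dna[half:] + array_dna + stop
        intron_rel = (len(krab_dna) + half, len(krab_dna) + half + cfg.intron_length)
    else:
        seq = krab_dna + gap_dna + array_dna + stop
        intron_rel = None
    array_start = len(seq) - 3 - len(array_dna)
    coords = {
        "krab": (0, len(krab_dna)),
        "array": (array_start, array_start + len(array_dna)),
        "orf": (0, len(seq)),
        "intron": intron_rel,
    }
    return seq, coords, triplets


def _mirror(rel: tuple[int, int], locus_len: int) -> tuple[int, int]:
    return locus_len - rel[1], locus_len - rel[0]


def simulate_annotations(config: GenomeConfig, seed: int | None = None):
    """Plant units, KRAB hits, TEs, retrocopies and cluster truth.

    Returns ``(unit_intervals, krab_intervals, repeats, truth)``. The truth
    table also stores the per-unit layout (locus coordinates, finger
    triplets, donor linkage) consumed by :func:`simulate_sequences`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    unit_counter = 0

    def plant_unit(chrom, locus_start, cluster_id, is_donor, strand):
        nonlocal unit_counter
        unit_counter += 1
        name = f"unit_{unit_counter:03d}"
        n_znf = int(rng.integers(config.n_znf_range[0], config.n_znf_range[1] + 1))
        krab_gap = 3 * int(rng.integers(config.krab_gap_range[0] // 3, config.krab_gap_range[1] // 3 + 1))
        seq, coords, triplets = _unit_layout(n_znf, krab_gap, is_donor, config, rng)
        L = len(seq)
        rel = {k: v for k, v in coords.items() if v is not None}
        if strand == "-":
            rel = {k: _mirror(v, L) for k, v in rel.items()}
        row = {
            "kind": "unit",
            "name": name,
            "chrom": chrom,
            "start": locus_start + rel["array"][0],
            "end": locus_start + rel["array"][1],
            "strand": strand,
            "cluster_id": cluster_id,
            "n_znf": n_znf,
            "fingerprint": "-".join(triplets),
            "locus_start": locus_start,
            "locus_end": locus_start + L,
            "krab_start": locus_start + rel["krab"][0],
            "krab_end": locus_start + rel["krab"][1],
            "orf_start": locus_start + rel["orf"][0],
            "orf_end": locus_start + rel["orf"][1],
            "intron_start": locus_start + rel["intron"][0] if is_donor else -1,
            "intron_end": locus_start + rel["intron"][1] if is_donor else -1,
            "is_donor": is_donor,
            "donor": "",
            "sense_seq": seq,
            "expr_class": "up_in_ko" if cluster_id > 0 else "unchanged",
        }
        rows.append(row)
        return row, L

    # --- clusters -----------------------------------------------------------
    donor_slots: list[str] = []
    for ci, spec in enumerate(config.cluster_specs, start=1):
        pos = spec.start_offset
        members = []
        for u in range(spec.n_units):
            is_donor = len(donor_slots) < config.n_retrocopies and u in (2, 5)
            strand = "+" if rng.random() < 0.5 else "-"
            row, L = plant_unit(spec.chrom, pos, ci, is_donor, strand)
            if is_donor:
                donor_slots.append(row["name"])
            members.append(row)
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            pos += L + gap
        if pos > config.chrom_lengths[spec.chrom]:
            raise ValueError(
                f"chromosome {spec.chrom} too short for cluster of {spec.n_units} units"
            )
        rows.append(
            {
                "kind": "cluster",
                "name": f"cluster_{ci}",
                "chrom": spec.chrom,
                "start": members[0]["start"],
                "end": members[-1]["end"],
                "strand": ".",
                "cluster_id": ci,
            }
        )

    # --- isolated units (groups below the chaining minimum) ------------------
    pos = 60_000
    for i in range(config.n_isolated_units):
        strand = "+" if rng.random() < 0.5 else "-"
        _, L = plant_unit(config.isolated_chrom, pos, 0, False, strand)
        if (i + 1) % config.isolated_group_size == 0:
            pos += L + config.isolated_inter_gap
        else:
            pos += L + config.isolated_intra_gap
    if pos > config.chrom_lengths[config.isolated_chrom]:
        raise ValueError("isolated-unit chromosome too short for requested content")

    # --- retrocopies ----------------------------------------------------------
    pos = 50_000
    for ri, donor_name in enumerate(donor_slots[: config.n_retrocopies], start=1):
        donor = next(r for r in rows if r.get("name") == donor_name)
        exonic_len = (donor["locus_end"] - donor["locus_start"]) - config.intron_length
        L = exonic_len + config.polya_length
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "kind": "retrocopy",
                "name": f"retro_{ri}",
                "chrom": config.retrocopy_chrom,
                "start": pos,
                "end": pos + L,
                "strand": strand,
                "cluster_id": 0,
                "donor": donor_name,
                "expr_class": "unchanged",
            }
        )
        pos += L + 100_000
    if config.n_retrocopies > len(donor_slots):
        raise ValueError("not enough cluster units to host the requested donors")
    if pos > config.chrom_lengths[config.retrocopy_chrom]:
        raise ValueError("retrocopy chromosome too short for requested content")

    # --- transposable elements ------------------------------------------------
    cluster_rows = [r for r in rows if r["kind"] == "cluster"]
    te_counter = 0

    def plant_te(chrom, start, length, subfamily, in_cluster, cluster_id):
        nonlocal te_counter
        te_counter += 1
        cls, fam = TE_TAXONOMY[subfamily]
        rows.append(
            {
                "kind": "te",
                "name": f"te_{te_counter:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "cluster_id": cluster_id,
                "subfamily": subfamily,
                "rep_class": cls,
                "rep_family": fam,
                "expr_class": "up_in_ko" if (in_cluster and fam in ("ERVK", "ERV1")) else "unchanged",
            }
        )

    in_names = sorted(config.te_mix_in_cluster)
    in_probs = np.array([config.te_mix_in_cluster[s] for s in in_names])
    bg_names = sorted(config.te_mix_background)
    bg_probs = np.array([config.te_mix_background[s] for s in bg_names])
    unit_loci: dict[str, list[tuple[int, int]]] = {}
    for r in rows:
        if r["kind"] == "unit":
            unit_loci.setdefault(r["chrom"], []).append((r["locus_start"], r["locus_end"]))
        elif r["kind"] == "retrocopy":
            unit_loci.setdefault(r["chrom"], []).append((r["start"], r["end"]))

    def clear_of_units(chrom, start, end):
        return not any(start < e and end > s for s, e in unit_loci.get(chrom, []))

    for cr in cluster_rows:
        span_len = cr["end"] - cr["start"]
        for _ in range(config.n_te_per_cluster):
            length = int(rng.integers(*config.te_length_range))
            # TEs sit in the intergenic space of the cluster, not on coding loci
            for _attempt in range(200):
                start = cr["start"] + int(rng.integers(0, max(1, span_len - length)))
                if clear_of_units(cr["chrom"], start, start + length):
                    break
            sf = in_names[rng.choice(len(in_names), p=in_probs)]
            plant_te(cr["chrom"], start, length, sf, True, cr["cluster_id"])
    chroms = sorted(config.chrom_lengths)
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for cr in cluster_rows:
        spans_by_chrom.setdefault(cr["chrom"], []).append((cr["start"], cr["end"]))
    for _ in range(config.n_te_background):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(*config.te_length_range))
        for _attempt in range(200):
            start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
            if (
                not any(start < e and start + length > s for s, e in spans_by_chrom.get(chrom, []))
                and clear_of_units(chrom, start, start + length)
            ):
                break
        sf = bg_names[rng.choice(len(bg_names), p=bg_probs)]
        plant_te(chrom, start, length, sf, False, 0)

    truth = TruthTable(objects=pd.DataFrame(rows), config=config)
    units = truth.intervals("unit")
    krab_hits = [
        GenomicInterval(r.chrom, int(r.krab_start), int(r.krab_end), r.strand, f"krab_{r.name}")
        for r in truth.of_kind("unit").itertuples()
    ]
    repeats = [
        RepeatAnnotation(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.name),
            rep_class=r.rep_class,
            rep_family=r.rep_family,
            subfamily=r.subfamily,
        )
        for r in truth.of_kind("te").itertuples()
    ]
    return units, krab_hits, repeats, truth


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_sequences(
    config: GenomeConfig, truth: TruthTable, seed: int | None = None
) -> list[SequenceRecord]:
    """Write the genome FASTA implied by the truth table.

    Backgrounds are i.i.d. uniform ACGT; planted loci (units with optional
    introns, retrocopies as intron-free donor copies plus a genomic poly-A
    run) are pasted in, then point substitutions are applied to the planted
    loci at ``mutation_rate``. Retrocopies mutate independently of their
    donor, emulating post-insertion divergence.
    """
    if truth.config is not config and truth.config != config:
        raise ValueError("truth table was generated from a different config")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_arrays = {
        chrom: bases[rng.integers(0, 4, size=length)].copy()
        for chrom, length in sorted(config.chrom_lengths.items())
    }

    def paste(chrom, start, seq):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        chrom_arrays[chrom][start : start + len(arr)] = arr

    def mutate(chrom, start, end):
        if config.mutation_rate <= 0:
            return
        n = end - start
        hits = np.flatnonzero(rng.random(n) < config.mutation_rate)
        for h in hits:
            cur = chrom_arrays[chrom][start + h]
            choices = bases[bases != cur]
            chrom_arrays[chrom][start + h] = choices[rng.integers(0, 3)]

    units = truth.of_kind("unit")
    for r in units.itertuples():
        seq = r.sense_seq if r.strand == "+" else _revcomp(r.sense_seq)
        paste(r.chrom, int(r.locus_start), seq)
        mutate(r.chrom, int(r.locus_start), int(r.locus_end))

    unit_by_name = {r.name: r for r in units.itertuples()}
    for r in truth.of_kind("retrocopy").itertuples():
        donor = unit_by_name[r.donor]
        sense = donor.sense_seq
        rel_i0 = int(donor.intron_start) - int(donor.locus_start)
        rel_i1 = int(donor.intron_end) - int(donor.locus_start)
        if donor.strand == "-":
            L = int(donor.locus_end) - int(donor.locus_start)
            rel_i0, rel_i1 = L - rel_i1, L - rel_i0
        exonic = sense[:rel_i0] + sense[rel_i1:]
        tail = exonic + "A" * config.polya_length
        seq = tail if r.strand == "+" else _revcomp(tail)
        paste(r.chrom, int(r.start), seq)
        mutate(r.chrom, int(r.start), int(r.end))

    return [
        SequenceRecord(id=chrom, residues=arr.tobytes().decode("ascii"))
        for chrom, arr in sorted(chrom_arrays.items())
    ]


def truth_transcripts(config: GenomeConfig, truth: TruthTable, genome: list[SequenceRecord]):
    """Donor and retrocopy transcript models plus oriented sequences.

    Returns ``(donors, candidates)`` where donors is a list of
    ``(Transcript, exonic_seq)`` and candidates a list of
    ``(Transcript, seq)`` covering retrocopies and the donors themselves
    (the latter as intron-bearing negative controls).
    """
    seqs = {rec.id: rec.residues for rec in genome}

    def fetch(chrom, start, end, strand):
        s = seqs[chrom][start:end]
        return s if strand == "+" else _revcomp(s)

    donors = []
    candidates = []
    units = truth.of_kind("unit")
    for r in units[units["is_donor"] == True].itertuples():  # noqa: E712
        s, e = int(r.locus_start), int(r.locus_end)
        i0, i1 = int(r.intron_start), int(r.intron_end)
        ex_genomic = [GenomicInterval(r.chrom, s, i0, r.strand), GenomicInterval(r.chrom, i1, e, r.strand)]
        exons = ex_genomic if r.strand == "+" else ex_genomic[::-1]
        t = Transcript(
            interval=GenomicInterval(r.chrom, s, e, r.strand), exons=tuple(exons), id=r.name
        )
        exonic_seq = "".join(fetch(r.chrom, ex.start, ex.end, r.strand) for ex in exons)
        donors.append((t, exonic_seq))
        candidates.append((t, fetch(r.chrom, s, e, r.strand)))
    for r in truth.of_kind("retrocopy").itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        t = Transcript(interval=iv, exons=(iv,), id=r.name)
        candidates.append((t, fetch(r.chrom, iv.start, iv.end, r.strand)))
    return donors, candidates


def _nb_draw(rng, mean: float, dispersion: float) -> float:
    if dispersion <= 0:
        return float(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return float(rng.negative_binomial(n, p))


def simulate_signal(config: GenomeConfig, truth: TruthTable, seed: int | None = None):
    """WT/KO peak sets and coverage tracks.

    WT places repressor-style peaks over every unit 3' end and over
    ERVK/ERV1 cluster TEs (with probability ``wt_te_peak_prob``); KO drops
    them and instead gains activation-style peaks over a random fraction of
    cluster TEs. Coverage over each element is a negative-binomial draw
    from its truth expression class, written as a constant per-base value.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    half = config.peak_width // 2
    peaks = {"WT": [], "KO": []}

    units = truth.of_kind("unit")
    for r in units.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.name)
        tp = iv.three_prime()
        peaks["WT"].append(
            GenomicInterval(r.chrom, max(0, tp - half), tp + half, ".", f"wtpeak_{r.name}")
        )
    tes = truth.of_kind("te")
    for r in tes.itertuples():
        in_cluster = r.cluster_id > 0
        if in_cluster and r.rep_family in ("ERVK", "ERV1") and rng.random() < config.wt_te_peak_prob:
            mid = (int(r.start) + int(r.end)) // 2
            peaks["WT"].append(
                GenomicInterval(r.chrom, max(0, mid - half), mid + half, ".", f"wtpeak_{r.name}")
            )
        if in_cluster and rng.random() < config.ko_te_activation_fraction:
            mid = (int(r.start) + int(r.end)) // 2
            peaks["KO"].append(
                GenomicInterval(r.chrom, max(0, mid - half), mid + half, ".", f"kopeak_{r.name}")
            )

    tracks = {}
    elements = pd.concat([units, tes, truth.of_kind("retrocopy")], ignore_index=True)
    bin_w = config.coverage_bin
    for cond in ("WT", "KO"):
        data: dict[str, list[list]] = {}
        for r in elements.sort_values(["chrom", "start"]).itertuples():
            mean = config.coverage_model[r.expr_class][cond]
            d = data.setdefault(r.chrom, [[], [], []])
            if d[1] and int(r.start) < d[1][-1]:
                # overlap with the previously written element: draws are
                # still consumed so WT and KO stay aligned per element
                n_bins = -(-(int(r.end) - int(r.start)) // bin_w)
                for _ in range(n_bins):
                    _nb_draw(rng, mean, config.dispersion)
                continue
            pos = int(r.start)
            while pos < int(r.end):
                end = min(pos + bin_w, int(r.end))
                val = _nb_draw(rng, mean, config.dispersion)
                if val > 0:
                    d[0].append(pos)
                    d[1].append(end)
                    d[2].append(val)
                pos = end
        tracks[cond] = CoverageTrack(
            {c: tuple(np.asarray(x) for x in cols) for c, cols in data.items()}
        )
    return peaks, tracks
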