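"""C2H2 zinc-finger and KRAB-domain annotation.

KRAB zinc-finger proteins (KZFPs) pair an N-terminal KRAB repressor domain
with a C-terminal tandem array of C2H2 zinc fingers. This module detects
both halves and their in-frame combination:

* :func:`find_c2h2_motifs` — scans a protein for the C-X(2,4)-C-X(12)-H-X(3,4)-H
  motif (21–24 residues per finger).
* :func:`extract_fingerprint` — pulls the DNA-contacting specificity triplet
  (alpha-helix positions −1, +3, +6) from each finger; the ordered list of
  triplets is the protein's "zinc fingerprint".
* :func:`detect_krab` — six-frame log-odds scan with a position-specific
  scoring model of the KRAB-A box.
* :func:`scan_kzfp_orfs` — reports open reading frames in which a KRAB
  domain precedes ≥ ``min_znf`` zinc fingers with no intervening stop codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .intervals import GenomicInterval, SequenceRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Helix positions −1, +3 and +6 of a C2H2 finger sit at positions 6, 9 and
#: 12 (1-based) of the 12-residue spacer between the second cysteine and the
#: first histidine — i.e. 7, 4 and 1 residues before that histidine.
FINGERPRINT_SPACER_OFFSETS = (5, 8, 11)


@dataclass(frozen=True)
class ZnfMotif:
    """One C2H2 zinc finger located in a protein sequence."""

    start: int
    end: int  # half-open protein offsets
    cys_positions: tuple[int, int]
    his_positions: tuple[int, int]
    spacer: str  # the 12 residues between second C and first H
    linker: str  # up to 7 residues following the motif

    def __post_init__(self) -> None:
        if len(self.spacer) != 12:
            raise ValueError("C2H2 spacer must be exactly 12 residues")
        if not 21 <= self.end - self.start <= 24:
            raise ValueError("C2H2 motif length must be 21-24 residues")


@dataclass(frozen=True)
class Fingerprint:
    """Ordered specificity triplets, one per finger, N→C."""

    triplets: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "triplets", tuple(self.triplets))
        for t in self.triplets:
            if len(t) != 3:
                raise ValueError(f"fingerprint triplet must be 3 residues, got {t!r}")

    def __len__(self) -> int:
        return len(self.triplets)

    def __iter__(self):
        return iter(self.triplets)

    def __getitem__(self, i):
        return self.triplets[i]

    def to_text(self) -> str:
        """Dash-joined form used in TSV output, e.g. ``RER-QSN``."""
        return "-".join(self.triplets)

    @classmethod
    def from_text(cls, text: str) -> "Fingerprint":
        return cls(tuple(text.split("-"))) if text else cls(())


def find_c2h2_motifs(protein: SequenceRecord | str) -> list[ZnfMotif]:
    """Left-to-right, shortest-match, non-overlapping C2H2 motif scan.

    At each candidate position the smallest C-C gap (2..4) is tried first,
    then the smallest H-H gap (3..4); scanning resumes after the final
    histidine of an accepted motif. ``X`` ambiguity never satisfies an
    anchor position.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein
    motifs: list[ZnfMotif] = []
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] != "C":
            i += 1
            continue
        hit = None
        for a in (2, 3, 4):  # residues between the cysteines
            c2 = i + 1 + a
            if c2 >= n or seq[c2] != "C":
                continue
            h1 = c2 + 13
            if h1 >= n or seq[h1] != "H":
                continue
            spacer = seq[c2 + 1 : h1]
            if "*" in spacer:
                continue
            for b in (3, 4):  # residues between the histidines
                h2 = h1 + 1 + b
                if h2 < n and seq[h2] == "H" and "*" not in seq[h1 + 1 : h2]:
                    hit = (i, c2, h1, h2, spacer)
                    break
            if hit:
                break
        if hit is None:
            i += 1
            continue
        c1, c2, h1, h2, spacer = hit
        end = h2 + 1
        motifs.append(
            ZnfMotif(
                start=c1,
                end=end,
                cys_positions=(c1, c2),
                his_positions=(h1, h2),
                spacer=spacer,
                linker=seq[end : min(end + 7, n)],
            )
        )
        i = end
    return motifs


def extract_fingerprint(motifs: Sequence[ZnfMotif]) -> Fingerprint:
    """Specificity triplet (helix −1, +3, +6) per finger, in array order."""
    triplets = []
    for m in motifs:
        if len(m.spacer) != 12:
            raise ValueError("motif spacer must be 12 residues")
        triplets.append("".join(m.spacer[o] for o in FINGERPRINT_SPACER_OFFSETS))
    return Fingerprint(tuple(triplets))


# ---------------------------------------------------------------------------
# KRAB scoring model
# ---------------------------------------------------------------------------

class PssmModel:
    """Position-specific scoring model over the 20-letter alphabet.

    Scores are log2 odds against a uniform background; unknown residues
    (X, *) contribute 0 bits. The packaged default covers the ~42-column
    KRAB-A box.
    """

    def __init__(self, probs: np.ndarray, name: str = "pssm"):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(AA_ALPHABET):
            raise ValueError(
                f"PSSM must be (n_columns, {len(AA_ALPHABET)}); got {probs.shape}"
            )
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PSSM rows must each sum to 1")
        self.probs = probs
        self.name = name
        self.log_odds = np.log2(probs / (1.0 / len(AA_ALPHABET)))

    @property
    def n_columns(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def score_window(self, window: str) -> float:
        if len(window) != self.n_columns:
            raise ValueError("window length must equal the number of PSSM columns")
        s = 0.0
        for col, aa in enumerate(window):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                s += self.log_odds[col, idx]
        return s

    def score_sequence(self, seq: str) -> np.ndarray:
        """Window score at every start position (length n-w+1)."""
        w = self.n_columns
        if len(seq) < w:
            return np.zeros(0)
        enc = np.array([_AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)
        scores = np.zeros(len(seq) - w + 1)
        for col in range(w):
            idx = enc[col : col + len(scores)]
            valid = idx >= 0
            scores[valid] += self.log_odds[col, idx[valid]]
        return scores

    def to_text(self) -> str:
        lines = ["# columns: " + " ".join(AA_ALPHABET)]
        for row in self.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, name: str = "pssm") -> "PssmModel":
        rows = [
            [float(x) for x in line.split()]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(np.array(rows), name=name)

    @classmethod
    def from_consensus(
        cls, consensus: str, match_prob: float = 0.7, name: str = "pssm"
    ) -> "PssmModel":
        off = (1.0 - match_prob) / (len(AA_ALPHABET) - 1)
        probs = np.full((len(consensus), len(AA_ALPHABET)), off)
        for col, aa in enumerate(consensus):
            probs[col, _AA_INDEX[aa]] = match_prob
        return cls(probs, name=name)


def default_krab_model() -> PssmModel:
    """The packaged KRAB-A box scoring model (42 columns)."""
    text = (
        resources.files("kzfptools").joinpath("data/krab_a_pssm.txt").read_text()
    )
    return PssmModel.from_text(text, name="KRAB-A")


def default_krab_threshold(model: PssmModel, fraction: float = 0.6) -> float:
    """Reporting threshold: ``fraction`` of the maximum attainable score."""
    return fraction * model.max_score


@dataclass(frozen=True)
class KrabHit:
    """A KRAB-domain hit with genomic placement and frame."""

    interval: GenomicInterval
    frame: int  # 0-2 within the strand
    strand: str
    score: float  # bits
    protein_start: int = 0  # offset in the frame's translation

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class KzfpOrf:
    """A KRAB→ZNF open reading frame (the KZFP/rGU gene model)."""

    krab: KrabHit
    znfs: tuple[ZnfMotif, ...]
    frame: int
    strand: str
    interval: GenomicInterval
    protein: str  # KRAB start through first stop (stop excluded)
    fingerprint: Fingerprint = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "znfs", tuple(self.znfs))
        if self.fingerprint is None:
            object.__setattr__(self, "fingerprint", extract_fingerprint(self.znfs))

    @property
    def n_znf(self) -> int:
        return len(self.znfs)


def _six_frames(dna: str) -> list[tuple[str, int, str]]:
    """(protein, frame, strand) for all six reading frames. Stops kept as *."""
    frames = []
    rc = str(Seq(dna).reverse_complement())
    for strand, seq in (("+", dna), ("-", rc)):
        for f in range(3):
            sub = seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append((str(Seq(sub).translate()), f, strand))
    return frames


def _codon_to_genomic(p_start: int, p_end: int, frame: int, strand: str, n: int):
    """Map a protein offset range in a frame back to genomic coordinates."""
    g0, g1 = frame + 3 * p_start, frame + 3 * p_end
    if strand == "+":
        return g0, g1
    return n - g1, n - g0


def detect_krab(
    dna: SequenceRecord,
    model: PssmModel | None = None,
    threshold: float | None = None,
) -> list[KrabHit]:
    """Scan all six reading frames of ``dna`` for KRAB domains.

    Sliding-window log-odds scores against a uniform background; reported
    hits are local maxima at or above ``threshold`` (default 60% of the
    model's maximum score), with overlapping hits within one frame merged
    keeping the best-scoring window.
    """
    model = model or default_krab_model()
    if threshold is None:
        threshold = default_krab_threshold(model)
    w = model.n_columns
    n = len(dna.residues)
    hits: list[KrabHit] = []
    for protein, frame, strand in _six_frames(dna.residues):
        scores = model.score_sequence(protein)
        above = np.flatnonzero(scores >= threshold)
        if above.size == 0:
            continue
        # group window starts whose windows overlap; keep the max per group
        breaks = np.flatnonzero(np.diff(above) >= w)
        groups = np.split(above, breaks + 1)
        for grp in groups:
            best = grp[np.argmax(scores[grp])]
            g0, g1 = _codon_to_genomic(best, best + w, frame, strand, n)
            hits.append(
                KrabHit(
                    interval=GenomicInterval(dna.id, g0, g1, strand),
                    frame=frame,
                    strand=strand,
                    score=float(scores[best]),
                    protein_start=int(best),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.strand))
    return hits


def scan_kzfp_orfs(
    dna: SequenceRecord,
    model: PssmModel | None = None,
    min_znf: int = 3,
    threshold: float | None = None,
) -> list[KzfpOrf]:
    """Find KRAB→ZNF ORFs: a KRAB hit followed, in the same reading frame
    and before the next stop codon, by at least ``min_znf`` C2H2 fingers.

    When several KRAB hits precede the same stop, the 5'-most (longest ORF)
    is kept, mirroring how a maximal gene model would be drawn.
    """
    model = model or default_krab_model()
    if threshold is None:
        threshold = default_krab_threshold(model)
    n = len(dna.residues)
    orfs: list[KzfpOrf] = []
    for protein, frame, strand in _six_frames(dna.residues):
        scores = model.score_sequence(protein)
        above = np.flatnonzero(scores >= threshold)
        if above.size == 0:
            continue
        w = model.n_columns
        breaks = np.flatnonzero(np.diff(above) >= w)
        seen_stops: set[int] = set()
        for grp in np.split(above, breaks + 1):
            best = int(grp[np.argmax(scores[grp])])
            stop = protein.find("*", best)
            stop_idx = stop if stop != -1 else len(protein)
            if stop_idx in seen_stops:
                continue  # a 5'-more KRAB already claimed this ORF
            segment = protein[best:stop_idx]
            motifs = find_c2h2_motifs(segment)
            if len(motifs) < min_znf:
                continue
            seen_stops.add(stop_idx)
            p_end = stop_idx + (1 if stop != -1 else 0)  # include the stop codon
            g0, g1 = _codon_to_genomic(best, p_end, frame, strand, n)
            krab_g0, krab_g1 = _codon_to_genomic(best, best + w, frame, strand, n)
            orfs.append(
                KzfpOrf(
                    krab=KrabHit(
                        interval=GenomicInterval(dna.id, krab_g0, krab_g1, strand),
                        frame=frame,
                        strand=strand,
                        score=float(scores[best]),
                        protein_start=best,
                    ),
                    znfs=tuple(motifs),
                    frame=frame,
                    strand=strand,
                    interval=GenomicInterval(dna.id, g0, g1, strand),
                    protein=segment,
                )
            )
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return orfs
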