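"""Diversification analysis of zinc-finger arrays and retrocopy detection.

A KZFP's "zinc fingerprint" — the ordered specificity triplets of its
finger array — evolves by tandem duplication of fingers, duplication of
multi-finger blocks, and exchange of blocks between paralogs (sometimes
read from the opposite strand). This module quantifies those events,
orders paralog emergence from shared-segment presence under a Dollo
(gain-once) model, and calls processed pseudogenes (retrocopies) by the
three classic criteria: no introns, a genomically encoded poly-A tract at
the 3' end, and sequence homology to an intron-containing donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .intervals import SequenceRecord, Transcript
from .znf import Fingerprint


@dataclass(frozen=True)
class TandemRun:
    triplet: str
    start_index: int
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("a tandem run has at least 2 copies")


@dataclass(frozen=True)
class RepeatedBlock:
    block: tuple[str, ...]
    occurrences: tuple[int, ...]


@dataclass(frozen=True)
class SharedBlock:
    block: tuple[str, ...]
    pos_a: int
    pos_b: int  # position in B's native orientation
    reversed: bool = False


def find_tandem_duplications(fp: Fingerprint) -> list[TandemRun]:
    """Maximal runs of identical consecutive triplets (≥2 copies)."""
    runs: list[TandemRun] = []
    i = 0
    trip = fp.triplets
    n = len(trip)
    while i < n:
        j = i
        while j + 1 < n and trip[j + 1] == trip[i]:
            j += 1
        if j > i:
            runs.append(TandemRun(triplet=trip[i], start_index=i, copies=j - i + 1))
        i = j + 1
    return runs


def find_repeated_blocks(
    fp: Fingerprint, kmin: int = 2, kmax: int = 7
) -> list[RepeatedBlock]:
    """Blocks of ``kmin``–``kmax`` consecutive triplets occurring ≥2 times.

    Longest blocks are reported first and consume their positions: a
    shorter block is only reported from occurrences not already covered by
    a longer reported block, and needs ≥2 surviving non-overlapping
    occurrences. Within one k, candidate blocks are processed in order of
    first occurrence; occurrences of a block are taken greedily left to
    right (non-overlapping).
    """
    if kmin > kmax:
        raise ValueError("kmin must be <= kmax")
    trip = fp.triplets
    n = len(trip)
    consumed = np.zeros(n, dtype=bool)
    out: list[RepeatedBlock] = []
    for k in range(min(kmax, n), kmin - 1, -1):
        starts_by_block: dict[tuple[str, ...], list[int]] = {}
        order: list[tuple[str, ...]] = []
        for i in range(n - k + 1):
            b = trip[i : i + k]
            if b not in starts_by_block:
                starts_by_block[b] = []
                order.append(b)
            starts_by_block[b].append(i)
        for b in order:
            starts = starts_by_block[b]
            if len(starts) < 2:
                continue
            taken: list[int] = []
            last_end = -1
            for s in starts:
                if s >= last_end and not consumed[s : s + k].any():
                    taken.append(s)
                    last_end = s + k
            if len(taken) >= 2:
                out.append(RepeatedBlock(block=b, occurrences=tuple(taken)))
                for s in taken:
                    consumed[s : s + k] = True
    return out


def shared_fingerprint_blocks(
    fpA: Fingerprint,
    fpB: Fingerprint,
    min_len: int = 2,
    allow_reverse: bool = True,
) -> list[SharedBlock]:
    """Maximal common contiguous triplet blocks between two fingerprints.

    A block is maximal when it cannot be extended in both fingerprints
    simultaneously. With ``allow_reverse``, blocks shared with the reversed
    B array (opposite-strand encoding of the finger order) are also
    reported, flagged, with ``pos_b`` mapped back to B's native
    orientation.
    """
    out = []
    out.extend(_common_blocks(fpA.triplets, fpB.triplets, min_len, False, len(fpB)))
    if allow_reverse:
        out.extend(
            _common_blocks(fpA.triplets, fpB.triplets[::-1], min_len, True, len(fpB))
        )
    return out


def _common_blocks(a, b, min_len, rev, b_len):
    n, m = len(a), len(b)
    # L[i][j] = length of common suffix ending at a[i-1], b[j-1]
    L = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                L[i, j] = L[i - 1, j - 1] + 1
    blocks = []
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            l = int(L[i, j])
            if l < min_len:
                continue
            # maximal: not extendable to the right in both
            if i < n and j < m and a[i] == b[j]:
                continue
            pa, pb = i - l, j - l
            if rev:
                pb_native = b_len - (pb + l)
            else:
                pb_native = pb
            blocks.append(
                SharedBlock(
                    block=tuple(a[pa : pa + l]), pos_a=pa, pos_b=pb_native, reversed=rev
                )
            )
    blocks.sort(key=lambda x: (-len(x.block), x.pos_a, x.pos_b, x.reversed))
    return blocks


# ---------------------------------------------------------------------------
# Segment homology matrix and Dollo emergence ordering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentMatrix:
    genes: tuple[str, ...]
    segments: tuple[str, ...]
    present: np.ndarray  # bool, genes x segments
    mismatches: np.ndarray  # float, NaN where absent

    def gene_set(self, segment: str) -> frozenset[str]:
        j = self.segments.index(segment)
        return frozenset(g for i, g in enumerate(self.genes) if self.present[i, j])

    def segments_of(self, gene: str) -> frozenset[str]:
        i = self.genes.index(gene)
        return frozenset(s for j, s in enumerate(self.segments) if self.present[i, j])


def _make_local_aligner(match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _best_local(aligner, query: str, target: str):
    """(coverage of query, identity over aligned columns, mismatches)."""
    try:
        aln = aligner.align(target, query)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0, 0
    t_blocks, q_blocks = aln.aligned
    matches = mism = covered = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        covered += qe - qs
        for tt, qq in zip(target[ts:te], query[qs:qe]):
            if tt == qq:
                matches += 1
            else:
                mism += 1
    aligned_cols = matches + mism
    identity = matches / aligned_cols if aligned_cols else 0.0
    return covered / len(query), identity, mism


def build_segment_matrix(
    regions: Sequence[tuple[str, SequenceRecord]],
    segmentation: Sequence[tuple[str, str, int, int]],
    identity_threshold: float = 0.8,
    coverage_threshold: float = 0.8,
) -> SegmentMatrix:
    """Presence/absence of reference segments across genomic regions.

    ``segmentation`` rows are ``(segment_label, reference_region_label,
    start, end)`` in the reference region's own coordinates. Each segment's
    reference subsequence is locally aligned against every region; it is
    present where the best alignment covers ≥ ``coverage_threshold`` of the
    segment at ≥ ``identity_threshold`` identity.
    """
    region_map = {label: rec.residues for label, rec in regions}
    aligner = _make_local_aligner()
    genes = tuple(label for label, _ in regions)
    seg_labels = tuple(s[0] for s in segmentation)
    present = np.zeros((len(genes), len(seg_labels)), dtype=bool)
    mism = np.full((len(genes), len(seg_labels)), np.nan)
    for j, (seg, ref_label, start, end) in enumerate(segmentation):
        ref = region_map[ref_label]
        if not (0 <= start < end <= len(ref)):
            raise ValueError(f"segment {seg!r}: coordinates outside region {ref_label!r}")
        query = ref[start:end]
        for i, gene in enumerate(genes):
            target = region_map[gene]
            if len(query) > len(target):
                continue
            cov, ident, nm = _best_local(aligner, query, target)
            if cov >= coverage_threshold and ident >= identity_threshold:
                present[i, j] = True
                mism[i, j] = nm
    return SegmentMatrix(genes=genes, segments=seg_labels, present=present, mismatches=mism)


@dataclass
class EmergenceNode:
    """A node of the emergence tree: genes placed here plus child lineages."""

    genes: tuple[str, ...]
    gained_segments: tuple[str, ...]
    children: list["EmergenceNode"] = field(default_factory=list)

    def to_newick(self) -> str:
        label = "|".join(self.genes)
        if not self.children:
            return label
        inner = ",".join(c.to_newick() for c in self.children)
        return f"({inner}){label}"

    def descendant_genes(self) -> frozenset[str]:
        out = set(self.genes)
        for c in self.children:
            out |= c.descendant_genes()
        return frozenset(out)


@dataclass
class EmergenceTree:
    root: EmergenceNode

    def to_newick(self) -> str:
        return self.root.to_newick() + ";"

    def parent_children(self) -> dict[str, frozenset[str]]:
        """For each gene, the set of genes strictly below its node."""
        out: dict[str, frozenset[str]] = {}

        def walk(node: EmergenceNode):
            below = node.descendant_genes() - set(node.genes)
            for g in node.genes:
                out[g] = below
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


class DolloInconsistencyError(ValueError):
    """Two segments have overlapping but non-nested gene sets."""


def emergence_order(matrix: SegmentMatrix) -> EmergenceTree:
    """Order paralog emergence under a Dollo (single-gain) model.

    Segments are characters gained once and never regained, so the gene
    sets carrying each segment must form a laminar family (pairwise nested
    or disjoint). Gain events nest into a tree; each gene attaches at the
    deepest event whose carrier set contains it, making its segment
    complement exactly the union of gains on its root path. Output is
    invariant to gene/segment input order (children sorted by label).
    """
    gene_sets = {s: matrix.gene_set(s) for s in matrix.segments}
    segs = [s for s in matrix.segments if gene_sets[s]]
    for i, s1 in enumerate(segs):
        for s2 in segs[i + 1 :]:
            a, b = gene_sets[s1], gene_sets[s2]
            if a & b and not (a <= b or b <= a):
                raise DolloInconsistencyError(
                    f"segments {s1!r} and {s2!r} have overlapping, non-nested "
                    f"carrier sets {sorted(a)} / {sorted(b)}: no single-gain tree exists"
                )
    # group segments by identical carrier set -> one gain event each
    events: dict[frozenset[str], list[str]] = {}
    for s in segs:
        events.setdefault(gene_sets[s], []).append(s)
    all_genes = frozenset(matrix.genes)
    if all_genes not in events:
        events[all_genes] = events.get(all_genes, [])
    carrier_sets = sorted(events, key=lambda s: (-len(s), sorted(s)))

    node_of: dict[frozenset[str], EmergenceNode] = {}
    children_of: dict[frozenset[str], list[frozenset[str]]] = {s: [] for s in carrier_sets}
    parent_of: dict[frozenset[str], frozenset[str] | None] = {}
    for s in carrier_sets:
        parent = None
        for t in carrier_sets:
            if t != s and s < t and (parent is None or t < parent):
                parent = t
        parent_of[s] = parent
        if parent is not None:
            children_of[parent].append(s)

    # place each gene at its deepest containing event
    placed: dict[frozenset[str], list[str]] = {s: [] for s in carrier_sets}
    for g in matrix.genes:
        containing = [s for s in carrier_sets if g in s]
        deepest = min(containing, key=lambda s: (len(s), sorted(s)))
        placed[deepest].append(g)

    def build(s: frozenset[str]) -> EmergenceNode:
        kids = sorted(children_of[s], key=lambda c: sorted(c))
        return EmergenceNode(
            genes=tuple(sorted(placed[s])),
            gained_segments=tuple(sorted(events[s])),
            children=[build(c) for c in kids],
        )

    return EmergenceTree(root=build(all_genes))


# ---------------------------------------------------------------------------
# Retrocopy detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetrocopyCall:
    candidate: str
    donor: str | None
    exon_count: int
    polya_run: int
    polya_distance: int  # run end to 3' end, bp
    identity: float
    verdict: bool


def _find_polya(seq: str, min_run: int, max_dist: int) -> tuple[int, int]:
    """Longest ≥90%-A run ending within ``max_dist`` of the 3' end.

    Returns (run_length, distance from run end to sequence end); (0, -1)
    when nothing qualifies. Purity rule: at most 1 non-A per 10 positions.
    """
    n = len(seq)
    lo = max(0, n - max_dist - min_run)
    best = (0, -1)
    for i in range(lo, n):
        non_a = 0
        for j in range(i, n):
            if seq[j] != "A":
                non_a += 1
            run = j - i + 1
            if non_a * 10 > run:
                break
            dist = n - (j + 1)
            if run >= min_run and dist <= max_dist and run > best[0]:
                best = (run, dist)
    return best


def _global_identity(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    matches = 0
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    return matches / aln.length


def detect_retrocopy(
    candidate: Transcript,
    candidate_seq: str,
    donors: Sequence[tuple[Transcript, str]],
    polyA_min_run: int = 10,
    polyA_max_dist: int = 200,
    identity_min: float = 0.8,
) -> RetrocopyCall:
    """Call a candidate transcript as a retrocopy of one of the donors.

    ``candidate_seq`` and the donor sequences are 5'→3' in transcript
    orientation (donor sequences are the concatenated exonic sequence).
    The verdict is true only if all three criteria hold: single exon,
    qualifying poly-A tract near the 3' end, and global identity
    ≥ ``identity_min`` with the best-matching donor (which must itself be
    multi-exonic).
    """
    if not donors:
        raise ValueError("detect_retrocopy requires at least one donor")
    for t, _ in donors:
        if t.n_exons < 2:
            raise ValueError(f"donor {t.id!r} must have >=2 exons")
    run, dist = _find_polya(candidate_seq.upper(), polyA_min_run, polyA_max_dist)
    best_donor, best_ident = None, -1.0
    for t, dseq in donors:
        ident = _global_identity(candidate_seq.upper(), dseq.upper())
        if ident > best_ident:
            best_donor, best_ident = t.id, ident
    verdict = (
        candidate.n_exons == 1 and run >= polyA_min_run and best_ident >= identity_min
    )
    return RetrocopyCall(
        candidate=candidate.id,
        donor=best_donor if verdict else best_donor,
        exon_count=candidate.n_exons,
        polya_run=run,
        polya_distance=dist,
        identity=best_ident,
        verdict=verdict,
    )
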