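"""Per-cluster consensus sequences and neighbor-joining similarity trees.

The cluster-relatedness analysis proceeds in four steps: align the unit
sequences of each cluster (:func:`kzfptools.align.progressive_align`),
collapse each alignment to a majority-rule consensus, compute pairwise
p-distances between consensuses, and build an unrooted neighbor-joining
tree. p-distance is not guaranteed to satisfy the triangle inequality;
only symmetry and the zero diagonal are asserted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, Msa, align_pair
from .intervals import SequenceRecord

logger = logging.getLogger(__name__)

AMBIGUITY = {"N", "X"}


@dataclass(frozen=True)
class ConsensusSeq:
    id: str
    residues: str


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape must match label count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label] if self.label else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def _newick(self, decimals: int) -> str:
        if self.is_leaf():
            return self.label or ""
        inner = ",".join(
            f"{c._newick(decimals)}:{bl:.{decimals}f}" for c, bl in self.children
        )
        return f"({inner}){self.label or ''}"


@dataclass
class PhyloTree:
    """An unrooted tree, stored rooted at the final join for serialisation."""

    root: TreeNode

    def to_newick(self, decimals: int = 6) -> str:
        return self.root._newick(decimals) + ";"

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()


def consensus_from_msa(
    msa: Msa, min_frac: float = 0.5, cluster_id: str = "consensus", alphabet: str = "ACGT"
) -> ConsensusSeq:
    """Majority-rule consensus of an MSA.

    Columns where gaps are the strict majority are dropped. Otherwise the
    most frequent residue is emitted when its frequency among non-gap
    characters reaches ``min_frac``; below that the column becomes ``N``.
    Frequency ties resolve to the earlier residue in ``alphabet`` order
    (unlisted residues after listed ones, alphabetically).
    """
    rows = [s for _, s in msa.rows]
    n = len(rows)
    out = []
    rank = {a: i for i, a in enumerate(alphabet)}
    for j in range(msa.n_columns):
        col = [r[j] for r in rows]
        gaps = col.count("-")
        if gaps > n - gaps:
            continue
        residues = [c for c in col if c != "-"]
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        best = min(counts, key=lambda c: (-counts[c], rank.get(c, len(rank)), c))
        if counts[best] / len(residues) >= min_frac:
            out.append(best)
        else:
            out.append("N")
    return ConsensusSeq(id=cluster_id, residues="".join(out))


def pdistance(a: str, b: str, params: AlignParams | None = None) -> float:
    """Mismatch fraction over aligned non-gap columns, N/X excluded."""
    ra, rb, _ = align_pair(a, b, params)
    comparable = mismatches = 0
    for ca, cb in zip(ra, rb):
        if ca == "-" or cb == "-" or ca in AMBIGUITY or cb in AMBIGUITY:
            continue
        comparable += 1
        if ca != cb:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable alignment columns between the pair")
    return mismatches / comparable


def pdistance_matrix(
    consensuses: list[ConsensusSeq], params: AlignParams | None = None
) -> DistanceMatrix:
    """All-pairs p-distance between consensus sequences."""
    labels = tuple(c.id for c in consensuses)
    n = len(consensuses)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = pdistance(
                    consensuses[i].residues, consensuses[j].residues, params
                )
            except ValueError as exc:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                ) from exc
    return DistanceMatrix(labels=labels, values=d)


def _clamp(bl: float, context: str) -> float:
    if bl < 0:
        logger.info("negative NJ branch length %.6g at %s clamped to 0", bl, context)
        return 0.0
    return bl


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining.

    Ties in the Q criterion break on the lexicographically smallest label
    pair; negative branch-length estimates are clamped to zero (the deficit
    is logged). The result is returned rooted at the final three-way join.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in labels}
    # mutable working copies; "active" maps working label -> sorted leaf-set
    # key used for deterministic tie-breaking
    d = {a: {b: float(matrix.values[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    tiekey = {l: (l,) for l in labels}

    active = list(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for x in range(n):
            for y in range(x + 1, n):
                a, b = active[x], active[y]
                q = (n - 2) * d[a][b] - r[a] - r[b]
                pair_key = tuple(sorted((min(tiekey[a], tiekey[b]), max(tiekey[a], tiekey[b]))))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        la = d[a][b] / 2 + (r[a] - r[b]) / (2 * (len(active) - 2))
        lb = d[a][b] - la
        parent = TreeNode(
            children=[
                (nodes[a], _clamp(la, f"join({a},{b})")),
                (nodes[b], _clamp(lb, f"join({a},{b})")),
            ]
        )
        counter += 1
        new = f"__internal_{counter}"
        nodes[new] = parent
        tiekey[new] = min(tiekey[a], tiekey[b])
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = (d[a][c] + d[b][c] - d[a][b]) / 2
            d[new][c] = dc
            d[c][new] = dc
        d[new][new] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = active
    la = (d[a][b] + d[a][c] - d[b][c]) / 2
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2
    root = TreeNode(
        children=[
            (nodes[a], _clamp(la, "final")),
            (nodes[b], _clamp(lb, "final")),
            (nodes[c], _clamp(lc, "final")),
        ]
    )
    return PhyloTree(root=root)


def cluster_consensus_tree(
    cluster_seqs: dict[str, list[SequenceRecord]],
    params: AlignParams | None = None,
    min_frac: float = 0.5,
):
    """align → consensus → p-distance → NJ over a {cluster: sequences} map.

    Returns ``(consensuses, distance_matrix, tree)``.
    """
    from .align import progressive_align

    params = params or AlignParams()
    consensuses = []
    for cid in sorted(cluster_seqs):
        seqs = cluster_seqs[cid]
        if len(seqs) == 1:
            msa = Msa(((seqs[0].id, seqs[0].residues),))
        else:
            msa = progressive_align(
                seqs,
                match=params.match,
                mismatch=params.mismatch,
                gap_open=params.gap_open,
                gap_extend=params.gap_extend,
                alphabet=params.alphabet,
            )
        consensuses.append(consensus_from_msa(msa, min_frac=min_frac, cluster_id=cid))
    dm = pdistance_matrix(consensuses, params)
    return consensuses, dm, nj_tree(dm)
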