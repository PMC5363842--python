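"""Alignment, consensus, p-distance and neighbor joining.

Small-instance oracles: exhaustive alignment-path enumeration for pairwise
scores, dendropy for tree comparison (Robinson–Foulds) and additive-matrix
cross-checks.
"""

import numpy as np
import pytest

import dendropy

from kzfptools.align import AlignParams, Msa, align_pair, guide_order, progressive_align
from kzfptools.intervals import SequenceRecord
from kzfptools.phylo import (
    ConsensusSeq,
    DistanceMatrix,
    cluster_consensus_tree,
    consensus_from_msa,
    nj_tree,
    pdistance,
    pdistance_matrix,
)


def brute_force_best_score(a, b, match, mismatch, open_, extend):
    """Enumerate every global alignment path; affine gaps, opening covers
    the first gapped column."""
    best = [-1e18]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (extend if last == "X" else open_), "X")
        if j < len(b):
            rec(i, j + 1, score + (extend if last == "Y" else open_), "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


class TestPairwiseAlignment:
    def test_identical_sequences_gap_free(self):
        ra, rb, score = align_pair("ACGTACGT", "ACGTACGT")
        assert ra == rb == "ACGTACGT"
        assert score == 8

    def test_acgt_vs_act_single_gap(self):
        ra, rb, score = align_pair("ACGT", "ACT", AlignParams(1, -1, -2, -1))
        assert score == 1
        assert ra == "ACGT" and rb in ("AC-T",)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 5)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 5)))
        params = AlignParams(1, -1, -2, -1)
        _, _, score = align_pair(a, b, params)
        assert score == pytest.approx(brute_force_best_score(a, b, 1, -1, -2, -1))

    def test_degapping_recovers_inputs(self):
        ra, rb, _ = align_pair("ACGTTTACG", "ACGACGCC")
        assert ra.replace("-", "") == "ACGTTTACG"
        assert rb.replace("-", "") == "ACGACGCC"


class TestProgressiveAlign:
    def test_single_sequence_is_one_row_msa(self):
        msa = progressive_align([SequenceRecord("a", "ACGT")])
        assert msa.rows == (("a", "ACGT"),)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([SequenceRecord("a", "ACGT"), SequenceRecord("b", "")])

    def test_structural_invariants(self):
        rng = np.random.default_rng(4)
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT"), size=rng.integers(30, 60))))
            for i in range(6)
        ]
        msa = progressive_align(seqs)
        assert msa.n_columns >= max(len(s.residues) for s in seqs)
        by_id = dict(msa.rows)
        for s in seqs:
            assert by_id[s.id].replace("-", "") == s.residues

    def test_identical_sequences_align_gap_free(self):
        seqs = [SequenceRecord(f"s{i}", "ACGTACGTAC") for i in range(4)]
        msa = progressive_align(seqs)
        assert msa.n_columns == 10
        assert all(s == "ACGTACGTAC" for _, s in msa.rows)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        seqs = [
            SequenceRecord(f"s{i}", "".join(rng.choice(list("ACGT"), size=40)))
            for i in range(5)
        ]
        assert progressive_align(seqs) == progressive_align(seqs)


class TestConsensus:
    def test_majority_vote(self):
        msa = Msa((("a", "AC"), ("b", "AC"), ("c", "AT")))
        assert consensus_from_msa(msa).residues == "AC"

    def test_tie_breaks_by_alphabet_order(self):
        msa = Msa((("a", "A"), ("b", "C")))
        assert consensus_from_msa(msa).residues == "A"

    def test_gap_majority_column_dropped(self):
        msa = Msa((("a", "A-G"), ("b", "A-G"), ("c", "ACG")))
        assert consensus_from_msa(msa).residues == "AG"

    def test_low_majority_becomes_n(self):
        msa = Msa((("a", "A"), ("b", "C"), ("c", "G"), ("d", "T")))
        assert consensus_from_msa(msa, min_frac=0.5).residues == "N"


class TestPdistance:
    def test_identical_zero(self):
        assert pdistance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_mismatch_fraction(self):
        assert pdistance("AAAA", "AAAT") == pytest.approx(0.25)

    def test_n_positions_excluded(self):
        assert pdistance("AANA", "AATA") == 0.0

    def test_no_comparable_columns_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pdistance_matrix([ConsensusSeq("a", "NNNN"), ConsensusSeq("b", "NNNN"),
                              ConsensusSeq("c", "ACGT")])

    def test_matrix_symmetry(self):
        cons = [ConsensusSeq(f"c{i}", s) for i, s in
                enumerate(["ACGTACGT", "ACGTACGA", "TCGTACGA"])]
        dm = pdistance_matrix(cons)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


def random_topology(rng, labels):
    """Random rooted binary topology as nested tuples of labels."""
    labels = list(labels)
    if len(labels) == 1:
        return labels[0]
    idx = rng.permutation(len(labels))
    cut = int(rng.integers(1, len(labels)))
    left = [labels[i] for i in idx[:cut]]
    right = [labels[i] for i in idx[cut:]]
    return (random_topology(rng, left), random_topology(rng, right))


def topology_newick(node, bl=None):
    if isinstance(node, str):
        return node if bl is None else f"{node}:{bl[node]:.6f}"
    a, b = node
    return f"({topology_newick(a, bl)},{topology_newick(b, bl)})"


def _leaf_depths(node, rng, depths, acc):
    """Assign random branch lengths; record each leaf's path from the root
    as a list of (edge id, length) for additive-distance computation."""
    if isinstance(node, str):
        depths[node] = acc
        return
    for child in node:
        length = float(rng.uniform(0.05, 1.0))
        edge = object()
        _leaf_depths(child, rng, depths, acc + ((edge, length),))


def random_additive_matrix(rng, labels):
    """Random binary tree with positive branch lengths -> additive distances."""
    topo = random_topology(rng, labels)
    paths: dict[str, tuple] = {}
    _leaf_depths(topo, rng, paths, ())
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                ea = dict(paths[a])
                eb = dict(paths[b])
                shared = set(ea) & set(eb)
                dist = sum(l for e, l in ea.items() if e not in shared)
                dist += sum(l for e, l in eb.items() if e not in shared)
                d[i, j] = d[j, i] = dist
    return topology_newick(topo) + ";", DistanceMatrix(labels=tuple(labels), values=d)


def rf_distance(newick_a, newick_b, labels):
    tns = dendropy.TaxonNamespace(labels)
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels=("A", "B", "C"), values=d))
        lengths = {c.label: bl for c, bl in tree.root.children}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)  # 1
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)  # 3
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)  # 5

    def test_four_taxon_q_criterion_by_hand(self):
        # additive matrix from tree ((A:1,B:2):1,(C:3,D:4)) with center edge 1
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(labels=("A", "B", "C", "D"), values=d))
        nw = tree.to_newick()
        assert rf_distance(nw, "((A:1,B:2):1,C:3,D:4);", ["A", "B", "C", "D"]) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        true_nwk, dm = random_additive_matrix(rng, labels)
        est = nj_tree(dm)
        assert rf_distance(est.to_newick(), true_nwk, labels) == 0
        # branch lengths: leaf-to-leaf path distances reproduce the matrix
        tns = dendropy.TaxonNamespace(labels)
        t = dendropy.Tree.get(data=est.to_newick(), schema="newick", taxon_namespace=tns)
        pdm = t.phylogenetic_distance_matrix()
        tx = {x.label: x for x in tns}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(tx[a], tx[b]) == pytest.approx(
                        dm.values[i, j], abs=1e-4
                    )

    def test_nonsymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0, 1], [2, 0]]))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=("a", "b"), values=np.zeros((2, 2))))


def mutate(seq, rate, rng):
    bases = np.array(list("ACGT"))
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = rng.choice(bases[bases != out[i]])
    return "".join(out)


def simulate_lineages(rng, n_lineages=4, seq_len=300, edge_rate=0.06, within_rate=0.01,
                      n_per_cluster=3):
    """Duplicate a root sequence along a random binary tree; return
    (cluster sequences, generating tree newick, labels)."""
    labels = [f"L{i}" for i in range(n_lineages)]
    topo = random_topology(rng, labels)
    root = "".join(rng.choice(list("ACGT"), size=seq_len))
    leaf_seqs: dict[str, str] = {}

    def evolve(node, seq):
        if isinstance(node, str):
            leaf_seqs[node] = seq
            return
        for child in node:
            evolve(child, mutate(seq, edge_rate, rng))

    evolve(topo, root)
    clusters = {
        lab: [
            SequenceRecord(f"{lab}_m{j}", mutate(leaf_seqs[lab], within_rate, rng))
            for j in range(n_per_cluster)
        ]
        for lab in labels
    }
    return clusters, topology_newick(topo) + ";", labels


class TestLineageRecovery:
    @pytest.mark.parametrize("seed", range(3))
    def test_duplication_tree_recovered(self, seed):
        """align→consensus→p-distance→NJ recovers the planted duplication
        topology when lineage divergence well exceeds within-cluster
        diversity."""
        rng = np.random.default_rng(100 + seed)
        clusters, true_nwk, labels = simulate_lineages(rng, n_lineages=5)
        _, _, est = cluster_consensus_tree(clusters)
        assert rf_distance(est.to_newick(), true_nwk, labels) == 0
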