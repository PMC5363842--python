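"""Fingerprint diversification, segment homology, emergence order, retrocopies."""

import numpy as np
import pytest

from kzfptools.fingerprint import (
    DolloInconsistencyError,
    SegmentMatrix,
    build_segment_matrix,
    detect_retrocopy,
    emergence_order,
    find_repeated_blocks,
    find_tandem_duplications,
    shared_fingerprint_blocks,
)
from kzfptools.intervals import GenomicInterval, SequenceRecord, Transcript
from kzfptools.znf import Fingerprint

T = ("AAA", "BBB", "CCC", "DDD", "EEE", "FFF")  # triplet shorthand


def fp(*triplets):
    return Fingerprint(tuple(triplets))


def random_fp(rng, n, k=4):
    return fp(*(T[rng.integers(0, k)] for _ in range(n)))


def brute_force_runs(triplets):
    runs = []
    n = len(triplets)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if all(t == triplets[i] for t in triplets[i:j]) and j - i >= 2:
                left_ok = i == 0 or triplets[i - 1] != triplets[i]
                right_ok = j == n or triplets[j] != triplets[i]
                if left_ok and right_ok:
                    runs.append((triplets[i], i, j - i))
    # keep maximal only (largest j-i per start)
    best = {}
    for t, s, c in runs:
        if s not in best or c > best[s][1]:
            best[s] = (t, c)
    return sorted((s, t, c) for s, (t, c) in best.items())


class TestTandemDuplications:
    def test_quadruple_run(self):
        runs = find_tandem_duplications(fp("QSN", "QSN", "QSN", "QSN", "RER"))
        assert len(runs) == 1
        r = runs[0]
        assert (r.triplet, r.start_index, r.copies) == ("QSN", 0, 4)

    def test_all_distinct_empty(self):
        assert find_tandem_duplications(fp(*T)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        f = random_fp(rng, int(rng.integers(0, 30)), k=3)
        got = sorted((r.start_index, r.triplet, r.copies)
                     for r in find_tandem_duplications(f))
        assert got == brute_force_runs(f.triplets)


def brute_force_occurrences(triplets, block):
    k = len(block)
    return [i for i in range(len(triplets) - k + 1) if tuple(triplets[i:i + k]) == tuple(block)]


class TestRepeatedBlocks:
    def test_simple_pair(self):
        blocks = find_repeated_blocks(fp("AAA", "BBB", "AAA", "BBB"))
        assert len(blocks) == 1
        assert blocks[0].block == ("AAA", "BBB")
        assert blocks[0].occurrences == (0, 2)

    def test_longer_blocks_consume_positions(self):
        f = fp("AAA", "BBB", "CCC", "AAA", "BBB", "CCC", "AAA", "BBB", "CCC")
        blocks = find_repeated_blocks(f)
        assert blocks[0].block == ("AAA", "BBB", "CCC")
        assert blocks[0].occurrences == (0, 3, 6)
        # no shorter block reported from consumed positions
        assert all(len(b.block) == 3 for b in blocks)

    def test_short_fingerprint_empty(self):
        assert find_repeated_blocks(fp("AAA")) == []

    def test_occurrences_verified_against_substring_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            f = random_fp(rng, int(rng.integers(2, 30)), k=3)
            for b in find_repeated_blocks(f):
                occ_all = brute_force_occurrences(f.triplets, b.block)
                assert set(b.occurrences) <= set(occ_all)
                assert len(b.occurrences) >= 2
                # reported occurrences are non-overlapping
                ends = -1
                for s in b.occurrences:
                    assert s >= ends
                    ends = s + len(b.block)


def lcs_oracle(a, b):
    """Longest common contiguous substring length by dynamic programming."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            l = 0
            while i + l < len(a) and j + l < len(b) and a[i + l] == b[j + l]:
                l += 1
            best = max(best, l)
    return best


class TestSharedBlocks:
    def test_identical_fingerprints_share_everything(self):
        f = fp("AAA", "BBB", "CCC")
        blocks = shared_fingerprint_blocks(f, f, allow_reverse=False)
        assert blocks[0].block == ("AAA", "BBB", "CCC")

    def test_reversed_sharing_flagged(self):
        f = fp("AAA", "BBB", "CCC", "DDD")
        r = fp("DDD", "CCC", "BBB", "AAA")
        blocks = shared_fingerprint_blocks(f, r, allow_reverse=True)
        full = [b for b in blocks if len(b.block) == 4]
        assert full and all(b.reversed for b in full)
        assert shared_fingerprint_blocks(f, r, allow_reverse=False, min_len=2) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_longest_block_matches_lcs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_fp(rng, int(rng.integers(2, 20)), k=3)
        b = random_fp(rng, int(rng.integers(2, 20)), k=3)
        blocks = shared_fingerprint_blocks(a, b, min_len=1, allow_reverse=False)
        got = max((len(x.block) for x in blocks), default=0)
        assert got == lcs_oracle(a.triplets, b.triplets)


class TestSegmentMatrix:
    def _regions(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=600))
        other = "".join(rng.choice(list("ACGT"), size=600))
        shared = base[100:300]
        other = other[:200] + shared + other[400:]
        return [("geneA", SequenceRecord("geneA", base)),
                ("geneB", SequenceRecord("geneB", other))]

    def test_self_match_zero_mismatches(self):
        rng = np.random.default_rng(3)
        regions = self._regions(rng)
        m = build_segment_matrix(regions, [("s1", "geneA", 100, 300)])
        assert m.present[0, 0] and m.mismatches[0, 0] == 0

    def test_shared_segment_found_in_both(self):
        rng = np.random.default_rng(3)
        regions = self._regions(rng)
        m = build_segment_matrix(regions, [("s1", "geneA", 100, 300)])
        assert m.gene_set("s1") == {"geneA", "geneB"}

    def test_unrelated_sequence_absent(self):
        rng = np.random.default_rng(4)
        regions = self._regions(rng)
        m = build_segment_matrix(regions, [("priv", "geneA", 350, 550)])
        assert m.gene_set("priv") == {"geneA"}

    def test_planted_substitutions_recovered_as_mismatches(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=500))
        seg = base[50:250]
        mutated = list(seg)
        pos = rng.choice(200, size=20, replace=False)  # 10% substitutions
        for p in pos:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        target = "".join(rng.choice(list("ACGT"), size=100)) + "".join(mutated) + \
            "".join(rng.choice(list("ACGT"), size=100))
        regions = [("src", SequenceRecord("src", base)), ("tgt", SequenceRecord("tgt", target))]
        m = build_segment_matrix(regions, [("s1", "src", 50, 250)], identity_threshold=0.8)
        assert m.present[1, 0]
        assert m.mismatches[1, 0] == 20

    def test_segment_longer_than_region_absent_not_error(self):
        regions = [("a", SequenceRecord("a", "ACGT" * 100)), ("b", SequenceRecord("b", "ACGT"))]
        m = build_segment_matrix(regions, [("s", "a", 0, 100)])
        assert not m.present[1, 0]


def seg_matrix(genes, seg_sets):
    segments = sorted({s for ss in seg_sets.values() for s in ss})
    present = np.array([[s in seg_sets[g] for s in segments] for g in genes])
    return SegmentMatrix(
        genes=tuple(genes), segments=tuple(segments), present=present,
        mismatches=np.where(present, 0.0, np.nan),
    )


class TestEmergenceOrder:
    def test_paralog_triplet_pattern(self):
        """Segments 1–5 shared by all, 6–7 by two paralogs, 8 and 9 private:
        the oldest gene roots the tree, the two younger ones are siblings."""
        m = seg_matrix(
            ["Zfp932", "Gm15446", "GmX"],
            {
                "Zfp932": {"s1", "s2", "s3", "s4", "s5"},
                "Gm15446": {"s1", "s2", "s3", "s4", "s5", "s6", "s7", "s8"},
                "GmX": {"s1", "s2", "s3", "s4", "s5", "s6", "s7", "s9"},
            },
        )
        tree = emergence_order(m)
        assert tree.root.genes == ("Zfp932",)
        (child,) = tree.root.children
        assert child.genes == ()
        assert {tuple(c.genes) for c in child.children} == {("Gm15446",), ("GmX",)}
        assert tree.to_newick() == "((Gm15446,GmX))Zfp932;"

    def test_single_gene(self):
        m = seg_matrix(["only"], {"only": {"s1"}})
        tree = emergence_order(m)
        assert tree.root.genes == ("only",) and tree.root.children == []

    def test_inconsistent_pattern_rejected_with_pair_named(self):
        m = seg_matrix(
            ["a", "b", "c"],
            {"a": {"s1"}, "b": {"s1", "s2"}, "c": {"s2"}},
        )
        with pytest.raises(DolloInconsistencyError, match="s1.*s2"):
            emergence_order(m)

    def test_input_order_invariance(self):
        sets = {
            "g1": {"s1"},
            "g2": {"s1", "s2"},
            "g3": {"s1", "s2", "s3"},
            "g4": {"s1", "s4"},
        }
        t1 = emergence_order(seg_matrix(["g1", "g2", "g3", "g4"], sets))
        t2 = emergence_order(seg_matrix(["g4", "g2", "g1", "g3"], sets))
        assert t1.to_newick() == t2.to_newick()

    @pytest.mark.parametrize("seed", range(10))
    def test_random_single_gain_simulations_recovered(self, seed):
        """Segments gained along a random gene genealogy are re-ordered into
        the generating ancestry."""
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(3, 7))
        genes = [f"g{i}" for i in range(n_genes)]
        parent = {genes[0]: None}
        seg_sets = {genes[0]: {"root_seg"}}
        counter = 0
        for g in genes[1:]:
            p = genes[int(rng.integers(0, genes.index(g)))]
            parent[g] = p
            counter += 1
            seg_sets[g] = set(seg_sets[p]) | {f"seg{counter}"}
        tree = emergence_order(seg_matrix(genes, seg_sets))
        below = tree.parent_children()
        for g in genes:
            expected = {h for h in genes if h != g and _is_ancestor(g, h, parent)}
            assert below[g] == expected


def _is_ancestor(anc, node, parent):
    p = parent[node]
    while p is not None:
        if p == anc:
            return True
        p = parent[p]
    return False


def _transcript(chrom, start, end, strand, exon_bounds, tid):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    if strand == "-":
        exons = exons[::-1]
    return Transcript(
        interval=GenomicInterval(chrom, start, end, strand), exons=tuple(exons), id=tid
    )


class TestDetectRetrocopy:
    def _fixture(self, rng):
        exon1 = "".join(rng.choice(list("ACGT"), size=300))
        exon2 = "".join(rng.choice(list("ACGT"), size=400))
        donor = _transcript("chr1", 0, 900, "+", [(0, 300), (500, 900)], "donor")
        donor_exonic = exon1 + exon2
        cand_seq = donor_exonic + "A" * 16
        cand = _transcript("chr2", 0, len(cand_seq), "+", [(0, len(cand_seq))], "cand")
        return donor, donor_exonic, cand, cand_seq

    def test_planted_retrocopy_called_with_true_donor(self):
        rng = np.random.default_rng(0)
        donor, donor_exonic, cand, cand_seq = self._fixture(rng)
        call = detect_retrocopy(cand, cand_seq, [(donor, donor_exonic)])
        assert call.verdict and call.donor == "donor"
        assert call.polya_run >= 16

    def test_donor_itself_rejected_by_intron_criterion(self):
        rng = np.random.default_rng(1)
        donor, donor_exonic, _, _ = self._fixture(rng)
        call = detect_retrocopy(donor, donor_exonic + "A" * 16, [(donor, donor_exonic)])
        assert not call.verdict and call.exon_count == 2

    def test_each_criterion_individually_necessary(self):
        rng = np.random.default_rng(2)
        donor, donor_exonic, cand, cand_seq = self._fixture(rng)
        # no poly-A run
        no_tail = detect_retrocopy(cand, donor_exonic + "CGTT" * 4, [(donor, donor_exonic)])
        assert not no_tail.verdict and no_tail.polya_run < 10
        # poly-A but unrelated sequence
        unrelated = "".join(rng.choice(list("CGT"), size=700)) + "A" * 16
        bad_id = detect_retrocopy(cand, unrelated, [(donor, donor_exonic)])
        assert not bad_id.verdict and bad_id.identity < 0.8

    def test_polya_purity_allows_one_non_a_per_ten(self):
        rng = np.random.default_rng(3)
        donor, donor_exonic, cand, _ = self._fixture(rng)
        tail = "AAAAAAAAAG" * 2  # 20 bp, 10% non-A
        call = detect_retrocopy(cand, donor_exonic + tail, [(donor, donor_exonic)])
        assert call.verdict

    def test_empty_donor_list_error(self):
        rng = np.random.default_rng(4)
        _, _, cand, cand_seq = self._fixture(rng)
        with pytest.raises(ValueError):
            detect_retrocopy(cand, cand_seq, [])

    def test_synthetic_genome_retrocopies_recovered(self, clean_config, clean_genome):
        from kzfptools.simulate import truth_transcripts

        _, _, _, truth, genome = clean_genome
        donors, candidates = truth_transcripts(clean_config, truth, genome)
        truth_names = set(truth.of_kind("retrocopy")["name"])
        called = set()
        for t, seq in candidates:
            call = detect_retrocopy(t, seq, donors)
            if call.verdict:
                called.add(call.candidate)
                assert truth.of_kind("retrocopy").set_index("name").loc[
                    call.candidate, "donor"
                ] == call.donor
        assert called == truth_names  # sensitivity 1, no paralog false positives
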