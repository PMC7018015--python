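import itertools

import numpy as np
import pytest

from specdelim import conspecificity_matrix, extract_blocks, order_by_upgma
from specdelim.conspecificity import ConspecificityMatrix
from specdelim.haploweb import FFRPartition


def make_ffr(locus, groups, unassigned=()):
    return FFRPartition(
        locus,
        [set(g) for g in groups],
        [set() for _ in groups],
        [],
        set(unassigned),
    )


def brute_force_upgma_heights(d):
    """Average-linkage agglomeration, recomputed from the raw matrix."""
    clusters = [[i] for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            vals = [d[i][j] for i in clusters[a] for j in clusters[b]]
            avg = sum(vals) / len(vals)
            if best is None or avg < best[0]:
                best = (avg, a, b)
        avg, a, b = best
        heights.append(avg)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestScores:
    def test_full_sharing_gives_locus_count(self):
        ffrs = [make_ffr(f"L{k}", [{"a", "b", "c"}]) for k in range(21)]
        m = conspecificity_matrix(ffrs)
        off = m.scores[~np.eye(3, dtype=bool)]
        assert (off == 21).all()

    def test_chain_example_hand_counts(self):
        ffrs = [
            make_ffr("L1", [{"i1", "i2"}, {"i3"}]),
            make_ffr("L2", [{"i1"}, {"i2", "i3"}]),
            make_ffr("L3", [{"i1", "i2"}, {"i3"}]),
        ]
        m = conspecificity_matrix(ffrs)
        idx = {ind: k for k, ind in enumerate(m.ids)}
        assert m.scores[idx["i1"], idx["i2"]] == 2
        assert m.scores[idx["i2"], idx["i3"]] == 1
        assert m.scores[idx["i1"], idx["i3"]] == 0

    def test_unassigned_pairs_not_scorable(self):
        ffrs = [
            make_ffr("L1", [{"i1", "i2"}], unassigned={"i3"}),
            make_ffr("L2", [{"i1", "i2", "i3"}]),
        ]
        m = conspecificity_matrix(ffrs)
        idx = {ind: k for k, ind in enumerate(m.ids)}
        assert m.n_scorable[idx["i1"], idx["i3"]] == 1
        assert m.scores[idx["i1"], idx["i3"]] == 1
        assert m.n_scorable[idx["i1"], idx["i2"]] == 2

    def test_duplicate_individual_rejected(self):
        with pytest.raises(ValueError, match="more than one FFR"):
            conspecificity_matrix([make_ffr("L1", [{"a"}, {"a", "b"}])])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            conspecificity_matrix([])

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        inds = [f"i{k}" for k in range(8)]
        ffrs = []
        for l in range(6):
            labels = rng.integers(0, 3, size=8)
            groups = [
                {ind for ind, lab in zip(inds, labels) if lab == g}
                for g in range(3)
            ]
            ffrs.append(make_ffr(f"L{l}", [g for g in groups if g]))
        m = conspecificity_matrix(ffrs)
        assert (m.scores == m.scores.T).all()
        assert (m.scores <= m.n_scorable).all()
        assert (m.n_scorable <= len(ffrs)).all()


class TestUPGMA:
    def test_perfect_blocks_contiguous_in_order(self):
        groups = [{"a1", "a2", "a3"}, {"b1", "b2"}]
        ffrs = [make_ffr(f"L{k}", groups) for k in range(5)]
        m = conspecificity_matrix(ffrs)
        order, _ = order_by_upgma(m)
        labels = [i[0] for i in order]
        # block members are adjacent
        assert labels in (["a"] * 3 + ["b"] * 2, ["b"] * 2 + ["a"] * 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_bruteforce_average_linkage(self, seed):
        # continuous scores: tie-free, so the agglomeration order (and hence
        # the height multiset) is uniquely defined
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        scores = rng.random((n, n)) * 10
        scores = np.triu(scores, 1)
        scores = scores + scores.T
        m = ConspecificityMatrix([f"i{k}" for k in range(n)], scores,
                                 np.full((n, n), 10), 10)
        _, linkage = order_by_upgma(m)
        d = 10 - scores
        np.fill_diagonal(d, 0)
        expected = brute_force_upgma_heights(d.tolist())
        got = sorted(linkage[:, 2])
        assert np.allclose(got, expected)

    def test_single_individual_trivial(self):
        m = ConspecificityMatrix(["solo"], np.zeros((1, 1), int),
                                 np.zeros((1, 1), int), 5)
        order, linkage = order_by_upgma(m)
        assert order == ["solo"]
        assert linkage is None


class TestExtractBlocks:
    def test_perfect_three_blocks_recovered(self, clean_sim):
        from specdelim import fields_for_recombination

        _, dataset, truth = clean_sim
        ffrs = [fields_for_recombination(dataset, n) for n in dataset.locus_names]
        m = conspecificity_matrix(ffrs)
        blocks = extract_blocks(m, min_score_fraction=0.5)
        got = sorted(sorted(g) for g in blocks.groups().values())
        expected = sorted(sorted(truth.members(t)) for t in truth.taxa)
        assert got == expected

    def test_uniform_matrix_single_block(self):
        ffrs = [make_ffr(f"L{k}", [{"a", "b", "c", "d"}]) for k in range(4)]
        m = conspecificity_matrix(ffrs)
        blocks = extract_blocks(m, min_score_fraction=0.5)
        assert len(blocks.taxa) == 1

    def test_threshold_one_on_noisy_matrix_oversplits(self):
        rng = np.random.default_rng(1)
        inds = [f"i{k}" for k in range(6)]
        ffrs = []
        for l in range(8):
            labels = rng.integers(0, 2, size=6)
            groups = [
                {i for i, lab in zip(inds, labels) if lab == g} for g in range(2)
            ]
            ffrs.append(make_ffr(f"L{l}", [g for g in groups if g]))
        m = conspecificity_matrix(ffrs)
        few = extract_blocks(m, min_score_fraction=0.5)
        many = extract_blocks(m, min_score_fraction=1.0)
        assert len(many.taxa) >= len(few.taxa)

    def test_threshold_validation(self):
        m = ConspecificityMatrix(["a", "b"], np.zeros((2, 2), int),
                                 np.zeros((2, 2), int), 1)
        with pytest.raises(ValueError, match="min_score_fraction"):
            extract_blocks(m, min_score_fraction=0.0)
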