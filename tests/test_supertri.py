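import itertools

import numpy as np
import pytest

from specdelim import (
    BipartitionTable,
    MRPMatrix,
    build_mrp,
    node_support,
    parse_bipartitions,
    supertree_bootstrap,
)
from specdelim.supertri import (
    enumerate_unrooted_trees,
    parsimony_length,
    search_best_tree,
    tree_bipartitions_mrp,
    tree_to_newick,
    write_bipartitions,
)

TAXA5 = ["t1", "t2", "t3", "t4", "t5"]


class TestBipartitionTable:
    def test_canonicalised_to_side_without_first_taxon(self):
        t = BipartitionTable("L1", TAXA5, {frozenset(["t1", "t2"]): 0.8})
        assert frozenset(["t3", "t4", "t5"]) in t.entries
        # listed from the other side: same canonical entry
        t2 = BipartitionTable("L1", TAXA5, {frozenset(["t3", "t4", "t5"]): 0.8})
        assert t.entries == t2.entries

    def test_pp_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="PP"):
            BipartitionTable("L1", TAXA5, {frozenset(["t2", "t3"]): 1.2})

    def test_tsv_roundtrip(self, tmp_path):
        t = BipartitionTable(
            "L1", TAXA5,
            {frozenset(["t2", "t3"]): 0.6, frozenset(["t4", "t5"]): 0.97},
        )
        p = tmp_path / "L1.tsv"
        write_bipartitions(t, p)
        back = parse_bipartitions(p)
        assert back.entries == t.entries
        assert back.taxa == t.taxa

    def test_unknown_taxon_rejected(self, tmp_path):
        p = tmp_path / "L1.tsv"
        p.write_text("#taxa: t1,t2,t3\nt2,zz\t0.5\n")
        with pytest.raises(ValueError, match="unknown"):
            parse_bipartitions(p)

    def test_mrbayes_dialect(self, tmp_path):
        parts = tmp_path / "L1.parts"
        parts.write_text("ID -- Partition\n1 -- .**..\n2 -- ...**\n")
        tstat = tmp_path / "L1.tstat"
        tstat.write_text("ID\t#obs\tProbab.\n1\t900\t0.9\n2\t50\t0.05\n")
        t = parse_bipartitions(parts, dialect="mrbayes", taxa=TAXA5)
        assert t.pp({"t2", "t3"}) == pytest.approx(0.9)
        assert t.pp({"t4", "t5"}) == pytest.approx(0.05)


class TestMRP:
    def test_single_certain_bipartition(self):
        t = BipartitionTable("L1", TAXA5, {frozenset(["t2", "t3"]): 1.0})
        mrp = build_mrp([t])
        assert mrp.n_characters == 1
        assert mrp.weights.tolist() == [100]

    def test_per_locus_characters_kept_separate(self):
        side = frozenset(["t2", "t3"])
        t1 = BipartitionTable("L1", TAXA5, {side: 0.6})
        t2 = BipartitionTable("L2", TAXA5, {side: 0.4})
        mrp = build_mrp([t1, t2])
        assert mrp.n_characters == 2
        assert sorted(mrp.weights.tolist()) == [40, 60]

    def test_round_half_up_weighting(self):
        t = BipartitionTable("L1", TAXA5, {frozenset(["t2", "t3"]): 0.975})
        assert build_mrp([t]).weights.tolist() == [98]

    def test_character_count_equals_sum_of_table_sizes(self):
        rng = np.random.default_rng(2)
        tables = []
        for l in range(21):
            entries = {}
            for _ in range(int(rng.integers(1, 6))):
                k = int(rng.integers(2, 4))
                side = frozenset(rng.choice(TAXA5, size=k, replace=False))
                if 0 < len(side) < 5:
                    entries[side] = float(rng.random())
            tables.append(BipartitionTable(f"L{l}", TAXA5, entries))
        mrp = build_mrp(tables)
        assert mrp.n_characters == sum(len(t.entries) for t in tables)

    def test_absent_taxa_coded_missing(self):
        t1 = BipartitionTable("L1", ["t1", "t2", "t3", "t4"],
                              {frozenset(["t3", "t4"]): 1.0})
        t2 = BipartitionTable("L2", TAXA5, {frozenset(["t4", "t5"]): 1.0})
        mrp = build_mrp([t1, t2])
        col_t5 = mrp.taxa.index("t5")
        assert mrp.cells[0, col_t5] == -1


class TestNodeSupport:
    def test_unanimous_node(self):
        side = {"t2", "t3"}
        tables = [
            BipartitionTable(f"L{k}", TAXA5, {frozenset(side): 1.0})
            for k in range(21)
        ]
        (ns,) = node_support(tables, [side])
        assert ns.MPP == pytest.approx(1.0)
        assert ns.NRep == 21
        assert ns.Rep == pytest.approx(1.0)

    def test_rare_weak_node_mpp_and_nrep(self):
        # present in 1 of 21 loci at PP=0.03: MPP = 0.03/21, NRep = 1
        tables = [BipartitionTable(f"L{k}", TAXA5, {}) for k in range(21)]
        tables[4] = BipartitionTable("L4", TAXA5, {frozenset(["t2", "t3"]): 0.03})
        (ns,) = node_support(tables, [{"t2", "t3"}])
        assert ns.MPP == pytest.approx(0.03 / 21)
        assert round(ns.MPP, 2) == 0.0
        assert ns.NRep == 1
        assert not ns.passes()["MPP_pass"]
        assert not ns.passes()["NRep_pass"]

    def test_mean_over_loci(self):
        tables = [
            BipartitionTable("L1", TAXA5, {frozenset(["t2", "t3"]): 0.5}),
            BipartitionTable("L2", TAXA5, {frozenset(["t2", "t3"]): 0.5}),
        ]
        (ns,) = node_support(tables, [{"t2", "t3"}])
        assert ns.MPP == pytest.approx(0.5)
        assert ns.NRep == 2

    def test_locus_order_invariance(self):
        t1 = BipartitionTable("L1", TAXA5, {frozenset(["t2", "t3"]): 0.7})
        t2 = BipartitionTable("L2", TAXA5, {frozenset(["t2", "t4"]): 0.2})
        a = node_support([t1, t2], [{"t2", "t3"}])[0]
        b = node_support([t2, t1], [{"t2", "t3"}])[0]
        assert (a.MPP, a.NRep) == (b.MPP, b.NRep)


class TestParsimony:
    def brute_force_length(self, adj, cells, weights, n_taxa):
        """Oracle: minimise changes over all assignments of states to
        internal nodes ('?' leaves are free to take either state)."""
        internal = [n for n in adj if n >= n_taxa]
        edges = {frozenset((u, v)) for u in adj for v in adj[u]}
        total = 0
        for ci in range(cells.shape[0]):
            leaf_states = cells[ci]
            free = [t for t in range(n_taxa) if leaf_states[t] < 0] + internal
            fixed = {t: int(leaf_states[t]) for t in range(n_taxa) if leaf_states[t] >= 0}
            best = None
            for assign in itertools.product([0, 1], repeat=len(free)):
                st = dict(fixed)
                st.update(zip(free, assign))
                cost = sum(1 for e in edges for (u, v) in [tuple(e)] if st[u] != st[v])
                best = cost if best is None else min(best, cost)
            total += best * weights[ci]
        return int(total)

    def test_fitch_length_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        n = 5
        for trial in range(5):
            cells = rng.integers(-1, 2, size=(4, n)).astype(np.int8)
            weights = rng.integers(1, 5, size=4)
            adj = next(enumerate_unrooted_trees(n))
            got = parsimony_length(adj, cells, weights)
            expected = self.brute_force_length(adj, cells, weights, n)
            assert got == expected

    def test_enumeration_counts(self):
        assert sum(1 for _ in enumerate_unrooted_trees(4)) == 3
        assert sum(1 for _ in enumerate_unrooted_trees(5)) == 15
        assert sum(1 for _ in enumerate_unrooted_trees(6)) == 105

    @pytest.mark.parametrize("seed", range(10))
    def test_heuristic_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 7))
        n_chars = int(rng.integers(5, 15))
        cells = rng.integers(0, 2, size=(n_chars, n)).astype(np.int8)
        cells[rng.random(cells.shape) < 0.1] = -1
        weights = rng.integers(1, 100, size=n_chars)
        mrp = MRPMatrix([f"x{i}" for i in range(n)],
                        [("L", frozenset())] * n_chars, weights, cells)
        exhaustive = min(
            parsimony_length(adj, cells, weights)
            for adj in enumerate_unrooted_trees(n)
        )
        _, best = search_best_tree(mrp, seed=seed)
        assert best == exhaustive


class TestSupertreeBootstrap:
    def test_fully_resolved_certain_input_gets_sbp_100(self):
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        # one locus, fully resolved caterpillar, all PP = 1.0
        entries = {
            frozenset(["t1", "t2"]): 1.0,
            frozenset(["t1", "t2", "t3"]): 1.0,
        }
        mrp = build_mrp([BipartitionTable("L1", taxa, entries)])
        sbp, best = supertree_bootstrap(mrp, replicates=30, seed=0)
        for side in entries:
            from specdelim._seq import canonical_bipartition

            canon = canonical_bipartition(side, set(taxa))
            assert sbp[canon] == pytest.approx(100.0)
            assert canon in best

    def test_majority_signal_wins(self):
        taxa = ["t1", "t2", "t3", "t4"]
        x = frozenset(["t1", "t2"])  # == {t3,t4} side
        y = frozenset(["t1", "t3"])  # incompatible split
        tables = [
            BipartitionTable("L1", taxa, {x: 1.0}),
            BipartitionTable("L2", taxa, {x: 1.0}),
            BipartitionTable("L3", taxa, {y: 1.0}),
        ]
        sbp, _ = supertree_bootstrap(build_mrp(tables), replicates=60, seed=1)
        from specdelim._seq import canonical_bipartition

        cx = canonical_bipartition(x, set(taxa))
        cy = canonical_bipartition(y, set(taxa))
        assert sbp.get(cx, 0) > sbp.get(cy, 0)

    def test_deterministic_under_seed_and_weight_scaling(self):
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        rng = np.random.default_rng(4)
        entries = {
            frozenset(["t1", "t2"]): 0.7,
            frozenset(["t4", "t5"]): 0.6,
            frozenset(["t1", "t3"]): 0.3,
        }
        tables = [BipartitionTable("L1", taxa, entries)]
        m1 = build_mrp(tables, weight_scale=100)
        m2 = build_mrp(tables, weight_scale=1000)
        s1a, _ = supertree_bootstrap(m1, replicates=25, seed=9)
        s1b, _ = supertree_bootstrap(m1, replicates=25, seed=9)
        assert s1a == s1b
        s2, _ = supertree_bootstrap(m2, replicates=25, seed=9)
        assert set(s1a) == set(s2)

    def test_too_few_taxa_rejected(self):
        t = BipartitionTable("L1", ["t1", "t2", "t3"], {frozenset(["t2", "t3"]): 1.0})
        with pytest.raises(ValueError, match="at least 4"):
            supertree_bootstrap(build_mrp([t]), replicates=5, seed=0)

    def test_newick_export_contains_all_taxa(self):
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        mrp = build_mrp(
            [BipartitionTable("L1", taxa, {frozenset(["t1", "t2"]): 1.0})]
        )
        adj, _ = search_best_tree(mrp, seed=0)
        nwk = tree_to_newick(adj, taxa)
        for t in taxa:
            assert t in nwk
        assert nwk.endswith(";")
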