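import itertools

import networkx as nx
import numpy as np
import pytest

from specdelim import TaxonomyHypothesis, median_joining, min_intergroup_steps
from specdelim.alignment_io import HaplotypeTable
from specdelim.mjnetwork import _mst_cost, hamming


def make_table(seqs, members=None):
    haps = {f"H{i+1}": s for i, s in enumerate(seqs)}
    membership = members or {f"H{i+1}": [f"m{i+1}"] for i in range(len(seqs))}
    return HaplotypeTable("x", haps, membership)


def steiner_oracle(seqs):
    """Exhaustive minimum spanning cost allowing Steiner points drawn from
    the per-column observed states (up to n-2 of them)."""
    cols = list(zip(*seqs))
    candidates = [
        "".join(p)
        for p in itertools.product(*[sorted(set(c)) for c in cols])
    ]
    candidates = [c for c in candidates if c not in seqs]
    best = _mst_cost(list(seqs))
    for k in range(1, max(2, len(seqs) - 1)):
        for combo in itertools.combinations(candidates, k):
            best = min(best, _mst_cost(list(seqs) + list(combo)))
    return best


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        net = median_joining(make_table(["AAAA", "AGGA"]))
        assert net.graph.number_of_edges() == 1
        ((u, v, w),) = net.edge_list()
        assert w == 2

    def test_star_data_no_medians(self):
        centre = "AAAA"
        leaves = ["CAAA", "AGAA", "AACA", "AAAG"]
        net = median_joining(make_table([centre] + leaves))
        assert net.median_nodes == []
        assert net.graph.degree["H1"] == 4

    def test_treelike_data_is_pure_mst(self):
        # sequential one-step chain: perfectly tree-like
        seqs = ["AAAA", "GAAA", "GCAA", "GCTA"]
        net = median_joining(make_table(seqs))
        assert net.median_nodes == []
        assert net.graph.number_of_edges() == 3
        assert net.cost() == 3

    def test_edge_weights_equal_hamming_distance(self):
        seqs = ["AAAA", "AGGA", "TTAA"]
        net = median_joining(make_table(seqs))
        node_seq = net.sequences()
        for u, v, w in net.edge_list():
            assert w == hamming(node_seq[u], node_seq[v])

    def test_network_connected_and_contains_all_observed(self):
        seqs = ["AAAAA", "GGAAA", "GGTTA", "AATTA"]
        net = median_joining(make_table(seqs))
        assert nx.is_connected(net.graph)
        assert set(net.observed_nodes) == {"H1", "H2", "H3", "H4"}

    @pytest.mark.parametrize("seed", range(8))
    def test_cost_matches_exhaustive_steiner_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 5))
        length = int(rng.integers(3, 6))
        seqs = []
        while len(seqs) < n:
            s = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
            if s not in seqs:
                seqs.append(s)
        net = median_joining(make_table(seqs))
        assert net.cost() == steiner_oracle(seqs)

    def test_gap_missing_columns_removed(self):
        net = median_joining(make_table(["A-GT", "ANGA"]))
        ((_, _, w),) = net.edge_list()
        assert w == 1  # only columns 1 and 4 retained, one difference

    def test_bad_state_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            median_joining(make_table(["ARGT", "ACGT"]))

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            median_joining(make_table(["ACGT"]))


class TestMinIntergroupSteps:
    def test_adjacent_groups_share_edge_weight(self):
        table = make_table(
            ["AAAA", "AGGA"], members={"H1": ["x1_A"], "H2": ["y1_A"]}
        )
        net = median_joining(table)
        hyp = TaxonomyHypothesis("h", {"x1": "X", "y1": "Y"})
        steps = min_intergroup_steps(net, hyp)
        assert steps[("X", "Y")] == 2

    def test_path_through_median_sums_weights(self):
        # three mutually distant haplotypes connected through one median
        seqs = ["AAGG", "GGGG", "AATT"]
        table = make_table(seqs, members={"H1": ["x_A"], "H2": ["y_A"], "H3": ["z_A"]})
        net = median_joining(table)
        hyp = TaxonomyHypothesis("h", {"x": "X", "y": "Y", "z": "Z"})
        steps = min_intergroup_steps(net, hyp)
        for (a, b), val in steps.items():
            assert val >= 2

    def test_matches_brute_force_shortest_path(self):
        rng = np.random.default_rng(3)
        seqs = []
        while len(seqs) < 5:
            s = "".join("ACGT"[b] for b in rng.integers(0, 4, size=5))
            if s not in seqs:
                seqs.append(s)
        members = {f"H{i+1}": [f"m{i+1}_A"] for i in range(5)}
        net = median_joining(make_table(seqs, members=members))
        hyp = TaxonomyHypothesis(
            "h", {"m1": "G1", "m2": "G1", "m3": "G2", "m4": "G2", "m5": "G3"}
        )
        steps = min_intergroup_steps(net, hyp)
        # oracle: networkx-independent Floyd-Warshall over the edge list
        nodes = list(net.graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        big = 10**9
        d = [[0 if i == j else big for j in nodes] for i in nodes]
        for u, v, w in net.edge_list():
            d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = min(d[idx[u]][idx[v]], w)
        for k in range(len(nodes)):
            for i in range(len(nodes)):
                for j in range(len(nodes)):
                    d[i][j] = min(d[i][j], d[i][k] + d[k][j])
        groups = {}
        for node, data in net.graph.nodes(data=True):
            for m in data["members"]:
                groups.setdefault(hyp.assignment[m[:-2]], set()).add(node)
        for (a, b), val in steps.items():
            oracle = min(
                d[idx[u]][idx[v]] for u in groups[a] for v in groups[b]
            )
            assert val == oracle

    def test_group_without_haplotype_errors(self):
        table = make_table(["AAAA", "AGGA"], members={"H1": ["x_A"], "H2": ["y_A"]})
        net = median_joining(table)
        hyp = TaxonomyHypothesis("h", {"x": "X", "y": "Y", "ghost": "Z"})
        with pytest.raises(ValueError, match="no haplotype"):
            min_intergroup_steps(net, hyp)
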