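"""Median-joining haplotype networks and inter-group mutation counts.

The construction follows the Bandelt median-joining scheme: connect
observed haplotypes through a minimum-spanning network (tolerance epsilon),
propose consensus (quasi-median) vectors for triplets of sequence types,
keep those that lower the cost of connecting everything, iterate to a
fixed point, and finally discard median vectors that no longer help.
Edge weights are Hamming distances (mutational steps) over the retained
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import networkx as nx
import numpy as np

from .alignment_io import HaplotypeTable
from .hypothesis import TaxonomyHypothesis

__all__ = ["HaplotypeNetwork", "median_joining", "min_intergroup_steps"]

_DNA = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class HaplotypeNetwork:
    """Observed haplotypes plus inferred median vectors.

    `graph` nodes carry attributes ``seq``, ``observed`` (bool) and
    ``members`` (original sequence ids; empty for medians); edges carry
    ``weight`` = Hamming distance between their endpoint sequences.
    """

    graph: nx.Graph

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    def sequences(self) -> dict[str, str]:
        return {n: d["seq"] for n, d in self.graph.nodes(data=True)}

    def cost(self) -> int:
        """Cost of connecting every node: total weight of a minimum spanning
        tree over the final node set (observed + retained medians)."""
        return _mst_cost(list(self.sequences().values()))

    def edge_list(self):
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


def _encode(seqs: list[str]) -> np.ndarray:
    return np.vstack([np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs])


def _pairwise_hamming(arr: np.ndarray) -> np.ndarray:
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=-1)


def _prim_cost(d: np.ndarray) -> int:
    """Minimum-spanning-tree cost of a complete graph given its distance
    matrix (Prim's algorithm)."""
    n = d.shape[0]
    if n <= 1:
        return 0
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = d[0].astype(np.int64).copy()
    total = 0
    for _ in range(n - 1):
        best_masked = np.where(in_tree, np.iinfo(np.int64).max, best)
        k = int(best_masked.argmin())
        total += int(best[k])
        in_tree[k] = True
        best = np.minimum(best, d[k])
    return total


def _mst_cost(seqs: list[str]) -> int:
    if len(seqs) <= 1:
        return 0
    return _prim_cost(_pairwise_hamming(_encode(seqs)))


def _quasi_medians(u: str, v: str, w: str, cap: int = 81) -> list[str]:
    """Consensus vectors of a triplet: majority state per site; where all
    three states differ, branch over the observed states (capped)."""
    options: list[tuple[str, ...]] = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append((a, b, c))
    n_combos = 1
    for opt in options:
        n_combos *= len(opt)
        if n_combos > cap:
            # too many unresolved sites: fall back to the first-state resolution
            options = [opt[:1] for opt in options]
            break
    return ["".join(ch) for ch in product(*options)]


def _msn_edges(seqs: dict[str, str], epsilon: int) -> list[tuple[str, str, int]]:
    """Minimum-spanning-network edges: every pair whose distance is within
    `epsilon` of the level at which its endpoints first become connected
    (the minimax path distance)."""
    ids = list(seqs)
    n = len(ids)
    d = {}
    for i, j in combinations(range(n), 2):
        d[i, j] = hamming(seqs[ids[i]], seqs[ids[j]])
    # Kruskal MST, then minimax distances along it
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (i, j), w in sorted(d.items(), key=lambda kv: kv[1]):
        if not nx.has_path(g, i, j):
            g.add_edge(i, j, weight=w)
    # minimax distance: max edge weight on the unique MST path
    edges = []
    for i, j in combinations(range(n), 2):
        path = nx.shortest_path(g, i, j)
        mm = max(g[a][b]["weight"] for a, b in zip(path, path[1:]))
        if d[i, j] <= mm + epsilon:
            edges.append((ids[i], ids[j], d[i, j]))
    return edges


def median_joining(table: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Build a median-joining network from collapsed haplotypes.

    Gap/missing columns are removed before construction (they carry no
    mutational-step information); any residue outside {A,C,G,T,-,N} raises.
    Requires at least 2 haplotypes.
    """
    if table.n_haplotypes < 2:
        raise ValueError("median joining needs at least 2 haplotypes")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    raw = dict(table.haplotypes)
    bad = set("".join(raw.values())) - (_DNA | {"-", "N"})
    if bad:
        raise ValueError(f"non-nucleotide states in haplotypes: {sorted(bad)}")
    length = len(next(iter(raw.values())))
    keep = [
        c for c in range(length) if all(s[c] in _DNA for s in raw.values())
    ]
    seqs = {h: "".join(s[c] for c in keep) for h, s in raw.items()}

    observed = dict(seqs)

    # Median-vector search: starting from the observed sequence types,
    # repeatedly add quasi-medians (triplet consensus vectors) that lower
    # the cost of spanning all types. Ties between equally good medians and
    # cost-neutral medians that only pay off in combination are explored by
    # a bounded branching search (medians often come in pairs); when the
    # evaluation budget runs out the search degrades to plain greedy, which
    # matters only for large inputs.
    max_medians = max(32, 4 * len(observed))
    # deep tie/neutral branching is affordable (and matters most) on small
    # inputs; large inputs get a leaner budget and near-greedy behaviour
    budget = [20000 if len(observed) <= 12 else 2000]
    best_state: list[tuple[int, tuple[str, ...]]] = [
        (_mst_cost(list(observed.values())), tuple(observed.values()))
    ]
    visited: set[frozenset[str]] = set()

    def candidates_of(values: tuple[str, ...]) -> list[str]:
        have = set(values)
        out: dict[str, None] = {}
        for i, j, k in combinations(range(len(values)), 3):
            for m in _quasi_medians(values[i], values[j], values[k]):
                if m not in have:
                    out.setdefault(m)
        return list(out)

    def explore(values: tuple[str, ...], cost: int, neutral_left: int) -> None:
        key = frozenset(values)
        if key in visited or budget[0] <= 0:
            return
        visited.add(key)
        if cost < best_state[0][0]:
            best_state[0] = (cost, values)
        if len(values) - len(observed) >= max_medians:
            return
        arr = _encode(list(values))
        d = _pairwise_hamming(arr)
        scored = []
        for m in candidates_of(values):
            if budget[0] <= 0:
                break
            budget[0] -= 1
            dm = (arr != _encode([m])[0]).sum(axis=1)
            n = d.shape[0]
            d2 = np.zeros((n + 1, n + 1), dtype=d.dtype)
            d2[:n, :n] = d
            d2[n, :n] = dm
            d2[:n, n] = dm
            scored.append((_prim_cost(d2), m))
        if not scored:
            return
        scored.sort(key=lambda t: (t[0], t[1]))
        best_cost = scored[0][0]
        if best_cost < cost:
            # branch over all tied best improvements
            for c, m in scored:
                if c > best_cost:
                    break
                explore(values + (m,), c, neutral_left)
        elif best_cost == cost and neutral_left > 0:
            # speculative neutral additions: a median may pay off only once
            # its partner is present
            for c, m in scored:
                if c > cost:
                    break
                explore(values + (m,), c, neutral_left - 1)

    explore(tuple(observed.values()), best_state[0][0], 2)
    final_values = best_state[0][1]
    current: dict[str, str] = dict(observed)
    counter = 0
    observed_seqs = set(observed.values())
    for v in final_values:
        if v not in observed_seqs:
            counter += 1
            current[f"MV{counter}"] = v

    # prune obsolete medians: non-observed vectors whose removal is cost-neutral
    changed = True
    while changed:
        changed = False
        for node in [n for n in current if n not in observed]:
            rest = [s for k, s in current.items() if k != node]
            if _mst_cost(rest) <= _mst_cost(list(current.values())):
                del current[node]
                changed = True

    g = nx.Graph()
    for node, seq in current.items():
        g.add_node(
            node,
            seq=seq,
            observed=node in observed,
            members=list(table.membership.get(node, [])),
        )
    for u, v, w in _msn_edges(current, epsilon):
        g.add_edge(u, v, weight=w)
    return HaplotypeNetwork(g)


def min_intergroup_steps(
    network: HaplotypeNetwork,
    hypothesis: TaxonomyHypothesis,
    individual_of=None,
):
    """Minimal mutational path between each pair of groups.

    `individual_of` maps a haplotype member id to an individual id (default:
    strip a trailing ``_A``/``_B`` allele suffix). Returns a DataFrame-like
    dict ``{(taxon_a, taxon_b): steps}`` over unordered group pairs.
    """
    import pandas as pd

    if individual_of is None:
        individual_of = lambda m: m[:-2] if m.endswith(("_A", "_B")) else m
    node_groups: dict[str, set[str]] = {}
    for node, data in network.graph.nodes(data=True):
        for member in data["members"]:
            ind = individual_of(member)
            if ind in hypothesis.assignment:
                node_groups.setdefault(hypothesis.assignment[ind], set()).add(node)
    missing = set(hypothesis.taxa) - set(node_groups)
    if missing:
        raise ValueError(f"groups with no haplotype in the network: {sorted(missing)}")
    out = {}
    taxa = sorted(node_groups)
    for a, b in combinations(taxa, 2):
        best = None
        for src in node_groups[a]:
            lengths = nx.single_source_dijkstra_path_length(
                network.graph, src, weight="weight"
            )
            for dst in node_groups[b]:
                if dst in lengths and (best is None or lengths[dst] < best):
                    best = lengths[dst]
        if best is None:
            raise ValueError(f"no path between groups {a!r} and {b!r}")
        out[(a, b)] = int(best)
    return pd.Series(out, name="min_steps")
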