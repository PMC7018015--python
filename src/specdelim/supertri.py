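"""Supertree reliability indices from per-locus Bayesian bipartition tables.

Each locus contributes the bipartitions sampled during its Bayesian
analysis, with posterior probabilities (PP). These become weighted binary
characters of an MRP (matrix representation with parsimony) supermatrix,
and three per-node indices summarise reliability across loci:

* MPP  — mean posterior probability over all loci (absent = 0);
* NRep — number of loci whose bipartition list contains the node (PP > 0);
* Rep  — NRep divided by the locus count;
* SBP  — supertree bootstrap percentage: resample MRP characters, find the
  maximum-parsimony supertree per replicate (Fitch length on binary
  characters with '?', NNI + SPR hill climbing), and count how often each
  bipartition appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import canonical_bipartition

__all__ = [
    "BipartitionTable",
    "MRPMatrix",
    "NodeSupport",
    "parse_bipartitions",
    "write_bipartitions",
    "build_mrp",
    "node_support",
    "supertree_bootstrap",
    "parsimony_length",
    "search_best_tree",
    "enumerate_unrooted_trees",
]


@dataclass
class BipartitionTable:
    """Per-locus posterior probabilities of canonical taxon bipartitions."""

    locus: str
    taxa: list[str]
    entries: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {}
        for side, pp in self.entries.items():
            if not 0.0 <= pp <= 1.0:
                raise ValueError(f"{self.locus}: PP {pp} outside [0, 1]")
            canon[canonical_bipartition(side, self.taxa)] = float(pp)
        self.entries = canon

    def pp(self, side) -> float:
        return self.entries.get(canonical_bipartition(side, self.taxa), 0.0)


@dataclass
class MRPMatrix:
    """Weighted binary supermatrix: one character per (locus, bipartition).

    `cells` is (n_characters x n_taxa) with values 1 (in the bipartition
    side), 0 (other side) and -1 ('?': taxon absent from the locus).
    """

    taxa: list[str]
    characters: list[tuple[str, frozenset]]  # (locus, canonical side)
    weights: np.ndarray
    cells: np.ndarray

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def to_nexus(self, path) -> None:
        lines = [
            "#NEXUS",
            "begin data;",
            f"  dimensions ntax={len(self.taxa)} nchar={self.n_characters};",
            '  format symbols="01" missing=?;',
            "  matrix",
        ]
        for t, taxon in enumerate(self.taxa):
            states = "".join(
                "?" if self.cells[c, t] < 0 else str(self.cells[c, t])
                for c in range(self.n_characters)
            )
            lines.append(f"    {taxon} {states}")
        lines += [
            "  ;",
            "end;",
            "begin assumptions;",
            "  wtset weights = "
            + ", ".join(f"{int(w)}:{c + 1}" for c, w in enumerate(self.weights))
            + ";",
            "end;",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class NodeSupport:
    bipartition: frozenset
    MPP: float
    NRep: int
    Rep: float
    SBP: float | None = None

    def passes(self, sbp_min=90.0, mpp_min=0.1, nrep_min=2) -> dict[str, bool]:
        """Reliability criteria used in reports: SBP >= 90, MPP >= 0.1, NRep >= 2."""
        return {
            "SBP_pass": self.SBP is not None and self.SBP >= sbp_min,
            "MPP_pass": self.MPP >= mpp_min,
            "NRep_pass": self.NRep >= nrep_min,
        }


def parse_bipartitions(
    path, dialect: str = "tsv", taxa: list[str] | None = None, locus: str | None = None
) -> BipartitionTable:
    """Read one locus's bipartition list.

    dialect="tsv": two tab-separated columns, a comma-separated taxon set
    and its PP (lines starting with '#' ignored; a ``#taxa:`` header line
    may declare the master taxon list).

    dialect="mrbayes": `path` names the ``.parts`` file (lines
    ``<id><tab-or-spaces><.*-pattern>``); the matching ``.tstat`` file
    (same stem) supplies ``<id> <#obs> <probability>`` lines. `taxa` must
    give the taxon order the patterns refer to; '*' marks the bipartition
    side.
    """
    path = Path(path)
    name = locus or path.stem
    if dialect == "tsv":
        entries: dict[frozenset, float] = {}
        file_taxa = taxa
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#taxa:"):
                file_taxa = [t.strip() for t in line[len("#taxa:"):].split(",") if t.strip()]
                continue
            if line.startswith("#"):
                continue
            side_txt, pp_txt = line.split("\t")
            side = frozenset(t.strip() for t in side_txt.split(","))
            entries[side] = float(pp_txt)
        if file_taxa is None:
            raise ValueError(f"{path}: no taxon list (pass taxa= or a '#taxa:' header)")
        unknown = set().union(*entries) - set(file_taxa) if entries else set()
        if unknown:
            raise ValueError(f"{path}: unknown taxa {sorted(unknown)}")
        return BipartitionTable(name, list(file_taxa), entries)
    if dialect == "mrbayes":
        if taxa is None:
            raise ValueError("mrbayes dialect requires the taxon order (taxa=)")
        patterns: dict[str, str] = {}
        for line in path.read_text().splitlines():
            parts = line.replace("--", " ").split()
            if len(parts) == 2 and set(parts[1]) <= {".", "*"}:
                patterns[parts[0]] = parts[1]
        tstat = path.with_suffix(".tstat")
        entries = {}
        for line in tstat.read_text().splitlines():
            parts = line.split()
            if len(parts) >= 3 and parts[0] in patterns:
                try:
                    pp = float(parts[2])
                except ValueError:
                    continue
                pattern = patterns[parts[0]]
                side = frozenset(t for t, c in zip(taxa, pattern) if c == "*")
                if 0 < len(side) < len(taxa):
                    entries[side] = pp
        return BipartitionTable(name, list(taxa), entries)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_bipartitions(table: BipartitionTable, path) -> None:
    lines = ["#taxa: " + ",".join(table.taxa)]
    for side, pp in sorted(table.entries.items(), key=lambda kv: sorted(kv[0])):
        lines.append(",".join(sorted(side)) + "\t" + repr(pp))
    Path(path).write_text("\n".join(lines) + "\n")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_mrp(tables: list[BipartitionTable], weight_scale: int = 100) -> MRPMatrix:
    """Assemble the weighted MRP supermatrix.

    One character per distinct bipartition per locus, weighted by the
    integerised PP (x100, round half up, so PP 0.975 -> 98). Taxa missing
    from a locus are coded '?' for all that locus's characters.
    """
    if not tables:
        raise ValueError("no bipartition tables")
    taxa: dict[str, None] = {}
    for t in tables:
        for x in t.taxa:
            taxa.setdefault(x)
    taxa_list = list(taxa)
    t_index = {x: i for i, x in enumerate(taxa_list)}
    characters = []
    weights = []
    rows = []
    for t in tables:
        present = set(t.taxa)
        for side, pp in sorted(t.entries.items(), key=lambda kv: sorted(kv[0])):
            characters.append((t.locus, side))
            weights.append(_round_half_up(pp * weight_scale))
            row = np.full(len(taxa_list), -1, dtype=np.int8)
            for x in present:
                row[t_index[x]] = 1 if x in side else 0
            rows.append(row)
    return MRPMatrix(taxa_list, characters, np.array(weights), np.vstack(rows))


def node_support(
    tables: list[BipartitionTable],
    nodes: list,
    sbp: dict[frozenset, float] | None = None,
) -> list[NodeSupport]:
    """MPP / NRep / Rep for each queried bipartition (SBP attached if given).

    MPP sums PP over all loci and divides by the locus count (a locus not
    containing the node contributes 0); NRep counts loci with PP > 0.
    """
    n_loci = len(tables)
    if n_loci == 0:
        raise ValueError("no bipartition tables")
    universe = set()
    for t in tables:
        universe |= set(t.taxa)
    out = []
    for node in nodes:
        side = canonical_bipartition(node, universe)
        pps = [t.pp(set(side) & set(t.taxa)) if 0 < len(set(side) & set(t.taxa)) < len(t.taxa) else 0.0
               for t in tables]
        nrep = sum(1 for p in pps if p > 0)
        mpp = sum(pps) / n_loci
        out.append(
            NodeSupport(
                bipartition=side,
                MPP=mpp,
                NRep=nrep,
                Rep=nrep / n_loci,
                SBP=None if sbp is None else sbp.get(side),
            )
        )
    return out


def support_frame(supports: list[NodeSupport]) -> pd.DataFrame:
    rows = []
    for s in supports:
        row = {
            "bipartition": "+".join(sorted(s.bipartition)),
            "SBP": s.SBP,
            "MPP": s.MPP,
            "NRep": s.NRep,
            "Rep": s.Rep,
        }
        row.update(s.passes())
        rows.append(row)
    return pd.DataFrame(rows)


# --- parsimony machinery -------------------------------------------------
#
# Unrooted binary trees over taxon indices 0..n-1; internal nodes are >= n.
# Adjacency is a dict node -> set of neighbours.


def _tree_copy(adj):
    return {k: set(v) for k, v in adj.items()}


def _star3(n_taxa: int):
    root = n_taxa
    adj = {root: {0, 1, 2}}
    for i in range(3):
        adj[i] = {root}
    return adj


def _tree_edges(adj):
    return {frozenset((u, v)) for u in adj for v in adj[u]}


def _insert_taxon(adj, taxon, edge, new_internal):
    u, v = tuple(edge)
    adj[u].remove(v)
    adj[v].remove(u)
    adj[new_internal] = {u, v, taxon}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj[taxon] = {new_internal}


def enumerate_unrooted_trees(n_taxa: int):
    """Yield every unrooted binary tree topology on n_taxa leaves
    (sequential edge addition; (2n-5)!! topologies)."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")

    def recurse(adj, next_taxon, next_internal):
        if next_taxon == n_taxa:
            yield adj
            return
        for edge in list(_tree_edges(adj)):
            child = _tree_copy(adj)
            _insert_taxon(child, next_taxon, edge, next_internal)
            yield from recurse(child, next_taxon + 1, next_internal + 1)

    yield from recurse(_star3(n_taxa), 3, n_taxa + 1)


def tree_bipartitions_mrp(adj, n_taxa: int) -> set[frozenset]:
    """Canonical non-trivial bipartitions (as leaf-index frozensets of the
    side not containing leaf 0) induced by internal edges."""
    out = set()
    for edge in _tree_edges(adj):
        u, v = tuple(edge)
        if u < n_taxa or v < n_taxa:
            continue
        side = _leaves_below(adj, u, v, n_taxa)
        if 1 < len(side) < n_taxa - 1:
            out.add(frozenset(side) if 0 not in side
                    else frozenset(range(n_taxa)) - frozenset(side))
    return out


def _leaves_below(adj, start, parent, n_taxa):
    leaves = []
    stack = [(start, parent)]
    while stack:
        node, par = stack.pop()
        if node < n_taxa:
            leaves.append(node)
            continue
        for nb in adj[node]:
            if nb != par:
                stack.append((nb, node))
    return leaves


def parsimony_length(adj, cells: np.ndarray, weights: np.ndarray) -> int:
    """Weighted Fitch length of an unrooted binary tree on binary characters.

    `cells` is (n_characters x n_taxa) over {1, 0, -1}; '?' (-1) carries the
    full state set and never forces a change.
    """
    n_chars, n_taxa = cells.shape
    # leaf state masks: 0 -> 01b, 1 -> 10b, ? -> 11b
    leaf_masks = np.where(cells < 0, 3, np.where(cells == 1, 2, 1)).astype(np.uint8)
    root_leaf = 0
    root = next(iter(adj[root_leaf]))
    # iterative postorder from the pseudo-root
    order = []
    stack = [(root, root_leaf)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if node >= n_taxa:
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    masks: dict[int, np.ndarray] = {}
    cost = np.zeros(n_chars, dtype=np.int64)
    for node, parent in reversed(order):
        if node < n_taxa:
            masks[node] = leaf_masks[:, node]
            continue
        children = [nb for nb in adj[node] if nb != parent]
        m = masks[children[0]]
        for ch in children[1:]:
            inter = m & masks[ch]
            union = m | masks[ch]
            empty = inter == 0
            cost += empty
            m = np.where(empty, union, inter)
        masks[node] = m
    # final union with the pseudo-root leaf
    inter = masks[root] & leaf_masks[:, root_leaf]
    cost += inter == 0
    return int((cost * weights).sum())


def _random_addition_tree(n_taxa: int, rng) -> dict:
    order = list(rng.permutation(n_taxa))
    relabel = {i: order[i] for i in range(n_taxa)}
    adj = {n_taxa: {relabel[0], relabel[1], relabel[2]}}
    for i in range(3):
        adj[relabel[i]] = {n_taxa}
    next_internal = n_taxa + 1
    for i in range(3, n_taxa):
        edges = list(_tree_edges(adj))
        edge = edges[int(rng.integers(len(edges)))]
        _insert_taxon(adj, relabel[i], edge, next_internal)
        next_internal += 1
    return adj


def _nni_neighbours(adj, n_taxa: int):
    """All trees one nearest-neighbour interchange away."""
    for edge in list(_tree_edges(adj)):
        u, v = tuple(edge)
        if u < n_taxa or v < n_taxa:
            continue
        u_nbrs = [x for x in adj[u] if x != v]
        v_nbrs = [x for x in adj[v] if x != u]
        b = u_nbrs[1]
        for c in v_nbrs:
            child = _tree_copy(adj)
            child[u].remove(b)
            child[b].remove(u)
            child[v].remove(c)
            child[c].remove(v)
            child[u].add(c)
            child[c].add(u)
            child[v].add(b)
            child[b].add(v)
            yield child


def _spr_neighbours(adj, n_taxa: int):
    """Subtree-pruning-and-regrafting neighbours (prune each edge-subtree,
    reattach to every non-adjacent edge)."""
    for edge in list(_tree_edges(adj)):
        u, v = tuple(edge)
        # prune the subtree rooted at u (seen from v); u's other neighbours
        # get fused through a suppressed node
        for sub_root, attach_side in ((u, v), (v, u)):
            if attach_side < n_taxa:
                continue  # cannot suppress a leaf
            rest = [x for x in adj[attach_side] if x != sub_root]
            if len(rest) != 2:
                continue
            a, b = rest
            pruned = _tree_copy(adj)
            pruned[a].remove(attach_side)
            pruned[b].remove(attach_side)
            pruned[sub_root].discard(attach_side)
            del pruned[attach_side]
            pruned[a].add(b)
            pruned[b].add(a)
            subtree_nodes = set()
            stack = [sub_root]
            while stack:
                nd = stack.pop()
                if nd in subtree_nodes:
                    continue
                subtree_nodes.add(nd)
                stack.extend(pruned.get(nd, ()))
            for new_edge in list(_tree_edges(pruned)):
                x, y = tuple(new_edge)
                if x in subtree_nodes or y in subtree_nodes:
                    continue
                if frozenset((x, y)) == frozenset((a, b)) and frozenset((u, v)) == frozenset((sub_root, attach_side)):
                    pass  # reattaching here recreates the original tree
                child = _tree_copy(pruned)
                _insert_taxon_subtree(child, sub_root, (x, y), attach_side)
                yield child


def _insert_taxon_subtree(adj, sub_root, edge, new_internal):
    x, y = edge
    adj[x].remove(y)
    adj[y].remove(x)
    adj[new_internal] = {x, y, sub_root}
    adj[x].add(new_internal)
    adj[y].add(new_internal)
    adj[sub_root].add(new_internal)


def search_best_tree(
    mrp: MRPMatrix,
    seed: int = 0,
    restarts: int = 6,
    use_spr: bool = True,
    cells: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    plateau_budget: int = 8,
):
    """Heuristic maximum-parsimony search.

    Random-addition starting trees, steepest descent over the combined
    NNI (+ optionally SPR) neighbourhood, and up to `plateau_budget`
    sideways moves onto unseen equal-length topologies to cross score
    plateaus. Returns (adjacency, length).
    """
    cells = mrp.cells if cells is None else cells
    weights = mrp.weights if weights is None else weights
    n_taxa = len(mrp.taxa)
    if n_taxa < 4:
        raise ValueError("parsimony search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    best_adj, best_len = None, None
    for _ in range(max(1, restarts)):
        adj = _random_addition_tree(n_taxa, rng)
        length = parsimony_length(adj, cells, weights)
        seen = {frozenset(tree_bipartitions_mrp(adj, n_taxa))}
        budget = plateau_budget
        while True:
            candidates = [
                (parsimony_length(nb, cells, weights), i, nb)
                for i, nb in enumerate(_nni_neighbours(adj, n_taxa))
            ]
            if use_spr:
                candidates += [
                    (parsimony_length(nb, cells, weights), 10_000 + i, nb)
                    for i, nb in enumerate(_spr_neighbours(adj, n_taxa))
                ]
            candidates.sort(key=lambda t: (t[0], t[1]))
            l2, _, nb = candidates[0]
            if l2 < length:
                adj, length = nb, l2
                seen.add(frozenset(tree_bipartitions_mrp(adj, n_taxa)))
                budget = plateau_budget
                continue
            moved = False
            if budget > 0:
                for l3, _, nb3 in candidates:
                    if l3 > length:
                        break
                    key = frozenset(tree_bipartitions_mrp(nb3, n_taxa))
                    if key not in seen:
                        adj = nb3
                        seen.add(key)
                        budget -= 1
                        moved = True
                        break
            if not moved:
                break
        if best_len is None or length < best_len:
            best_adj, best_len = adj, length
    return best_adj, best_len


def _index_bip_to_taxa(bip: frozenset, taxa: list[str]) -> frozenset:
    return frozenset(taxa[i] for i in bip)


def supertree_bootstrap(
    mrp: MRPMatrix,
    replicates: int = 100,
    seed: int = 0,
    restarts: int = 6,
    use_spr: bool = True,
):
    """Supertree bootstrap percentages.

    Characters are resampled with replacement respecting their integer
    weights (a multinomial draw over the weight-expanded matrix); each
    replicate's best tree is found by hill climbing and SBP is the
    percentage of replicates whose best tree contains a bipartition.
    Returns ``(sbp, best_tree_bipartitions)`` with bipartitions as
    taxon-name frozensets (canonical side).
    """
    n_taxa = len(mrp.taxa)
    if n_taxa < 4:
        raise ValueError("supertree bootstrap needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    weights = mrp.weights.astype(float)
    total = int(mrp.weights.sum())
    if total == 0:
        raise ValueError("all character weights are zero")
    p = weights / weights.sum()
    counts: dict[frozenset, int] = {}
    for rep in range(replicates):
        w = rng.multinomial(total, p)
        adj, _ = search_best_tree(
            mrp, seed=int(rng.integers(2**31)), restarts=restarts,
            use_spr=use_spr, weights=w,
        )
        for bip in tree_bipartitions_mrp(adj, n_taxa):
            counts[bip] = counts.get(bip, 0) + 1
    sbp = {
        _index_bip_to_taxa(bip, mrp.taxa): 100.0 * c / replicates
        for bip, c in counts.items()
    }
    # canonicalise on taxon names
    universe = set(mrp.taxa)
    sbp = {canonical_bipartition(side, universe): v for side, v in sbp.items()}
    best_adj, _ = search_best_tree(mrp, seed=seed, restarts=max(restarts, 6), use_spr=use_spr)
    best_bips = {
        canonical_bipartition(_index_bip_to_taxa(b, mrp.taxa), universe)
        for b in tree_bipartitions_mrp(best_adj, n_taxa)
    }
    return sbp, best_bips


def tree_to_newick(adj, taxa: list[str]) -> str:
    """Newick string for an unrooted tree (rooted arbitrarily at leaf 0)."""
    n_taxa = len(taxa)
    root_leaf = 0
    root = next(iter(adj[root_leaf]))

    def render(node, parent):
        if node < n_taxa:
            return taxa[node]
        parts = [render(nb, node) for nb in adj[node] if nb != parent]
        return "(" + ",".join(parts) + ")"

    inner = [render(nb, root) for nb in adj[root] if nb != root_leaf]
    return f"({taxa[root_leaf]},{','.join(inner)});"
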