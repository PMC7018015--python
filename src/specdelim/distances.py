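"""Uncorrected pairwise distances, group summaries and NJ bootstrap.

p-distances use pairwise deletion by default: a site contributes only when
both sequences carry a determinate base there, and IUPAC ambiguities match
whenever their base sets intersect. Neighbor-joining trees are built with
Saitou-Nei agglomeration and haplotype-cluster robustness is assessed by
resampling alignment columns with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix as SkbioDM

from ._seq import canonical_bipartition, seq_to_masks
from .alignment_io import LocusAlignment
from .hypothesis import TaxonomyHypothesis

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "pairwise_p_distances",
    "group_mean_distances",
    "nj_tree",
    "nj_bootstrap",
]


class UndefinedDistanceError(ValueError):
    """No scorable site shared by a sequence pair."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_skbio(self) -> SkbioDM:
        return SkbioDM(self.values, ids=self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over scorable sites (pairwise deletion).

    A site is scorable when both sequences have a determinate base (not '-'
    or 'N'); ambiguity codes match if their base sets intersect.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ma, mb = seq_to_masks(a), seq_to_masks(b)
    scorable = (ma != 0) & (mb != 0)
    n = int(scorable.sum())
    if n == 0:
        raise UndefinedDistanceError("no scorable site shared by the pair")
    mismatches = int(((ma & mb) == 0)[scorable].sum())
    return mismatches / n


def pairwise_p_distances(
    alignment: LocusAlignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs p-distance matrix.

    deletion="pairwise" drops unscorable sites per pair;
    deletion="complete" first drops every column with a gap/'N' in any row.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    ids = alignment.ids
    masks = np.vstack([seq_to_masks(alignment.rows[i]) for i in ids])
    if deletion == "complete":
        keep = (masks != 0).all(axis=0)
        if not keep.any():
            raise UndefinedDistanceError("complete deletion removed every column")
        masks = masks[:, keep]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scorable = (masks[i] != 0) & (masks[j] != 0)
            ns = int(scorable.sum())
            if ns == 0:
                raise UndefinedDistanceError(
                    f"no scorable site shared by {ids[i]!r} and {ids[j]!r}"
                )
            mism = int(((masks[i] & masks[j]) == 0)[scorable].sum())
            values[i, j] = values[j, i] = mism / ns
    return DistanceMatrix(ids, values)


def group_mean_distances(
    matrix: DistanceMatrix, hypothesis: TaxonomyHypothesis
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-group mean distances and within-group summaries.

    Returns ``(between, within)``: `between` is a taxon x taxon DataFrame of
    means over all cross pairs; `within` has mean/min/max/n_pairs per taxon
    (NaN and a flag for singleton groups).
    """
    hypothesis.check_covers(matrix.ids)
    groups = hypothesis.restrict(matrix.ids).groups()
    taxa = list(groups)
    idx = {t: [matrix.ids.index(i) for i in sorted(groups[t])] for t in taxa}
    between = pd.DataFrame(np.nan, index=taxa, columns=taxa)
    within_rows = []
    for a in taxa:
        ia = idx[a]
        sub = matrix.values[np.ix_(ia, ia)]
        pair_vals = sub[np.triu_indices(len(ia), k=1)]
        within_rows.append(
            {
                "taxon": a,
                "n_pairs": len(pair_vals),
                "mean": float(pair_vals.mean()) if len(pair_vals) else np.nan,
                "min": float(pair_vals.min()) if len(pair_vals) else np.nan,
                "max": float(pair_vals.max()) if len(pair_vals) else np.nan,
                "singleton": len(ia) == 1,
            }
        )
        for b in taxa:
            if a == b:
                continue
            cross = matrix.values[np.ix_(ia, idx[b])]
            between.loc[a, b] = float(cross.mean())
    return between, pd.DataFrame(within_rows).set_index("taxon")


def _clamp_negative_branches(tree: skbio.TreeNode) -> skbio.TreeNode:
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def nj_tree(matrix: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    tree = skbio.tree.nj(matrix.to_skbio())
    return _clamp_negative_branches(tree)


def tree_bipartitions(tree: skbio.TreeNode, universe: set[str]) -> set[frozenset]:
    """Canonical non-trivial bipartitions induced by the tree's internal edges."""
    out = set()
    universe = frozenset(universe)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(universe) - 1:
            out.add(canonical_bipartition(side, universe))
    return out


def nj_bootstrap(
    alignment: LocusAlignment,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> tuple[skbio.TreeNode, dict[frozenset, float]]:
    """NJ tree on the original alignment plus column-bootstrap supports.

    Per replicate, columns are resampled with replacement, distances and the
    NJ tree recomputed, and each original bipartition scored by the
    percentage of replicates containing it. A replicate producing an
    undefined distance is redrawn. With ``replicates=0`` only the tree is
    returned (empty support map).
    """
    ids = alignment.ids
    if len(ids) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    tree = nj_tree(pairwise_p_distances(alignment, deletion))
    universe = set(ids)
    if replicates == 0:
        return tree, {}
    ncol = alignment.columns
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    done = 0
    attempts = 0
    rows = {i: np.frombuffer(alignment.rows[i].encode(), dtype="S1") for i in ids}
    while done < replicates:
        attempts += 1
        if attempts > 20 * replicates + 100:
            raise UndefinedDistanceError("too many bootstrap replicates were undefined")
        cols = rng.integers(0, ncol, size=ncol)
        res = LocusAlignment(
            alignment.locus_name,
            {i: rows[i][cols].tobytes().decode() for i in ids},
        )
        try:
            rep_tree = nj_tree(pairwise_p_distances(res, deletion))
        except UndefinedDistanceError:
            continue
        for bip in tree_bipartitions(rep_tree, universe):
            counts[bip] = counts.get(bip, 0) + 1
        done += 1
    support = {bip: 100.0 * counts.get(bip, 0) / replicates
               for bip in tree_bipartitions(tree, universe)}
    # annotate internal nodes of the original tree with support values
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(universe) - 1:
            bip = canonical_bipartition(side, universe)
            node.name = f"{support[bip]:.0f}"
    return tree, support


def clade_support(
    support: dict[frozenset, float], members: set[str], universe: set[str]
) -> float | None:
    """Bootstrap percentage of the bipartition separating `members`, if that
    exact split exists on the original tree (else None)."""
    try:
        bip = canonical_bipartition(members, universe)
    except ValueError:
        return None
    return support.get(bip)
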