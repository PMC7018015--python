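"""Conspecificity matrices: aggregate per-locus FFRs across markers.

The conspecificity score of a pair of individuals is the number of loci at
which the two fall in the same field for recombination. Under scoring
option 1 no value is subtracted for absence of sharing, so scores count
positive evidence only. The matrix is ordered by UPGMA clustering of the
complementary dissimilarity and candidate species appear as high-scoring
diagonal blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .haploweb import FFRPartition
from .hypothesis import TaxonomyHypothesis

__all__ = [
    "ConspecificityMatrix",
    "conspecificity_matrix",
    "order_by_upgma",
    "extract_blocks",
    "plot_heatmap",
]


@dataclass
class ConspecificityMatrix:
    ids: list[str]
    scores: np.ndarray  # symmetric int, cell = loci supporting conspecificity
    n_scorable: np.ndarray  # per pair, loci where both individuals were assigned
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ids, columns=self.ids)


def conspecificity_matrix(
    ffrs: list[FFRPartition], option: int = 1
) -> ConspecificityMatrix:
    """Score every pair of individuals by co-membership across loci.

    Option 1 (the only implemented mode): +1 per locus where the pair share
    an FFR, nothing otherwise; a pair with either individual unassigned at a
    locus contributes to neither the score nor the scorable-locus count.
    """
    if option != 1:
        raise ValueError("only scoring option 1 (no penalty for non-sharing) is supported")
    if not ffrs:
        raise ValueError("need at least one FFR partition")
    ids: dict[str, None] = {}
    for part in ffrs:
        seen: set[str] = set()
        for g in part.groups:
            dup = g & seen
            if dup:
                raise ValueError(
                    f"{part.locus}: individuals in more than one FFR: {sorted(dup)}"
                )
            seen |= g
        for ind in sorted(seen | part.unassigned):
            ids.setdefault(ind)
    id_list = list(ids)
    index = {ind: k for k, ind in enumerate(id_list)}
    n = len(id_list)
    scores = np.zeros((n, n), dtype=int)
    scorable = np.zeros((n, n), dtype=int)
    for part in ffrs:
        assigned = [index[i] for g in part.groups for i in g]
        mask = np.zeros(n, dtype=bool)
        mask[assigned] = True
        scorable += np.outer(mask, mask)
        for g in part.groups:
            ix = [index[i] for i in g]
            scores[np.ix_(ix, ix)] += 1
    np.fill_diagonal(scores, 0)
    np.fill_diagonal(scorable, 0)
    return ConspecificityMatrix(id_list, scores, scorable, len(ffrs))


def order_by_upgma(matrix: ConspecificityMatrix):
    """UPGMA ordering of the matrix.

    Dissimilarity is ``n_loci - score``; returns ``(leaf order, scipy
    linkage)``. Ties break deterministically by input order (scipy's
    stable agglomeration).
    """
    n = len(matrix.ids)
    if n < 2:
        return list(matrix.ids), None
    d = (matrix.n_loci - matrix.scores).astype(float)
    np.fill_diagonal(d, 0.0)
    linkage = hierarchy.average(squareform(d, checks=False))
    order = hierarchy.leaves_list(linkage)
    return [matrix.ids[i] for i in order], linkage


def extract_blocks(
    matrix: ConspecificityMatrix,
    min_score_fraction: float = 0.5,
    name: str = "blocks",
) -> TaxonomyHypothesis:
    """Cut the UPGMA dendrogram into candidate species blocks.

    Walking from the root, a cluster is split whenever the mean
    conspecificity score between its two children is below
    ``min_score_fraction`` of the locus count; otherwise it is kept whole.
    Returns the resulting partition as a taxonomic hypothesis with taxa
    named ``B1``, ``B2``, ... in leaf order.
    """
    if not 0.0 < min_score_fraction <= 1.0:
        raise ValueError("min_score_fraction must be in (0, 1]")
    ids = matrix.ids
    if len(ids) == 1:
        return TaxonomyHypothesis(name, {ids[0]: "B1"})
    _, linkage = order_by_upgma(matrix)
    tree = hierarchy.to_tree(linkage)
    clusters: list[list[int]] = []

    def walk(node) -> None:
        if node.is_leaf():
            clusters.append([node.id])
            return
        left = node.get_left().pre_order(lambda x: x.id)
        right = node.get_right().pre_order(lambda x: x.id)
        cross = matrix.scores[np.ix_(left, right)]
        if cross.mean() / matrix.n_loci < min_score_fraction:
            walk(node.get_left())
            walk(node.get_right())
        else:
            clusters.append(left + right)

    walk(tree)
    assignment: dict[str, str] = {}
    for k, cluster in enumerate(clusters):
        for i in cluster:
            assignment[ids[i]] = f"B{k + 1}"
    return TaxonomyHypothesis(name, assignment)


def plot_heatmap(matrix: ConspecificityMatrix, path=None, order=None):
    """White-to-dark-red heatmap of the (optionally reordered) matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order is None:
        order, _ = order_by_upgma(matrix)
    ix = [matrix.ids.index(i) for i in order]
    data = matrix.scores[np.ix_(ix, ix)]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(data, cmap="Reds", vmin=0, vmax=matrix.n_loci)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=5)
    ax.set_yticks(range(len(order)), order, fontsize=5)
    fig.colorbar(im, ax=ax, label="loci supporting conspecificity")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
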