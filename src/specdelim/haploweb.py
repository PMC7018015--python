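"""Haplowebs and fields for recombination (FFRs).

At one locus, alleles co-occurring in a heterozygous individual are linked;
a pool of alleles connected through such links is exclusive to the group of
individuals carrying them, and that group is a field for recombination —
the allele-sharing unit used as a species-delimitation criterion. The FFR
partition is exactly the set of connected components of the bipartite
individual-allele graph, projected onto individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .alignment_io import PhasedDataset, collapse_haplotypes
from .mjnetwork import median_joining

__all__ = ["FFRPartition", "fields_for_recombination", "build_haploweb"]


@dataclass
class FFRPartition:
    """Per-locus grouping of individuals into fields for recombination."""

    locus: str
    groups: list[set[str]]
    allele_pools: list[set[str]]
    co_occurrence_edges: list[tuple[str, str]]
    unassigned: set[str] = field(default_factory=set)

    def group_of(self, individual: str) -> int | None:
        for k, g in enumerate(self.groups):
            if individual in g:
                return k
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": self.locus, "ffr_id": k + 1, "individual": ind}
            for k, g in enumerate(self.groups)
            for ind in sorted(g)
        ]
        return pd.DataFrame(rows)


def _allele_classes(dataset: PhasedDataset, locus_name: str):
    """Collapse the locus alignment into distinct allele classes and map each
    individual to its (up to two) allele class ids. Alleles that are entirely
    missing ('N' everywhere) count as absent."""
    locus = dataset.locus(locus_name)
    informative = {
        sid: seq for sid, seq in locus.rows.items() if set(seq) != {"N"}
    }
    if not informative:
        return {}, {}, {}
    table = collapse_haplotypes(locus.subset(list(informative)), ignore_gaps_missing=True)
    seq_to_class = table.member_to_haplotype()
    ind_alleles: dict[str, list[str]] = {}
    for ind in dataset.individuals:
        classes = [
            seq_to_class[aid]
            for aid in dataset.alleles_of(ind, locus_name)
            if aid is not None and aid in seq_to_class
        ]
        if classes:
            ind_alleles[ind] = classes
    return table.haplotypes, table.membership, ind_alleles


def fields_for_recombination(dataset: PhasedDataset, locus_name: str) -> FFRPartition:
    """Partition individuals into FFRs at one locus.

    Builds the bipartite graph linking each individual to its allele
    classes; FFRs are its connected components projected to individuals.
    Individuals with no scorable allele at the locus are listed as
    unassigned.
    """
    _, _, ind_alleles = _allele_classes(dataset, locus_name)
    g = nx.Graph()
    for ind, classes in ind_alleles.items():
        g.add_node(("ind", ind))
        for c in classes:
            g.add_edge(("ind", ind), ("allele", c))
    groups, pools = [], []
    for comp in nx.connected_components(g):
        inds = {n[1] for n in comp if n[0] == "ind"}
        alleles = {n[1] for n in comp if n[0] == "allele"}
        if inds:
            groups.append(inds)
            pools.append(alleles)
    order = sorted(range(len(groups)), key=lambda k: min(groups[k]))
    groups = [groups[k] for k in order]
    pools = [pools[k] for k in order]
    co_edges = sorted(
        {
            tuple(sorted((a, b)))
            for classes in ind_alleles.values()
            if len(set(classes)) == 2
            for a, b in [sorted(set(classes))]
        }
    )
    unassigned = set(dataset.individuals) - set(ind_alleles)
    return FFRPartition(locus_name, groups, pools, co_edges, unassigned)


def build_haploweb(
    dataset: PhasedDataset, locus_name: str, remove_singletons: bool = False
) -> nx.Graph:
    """Haploweb graph for one locus: allele-class nodes joined by mutation
    edges (median-joining backbone) plus co-occurrence curves for alleles
    found together in heterozygotes.

    ``remove_singletons`` only tags alleles carried once with
    ``display=False`` — FFR assignment always uses every allele, since
    dropping a singleton could detach its carrier from its own pool.
    """
    haplotypes, membership, ind_alleles = _allele_classes(dataset, locus_name)
    for ind in dataset.individuals:
        n_alleles = sum(a is not None for a in dataset.alleles_of(ind, locus_name))
        if n_alleles > 2:
            raise ValueError(f"{ind} has more than 2 alleles at {locus_name}")
    g = nx.Graph()
    counts = {h: len(m) for h, m in membership.items()}
    for h, seq in haplotypes.items():
        g.add_node(
            h,
            seq=seq,
            members=membership[h],
            n_members=counts[h],
            display=not (remove_singletons and counts[h] == 1),
        )
    if len(haplotypes) >= 2:
        from .alignment_io import HaplotypeTable

        table = HaplotypeTable(locus_name, dict(haplotypes), dict(membership))
        net = median_joining(table)
        for u, v, w in net.edge_list():
            if u in g and v in g:
                g.add_edge(u, v, weight=w, kind="mutation")
    for classes in ind_alleles.values():
        distinct = sorted(set(classes))
        if len(distinct) == 2:
            a, b = distinct
            if g.has_edge(a, b) and g[a][b].get("kind") == "mutation":
                g[a][b]["co_occurring"] = True
            else:
                g.add_edge(a, b, kind="co-occurrence")
    return g
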