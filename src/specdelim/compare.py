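"""Score competing taxonomic hypotheses across all implemented methods.

For each hypothesis and taxon the report collects: exclusive-synapomorphy
counts and the loci carrying them; the fraction of loci whose field-for-
recombination partition supports the taxon; whether the conspecificity-
matrix blocks recover it; the NJ bootstrap of its haplotype cluster;
within/between mean p-distances; and, when per-locus bipartition tables or
clustering log-probability tables are supplied, the MPP/NRep/SBP supertree
indices and the selected K. Standard reliability thresholds (bootstrap and
SBP >= 90, MPP >= 0.1, NRep >= 2) are applied as pass/fail flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import PhasedDataset, concatenate, consensus_from_phased
from .conspecificity import conspecificity_matrix, extract_blocks
from .distances import clade_support, group_mean_distances, nj_bootstrap, pairwise_p_distances
from .haploweb import FFRPartition, fields_for_recombination
from .hypothesis import TaxonomyHypothesis
from .structure_select import consensus_k, evanno_delta_k, plateau_k
from .supertri import build_mrp, node_support, supertree_bootstrap
from .synapomorphy import diagnose_partition

__all__ = ["TaxonomyHypothesis", "SupportReport", "ffr_congruence", "evaluate_hypotheses"]

BOOTSTRAP_MIN = 90.0
SBP_MIN = 90.0
MPP_MIN = 0.1
NREP_MIN = 2


def ffr_congruence(
    ffrs: list[FFRPartition], hypothesis: TaxonomyHypothesis
) -> pd.DataFrame:
    """Fraction of loci whose FFR partition supports each taxon.

    A locus supports a taxon when the taxon's members scorable there form a
    union of whole FFRs containing no non-members — allele pools exclusive
    to the taxon, possibly several of them.
    """
    rows = []
    for taxon, members in hypothesis.groups().items():
        supporting = []
        for part in ffrs:
            scorable = members - part.unassigned
            scorable &= set().union(*part.groups) if part.groups else set()
            if not scorable:
                continue
            covered = set()
            ok = True
            for g in part.groups:
                if g & scorable:
                    if g - members:
                        ok = False  # pool shared with outsiders
                        break
                    covered |= g
            if ok and scorable <= covered:
                supporting.append(part.locus)
        rows.append(
            {
                "taxon": taxon,
                "n_supporting_loci": len(supporting),
                "n_loci": len(ffrs),
                "ffr_congruence": len(supporting) / len(ffrs) if ffrs else np.nan,
                "supporting_loci": supporting,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def _partition_agreement(a: TaxonomyHypothesis, b: TaxonomyHypothesis) -> float:
    """Adjusted Rand index between two partitions of the same individuals."""
    from scipy.special import comb

    ids = sorted(set(a.assignment) & set(b.assignment))
    la = [a.assignment[i] for i in ids]
    lb = [b.assignment[i] for i in ids]
    ct = pd.crosstab(pd.Series(la), pd.Series(lb)).to_numpy()
    n = len(ids)
    sum_cells = comb(ct, 2).sum()
    sum_rows = comb(ct.sum(axis=1), 2).sum()
    sum_cols = comb(ct.sum(axis=0), 2).sum()
    expected = sum_rows * sum_cols / comb(n, 2)
    max_index = (sum_rows + sum_cols) / 2
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


@dataclass
class SupportReport:
    """Per-hypothesis, per-taxon support across all methods."""

    table: pd.DataFrame
    blocks: TaxonomyHypothesis | None = None
    block_agreement: dict[str, float] = field(default_factory=dict)
    k_selection: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        cols = [
            c
            for c in self.table.columns
            if c not in ("supporting_loci", "sites")
        ]
        out = self.table[cols].to_markdown()
        if self.k_selection:
            out += (
                f"\n\nSelected K: {self.k_selection['consensus'].k} "
                f"({self.k_selection['consensus'].rationale})"
            )
        return out


def evaluate_hypotheses(
    dataset: PhasedDataset,
    hypotheses: list[TaxonomyHypothesis],
    bipartition_tables=None,
    lnp_table=None,
    nj_replicates: int = 200,
    sbp_replicates: int = 0,
    min_score_fraction: float = 0.5,
    seed: int = 0,
) -> SupportReport:
    """Run every applicable method and assemble the comparative report.

    Bipartition tables and the clustering likelihood table are optional
    inputs produced upstream by external Bayesian programs; when absent the
    corresponding columns are omitted. Multispecies-coalescent support
    values are likewise external and can be merged into the final table by
    the caller.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    for h in hypotheses:
        h.check_covers(dataset.individuals)

    ffrs = [fields_for_recombination(dataset, name) for name in dataset.locus_names]
    coma = conspecificity_matrix(ffrs)
    blocks = extract_blocks(coma, min_score_fraction=min_score_fraction)

    consensus = consensus_from_phased(dataset)
    supermatrix, _ = concatenate(consensus, row_ids=dataset.individuals)
    dm = pairwise_p_distances(supermatrix)

    # cluster robustness: NJ bootstrap of the consensus supermatrix at the
    # individual level, so every taxon corresponds to a candidate clade
    boot_support = {}
    if len(dataset.individuals) >= 4 and nj_replicates > 0:
        try:
            _, boot_support = nj_bootstrap(
                supermatrix, replicates=nj_replicates, seed=seed
            )
        except ValueError:
            boot_support = {}

    sbp = None
    if bipartition_tables and sbp_replicates > 0:
        mrp = build_mrp(bipartition_tables)
        sbp, _ = supertree_bootstrap(mrp, replicates=sbp_replicates, seed=seed)

    k_selection = None
    if lnp_table is not None:
        dk = evanno_delta_k(lnp_table)
        pk = plateau_k(lnp_table)
        k_selection = {"delta_k": dk, "plateau": pk, "consensus": consensus_k(dk, pk)}

    rows = []
    block_agreement = {}
    for hyp in hypotheses:
        es = diagnose_partition(dataset, hyp)
        congr = ffr_congruence(ffrs, hyp)
        between, within = group_mean_distances(dm, hyp)
        block_agreement[hyp.name] = _partition_agreement(hyp, blocks)
        if bipartition_tables:
            nodes = [hyp.members(t) for t in hyp.taxa]
            sup = node_support(bipartition_tables, nodes, sbp=sbp)
            sup_by_taxon = dict(zip(hyp.taxa, sup))
        else:
            sup_by_taxon = {}
        for taxon in hyp.taxa:
            members = hyp.members(taxon)
            cluster_support = (
                clade_support(boot_support, members, set(dataset.individuals))
                if boot_support
                else None
            )
            block_taxa = {blocks.assignment[m] for m in members}
            block_members = set().union(*(blocks.members(b) for b in block_taxa))
            row = {
                "hypothesis": hyp.name,
                "taxon": taxon,
                "n_individuals": len(members),
                "n_es": int(es.loc[taxon, "n_es"]),
                "n_loci_with_es": int(es.loc[taxon, "n_loci_with_es"]),
                "ffr_congruence": float(congr.loc[taxon, "ffr_congruence"]),
                "coma_block_match": block_members == members,
                "nj_bootstrap": cluster_support,
                "bootstrap_pass": cluster_support is not None
                and cluster_support >= BOOTSTRAP_MIN,
                "within_mean_dist": float(within.loc[taxon, "mean"]),
                "between_min_dist": float(between.loc[taxon].min())
                if len(hyp.taxa) > 1
                else np.nan,
            }
            ns = sup_by_taxon.get(taxon)
            if ns is not None:
                row.update(
                    {
                        "MPP": ns.MPP,
                        "NRep": ns.NRep,
                        "SBP": ns.SBP,
                        "MPP_pass": ns.MPP >= MPP_MIN,
                        "NRep_pass": ns.NRep >= NREP_MIN,
                        "SBP_pass": ns.SBP is not None and ns.SBP >= SBP_MIN,
                    }
                )
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["hypothesis", "taxon"])
    return SupportReport(
        table=table,
        blocks=blocks,
        block_agreement=block_agreement,
        k_selection=k_selection,
        extras={"conspecificity": coma, "ffrs": ffrs},
    )
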