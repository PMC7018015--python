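import pytest

from specdelim import (
    LocusAlignment,
    PhasedDataset,
    SimulationConfig,
    TaxonomyHypothesis,
    simulate_multilocus,
)


def make_phased(locus_rows: dict[str, dict[str, tuple[str, str]]]) -> PhasedDataset:
    """Build a PhasedDataset from {locus: {individual: (seq_a, seq_b)}}."""
    individuals: dict[str, None] = {}
    loci = []
    allele_map: dict[str, dict[str, tuple[str | None, str | None]]] = {}
    for locus_name, per_ind in locus_rows.items():
        rows = {}
        for ind, (a, b) in per_ind.items():
            individuals.setdefault(ind)
            rows[f"{ind}_A"] = a
            rows[f"{ind}_B"] = b
            allele_map.setdefault(ind, {})[locus_name] = (f"{ind}_A", f"{ind}_B")
        loci.append(LocusAlignment(locus_name, rows))
    return PhasedDataset(list(individuals), loci, allele_map)


@pytest.fixture
def clean_sim():
    """Noise-free 3-species simulation with 2 planted fixed differences per
    species per locus."""
    config = SimulationConfig(
        n_species=3,
        inds_per_species=4,
        n_loci=4,
        locus_length=300,
        fixed_diffs=2,
        seed=11,
    )
    dataset, truth = simulate_multilocus(config)
    return config, dataset, truth


@pytest.fixture
def two_group_hypothesis():
    return TaxonomyHypothesis(
        "2g", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    )
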