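"""Synthetic multi-locus diploid datasets with known species boundaries.

The generator plants an exact, known signal: per species and locus a chosen
number of diagnostic columns is overwritten so that all members carry a
state found in no other individual (exclusive synapomorphies by
construction). Background variation is *shared* intraspecific polymorphism
(the same two states segregating in every species), which adds noise to
allele pools and distances without ever creating an extra fixed
inter-species difference. An optional maternally inherited locus can carry
an introgressed haplotype, moving the recipient species next to the donor
on that locus only — the classic mito-nuclear conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .alignment_io import LocusAlignment, PhasedDataset
from .hypothesis import TaxonomyHypothesis

BASES = "ACGT"

__all__ = ["SimulationConfig", "Introgression", "simulate_multilocus"]


@dataclass(frozen=True)
class Introgression:
    """Replace the recipient species' haplotypes at `locus` with
    donor-derived ones (plus `private_diffs` extra private substitutions)."""

    donor: str
    recipient: str
    locus: str = "mt"
    private_diffs: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 3
    inds_per_species: int = 10
    n_loci: int = 10
    locus_length: int = 600
    fixed_diffs: int = 2  # planted diagnostic substitutions per species per locus
    polymorphic_rate: float = 0.0  # per-site probability of shared segregating variation
    missing_rate: float = 0.0  # per-allele probability of a missing call
    indel_rate: float = 0.0  # per species/locus probability of a diagnostic indel
    introgression: Introgression | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.inds_per_species < 1:
            raise ValueError("need at least one species and one individual per species")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.fixed_diffs < 0:
            raise ValueError("fixed_diffs must be >= 0")
        for name in ("polymorphic_rate", "missing_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fixed_diffs and self.n_species * self.fixed_diffs > self.locus_length // 2:
            raise ValueError(
                f"locus_length {self.locus_length} too short to plant "
                f"{self.fixed_diffs} diagnostic sites for {self.n_species} species"
            )
        if self.introgression is not None:
            sp = {self.species_name(i) for i in range(self.n_species)}
            if self.introgression.donor not in sp or self.introgression.recipient not in sp:
                raise ValueError("introgression donor/recipient must name simulated species")
            if self.introgression.donor == self.introgression.recipient:
                raise ValueError("introgression donor and recipient must differ")

    def species_name(self, index: int) -> str:
        return f"sp{index + 1}"

    def to_dict(self) -> dict:
        return asdict(self)


def _mutate(rng: np.random.Generator, base: str) -> str:
    alt = [b for b in BASES if b != base]
    return alt[rng.integers(3)]


def _simulate_locus(
    rng: np.random.Generator,
    config: SimulationConfig,
    species: list[str],
    individuals: list[str],
    species_of: dict[str, str],
    maternal: bool,
) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
    L = config.locus_length
    intro = config.introgression
    ancestral = rng.integers(4, size=L)
    ancestral_chars = [BASES[b] for b in ancestral]

    # disjoint diagnostic columns, one block per species
    blocked: set[int] = set()
    templates = {sp: list(ancestral_chars) for sp in species}
    if config.fixed_diffs:
        cols = rng.choice(L, size=config.n_species * config.fixed_diffs, replace=False)
        blocked.update(int(c) for c in cols)
        for si, sp in enumerate(species):
            for c in cols[si * config.fixed_diffs : (si + 1) * config.fixed_diffs]:
                templates[sp][c] = _mutate(rng, ancestral_chars[c])

    # diagnostic indels: a contiguous 1-3 column gap fixed within one species,
    # never overlapping diagnostic columns or another species' indel
    indel_spans: dict[str, tuple[int, int]] = {}
    if config.indel_rate and not maternal:
        for sp in species:
            if rng.random() >= config.indel_rate:
                continue
            width = int(rng.integers(1, 4))
            for _ in range(200):
                start = int(rng.integers(0, max(1, L - width + 1)))
                span = set(range(start, start + width))
                if span <= set(range(L)) and not span & blocked:
                    indel_spans[sp] = (start, start + width)
                    blocked |= span
                    break

    # shared polymorphism: same two states segregating in every species
    poly_alt: dict[int, str] = {}
    for c in range(L):
        if c not in blocked and rng.random() < config.polymorphic_rate:
            poly_alt[c] = _mutate(rng, ancestral_chars[c])

    # introgressed maternal lineage: donor template plus private substitutions
    if maternal and intro is not None:
        donor_template = list(templates[intro.donor])
        free = [c for c in range(L) if c not in blocked and c not in poly_alt]
        priv = rng.choice(len(free), size=min(intro.private_diffs, len(free)), replace=False)
        for k in priv:
            c = free[int(k)]
            donor_template[c] = _mutate(rng, donor_template[c])
        templates[intro.recipient] = donor_template

    rows: dict[str, str] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for ind in individuals:
        sp = species_of[ind]
        hap_a = list(templates[sp])
        for c, alt in poly_alt.items():
            if rng.random() < 0.5:
                hap_a[c] = alt
        if maternal:
            hap_b = list(hap_a)
        else:
            hap_b = list(templates[sp])
            for c, alt in poly_alt.items():
                if rng.random() < 0.5:
                    hap_b[c] = alt
        if sp in indel_spans:
            lo, hi = indel_spans[sp]
            for hap in (hap_a, hap_b):
                hap[lo:hi] = "-" * (hi - lo)
        seq_a, seq_b = "".join(hap_a), "".join(hap_b)
        if config.missing_rate:
            if rng.random() < config.missing_rate:
                seq_a = "N" * L
            if rng.random() < config.missing_rate:
                seq_b = "N" * L
        rows[f"{ind}_A"] = seq_a
        rows[f"{ind}_B"] = seq_b
        pairs[ind] = (f"{ind}_A", f"{ind}_B")
    return rows, pairs


def simulate_multilocus(config: SimulationConfig) -> tuple[PhasedDataset, TaxonomyHypothesis]:
    """Generate a phased diploid dataset plus its ground-truth partition.

    Deterministic for a fixed config (byte-identical FASTA output). Loci are
    named ``L01``..; when an introgression event is configured an extra
    maternally inherited locus (default name ``mt``, emitted homozygous) is
    appended. The recipient species' haplotypes at that locus derive from the
    donor lineage while all nuclear loci are untouched.
    """
    rng = np.random.default_rng(config.seed)
    S, M = config.n_species, config.inds_per_species
    species = [config.species_name(s) for s in range(S)]
    individuals = [f"{sp}_i{m + 1:02d}" for sp in species for m in range(M)]
    species_of = {ind: ind.split("_")[0] for ind in individuals}
    truth = TaxonomyHypothesis("truth", species_of)

    locus_names = [f"L{i + 1:02d}" for i in range(config.n_loci)]
    intro = config.introgression
    if intro is not None and intro.locus not in locus_names:
        locus_names.append(intro.locus)

    loci: list[LocusAlignment] = []
    allele_map: dict[str, dict[str, tuple[str | None, str | None]]] = {
        ind: {} for ind in individuals
    }
    for locus in locus_names:
        maternal = intro is not None and locus == intro.locus
        rows, pairs = _simulate_locus(rng, config, species, individuals, species_of, maternal)
        loci.append(LocusAlignment(locus, rows))
        for ind, pair in pairs.items():
            allele_map[ind][locus] = pair

    return PhasedDataset(individuals, loci, allele_map), truth


def nuclear_locus_names(dataset: PhasedDataset, config: SimulationConfig) -> list[str]:
    """Locus names excluding the maternally inherited one, if any."""
    mt = config.introgression.locus if config.introgression else None
    return [n for n in dataset.locus_names if n != mt]
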