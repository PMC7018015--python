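"""Exclusive synapomorphies: diagnostic characters fixed within a taxon.

A column (or coded indel) is an exclusive synapomorphy (ES) for a group
when every scorable member carries one state and no individual outside the
group carries it. ES are the diagnosability criterion for candidate
species: a group with zero ES has never been fully isolated genetically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import expand
from .alignment_io import LocusAlignment, PhasedDataset
from .hypothesis import TaxonomyHypothesis

__all__ = [
    "DiagnosticSite",
    "IndelCharacter",
    "code_indels",
    "exclusive_synapomorphies",
    "diagnose_partition",
]


@dataclass(frozen=True)
class DiagnosticSite:
    locus: str
    column: int  # 1-based within the locus; indels report their start column
    kind: str  # substitution | insertion | deletion
    state: str
    span: int
    taxon: str


@dataclass(frozen=True)
class IndelCharacter:
    """One simple-indel-coded binary character: a maximal gap run shared by
    one or more rows, identified by its (start, end) columns (1-based,
    inclusive)."""

    locus: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq) - 1))
    return runs


def code_indels(alignment: LocusAlignment) -> tuple[list[IndelCharacter], dict]:
    """Simple indel coding: each distinct maximal gap run (same start and
    end across the rows sharing it) becomes one presence/absence character.

    Returns the characters and a state table ``states[char][row_id]`` with
    values 1 (row has exactly this run), 0 (row ungapped over the span) or
    None (row partially gapped over the span: inapplicable).
    """
    run_rows: dict[tuple[int, int], list[str]] = {}
    row_runs: dict[str, list[tuple[int, int]]] = {}
    for rid, seq in alignment.rows.items():
        runs = _gap_runs(seq)
        row_runs[rid] = runs
        for run in runs:
            run_rows.setdefault(run, []).append(rid)
    characters = []
    states: dict[IndelCharacter, dict[str, int | None]] = {}
    for (lo, hi) in sorted(run_rows):
        char = IndelCharacter(alignment.locus_name, lo + 1, hi + 1)
        characters.append(char)
        st: dict[str, int | None] = {}
        for rid, seq in alignment.rows.items():
            if (lo, hi) in row_runs[rid]:
                st[rid] = 1
            elif "-" not in seq[lo : hi + 1]:
                st[rid] = 0
            else:
                st[rid] = None
        states[char] = st
    return characters, states


def _individual_states(
    data: PhasedDataset | LocusAlignment | list[LocusAlignment],
) -> tuple[list[str], list[tuple[str, list[str], list[list[str]]]]]:
    """Normalise input to (individuals, per-locus (name, ids, seq lists)).

    For phased input each individual contributes its (up to two) allele
    sequences; for a consensus alignment (rows are individuals) each
    contributes its single row.
    """
    if isinstance(data, PhasedDataset):
        individuals = list(data.individuals)
        per_locus = []
        for loc in data.loci:
            seqs = [data.allele_sequences(ind, loc.locus_name) for ind in individuals]
            per_locus.append((loc.locus_name, individuals, seqs))
        return individuals, per_locus
    if isinstance(data, LocusAlignment):
        data = [data]
    individuals = list(data[0].ids)
    per_locus = []
    for loc in data:
        seqs = [[loc.rows[i]] if i in loc.rows else [] for i in individuals]
        per_locus.append((loc.locus_name, individuals, seqs))
    return individuals, per_locus


def _column_state_set(seqs: list[str], col: int) -> tuple[frozenset[str], bool]:
    """(union of possible bases over an individual's sequences at `col`,
    any_missing). Gaps and 'N' contribute nothing but flag missing."""
    bases: set[str] = set()
    missing = not seqs
    for s in seqs:
        c = s[col]
        if c in "N-":
            missing = True
        else:
            bases |= expand(c)
    return frozenset(bases), missing


def exclusive_synapomorphies(
    data: PhasedDataset | LocusAlignment | list[LocusAlignment],
    taxon: set[str],
    taxon_name: str = "taxon",
    missing_policy: str = "tolerant",
    include_indels: bool = True,
) -> list[DiagnosticSite]:
    """All diagnostic characters fixed in `taxon` and absent outside it.

    With phased input, fixation is read at the individual level: both
    alleles of every scorable member must carry the state. IUPAC
    ambiguities count as possessing each of their bases, so an ambiguous
    non-member can break exclusivity but an ambiguous member always breaks
    fixation.

    missing_policy:
      "tolerant" (default) — 'N'/gap neither confirms nor breaks a
        character, but at least one taxon member must be scorable;
      "strict" — any missing call at the column disqualifies it.
    """
    if missing_policy not in ("tolerant", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    individuals, per_locus = _individual_states(data)
    taxon = set(taxon)
    unknown = taxon - set(individuals)
    if unknown:
        raise ValueError(f"taxon members not in dataset: {sorted(unknown)}")
    if not taxon:
        raise ValueError("taxon is empty")
    if taxon >= set(individuals):
        raise ValueError("taxon equals the full individual set: no complement to compare")

    idx_in = [i for i, ind in enumerate(individuals) if ind in taxon]
    idx_out = [i for i, ind in enumerate(individuals) if ind not in taxon]
    sites: list[DiagnosticSite] = []

    for locus_name, ids, seqs in per_locus:
        ncol = next((len(s[0]) for s in seqs if s), None)
        if ncol is None:
            continue
        for col in range(ncol):
            fixed_state: frozenset[str] | None = None
            scorable_members = 0
            ok = True
            any_missing = False
            for i in idx_in:
                st, miss = _column_state_set(seqs[i], col)
                any_missing |= miss
                if miss and not st:
                    continue  # fully missing member: tolerated
                if miss:
                    # one allele known, one missing: the known alleles must
                    # still match the candidate state
                    pass
                scorable_members += 1
                if len(st) != 1:
                    ok = False  # heterozygous/ambiguous member: not fixed
                    break
                if fixed_state is None:
                    fixed_state = st
                elif st != fixed_state:
                    ok = False
                    break
            if not ok or fixed_state is None or scorable_members == 0:
                continue
            (state,) = fixed_state
            exclusive = True
            for i in idx_out:
                st, miss = _column_state_set(seqs[i], col)
                any_missing |= miss
                if state in st:
                    exclusive = False
                    break
            if not exclusive:
                continue
            if missing_policy == "strict" and any_missing:
                continue
            sites.append(
                DiagnosticSite(locus_name, col + 1, "substitution", state, 1, taxon_name)
            )

        if not include_indels:
            continue
        # indel characters, scored at the individual level
        merged_rows: dict[str, str] = {}
        for i, ind in enumerate(ids):
            for k, s in enumerate(seqs[i]):
                merged_rows[f"{ind}\x00{k}"] = s
        if not merged_rows:
            continue
        chars, states = code_indels(LocusAlignment(locus_name, merged_rows))
        for char in chars:
            st = states[char]
            ind_state: dict[str, int | None] = {}
            for key, val in st.items():
                ind = key.split("\x00")[0]
                if ind not in ind_state:
                    ind_state[ind] = val
                elif ind_state[ind] != val:
                    ind_state[ind] = None if None in (ind_state[ind], val) else -1
            # -1 marks a heterozygous indel (one allele gapped, one not)
            member_vals = [ind_state.get(ind) for ind in taxon if ind in ind_state]
            outside_vals = [
                ind_state[ind] for ind in individuals if ind not in taxon and ind in ind_state
            ]
            for present, kind in ((1, "deletion"), (0, "insertion")):
                mv = [v for v in member_vals if v is not None]
                if missing_policy == "strict" and (
                    None in member_vals or None in outside_vals
                ):
                    continue
                if not mv or any(v != present for v in mv):
                    continue
                # a heterozygous outsider (-1) possesses both states
                if any(v in (present, -1) for v in outside_vals if v is not None):
                    continue
                # "insertion": taxon ungapped while every scorable outsider
                # carries the gap — require at least one gapped outsider
                if present == 0 and not any(v == 1 for v in outside_vals if v is not None):
                    continue
                sites.append(
                    DiagnosticSite(
                        locus_name, char.start, kind, "-" * char.span, char.span, taxon_name
                    )
                )
    return sites


def diagnose_partition(
    data: PhasedDataset | LocusAlignment | list[LocusAlignment],
    hypothesis: TaxonomyHypothesis,
    missing_policy: str = "tolerant",
    include_indels: bool = True,
) -> pd.DataFrame:
    """Per-taxon ES counts for one taxonomic hypothesis.

    Returns a DataFrame indexed by taxon with columns ``n_es``,
    ``n_loci_with_es`` and ``sites`` (the DiagnosticSite list). Raises if
    the hypothesis does not cover every individual or has a single taxon
    (no complement to diagnose against).
    """
    individuals, _ = _individual_states(data)
    hypothesis.check_covers(individuals)
    groups = hypothesis.groups()
    if len(groups) < 2:
        raise ValueError(
            f"hypothesis {hypothesis.name!r} has a single taxon: no complement"
        )
    rows = []
    for taxon_name, members in groups.items():
        sites = exclusive_synapomorphies(
            data,
            members & set(individuals),
            taxon_name=taxon_name,
            missing_policy=missing_policy,
            include_indels=include_indels,
        )
        rows.append(
            {
                "taxon": taxon_name,
                "n_es": len(sites),
                "n_loci_with_es": len({s.locus for s in sites}),
                "sites": sites,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def sites_to_frame(sites: list[DiagnosticSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "locus": s.locus,
                "column": s.column,
                "kind": s.kind,
                "state": s.state,
                "span": s.span,
            }
            for s in sites
        ]
    )
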