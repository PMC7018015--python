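"""Alignment containers and dataset derivations.

Reads per-locus FASTA alignments of phased diploid alleles, builds IUPAC
consensus matrices (one row per individual), concatenates loci into a
supermatrix with back-mapping offsets, and collapses sequences into
distinct haplotypes under dataset-wide exclusion of gap/missing columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import VALID_CHARS, consensus_char

__all__ = [
    "LocusAlignment",
    "PhasedDataset",
    "HaplotypeTable",
    "read_locus_fasta",
    "write_locus_fasta",
    "consensus_from_phased",
    "concatenate",
    "collapse_haplotypes",
]


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad residues, empty file)."""


@dataclass
class LocusAlignment:
    """One aligned locus: ordered mapping of sequence id -> residue string."""

    locus_name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError(f"{self.locus_name}: empty alignment")
        clean = {}
        length = None
        for sid, seq in self.rows.items():
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"{self.locus_name}: sequence {sid!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"{self.locus_name}: invalid residues {sorted(bad)} in {sid!r}"
                )
            clean[sid] = seq
        self.rows = clean

    @property
    def columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, ids) -> "LocusAlignment":
        return LocusAlignment(self.locus_name, {i: self.rows[i] for i in ids})


@dataclass
class PhasedDataset:
    """Individuals x loci, each cell referencing up to two allele sequences.

    `allele_map[individual][locus_name]` is a pair of sequence ids into the
    corresponding :class:`LocusAlignment` (either id may be ``None`` for a
    missing allele call).
    """

    individuals: list[str]
    loci: list[LocusAlignment]
    allele_map: dict[str, dict[str, tuple[str | None, str | None]]]

    def __post_init__(self) -> None:
        by_name = {loc.locus_name: loc for loc in self.loci}
        if len(by_name) != len(self.loci):
            raise AlignmentError("duplicate locus names")
        for ind, per_locus in self.allele_map.items():
            if ind not in self.individuals:
                raise AlignmentError(f"allele_map references unknown individual {ind!r}")
            for locus_name, pair in per_locus.items():
                if len(pair) != 2:
                    raise AlignmentError(f"{ind}/{locus_name}: expected 2 allele slots")
                for aid in pair:
                    if aid is not None and aid not in by_name[locus_name].rows:
                        raise AlignmentError(
                            f"{ind}/{locus_name}: allele id {aid!r} not in alignment"
                        )

    @property
    def locus_names(self) -> list[str]:
        return [loc.locus_name for loc in self.loci]

    def locus(self, name: str) -> LocusAlignment:
        for loc in self.loci:
            if loc.locus_name == name:
                return loc
        raise KeyError(name)

    def alleles_of(self, individual: str, locus_name: str) -> tuple[str | None, str | None]:
        return self.allele_map.get(individual, {}).get(locus_name, (None, None))

    def allele_sequences(self, individual: str, locus_name: str) -> list[str]:
        loc = self.locus(locus_name)
        return [loc.rows[a] for a in self.alleles_of(individual, locus_name) if a is not None]

    def write_fasta_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for loc in self.loci:
            write_locus_fasta(loc, outdir / f"{loc.locus_name}.fasta")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes of one alignment after column exclusion.

    `membership` maps each haplotype id (H1, H2, ...) to the original
    sequence ids collapsed into it; `retained_sites` holds the 1-based
    columns of the source alignment that were compared.
    """

    locus_name: str
    haplotypes: dict[str, str]
    membership: dict[str, list[str]]
    retained_sites: list[int] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def member_to_haplotype(self) -> dict[str, str]:
        return {m: h for h, members in self.membership.items() for m in members}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "haplotype_id": h,
                    "n_members": len(members),
                    "member_ids": ",".join(members),
                }
                for h, members in self.membership.items()
            ]
        )


def read_locus_fasta(path, locus_name: str | None = None) -> LocusAlignment:
    """Read one aligned FASTA file into a :class:`LocusAlignment`.

    Residues are uppercased and validated; unequal row lengths raise
    :class:`AlignmentError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    rows: dict[str, str] = {}
    for rec in records:
        if rec.id in rows:
            raise AlignmentError(f"{path}: duplicate sequence id {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    return LocusAlignment(locus_name or path.stem, rows)


def write_locus_fasta(alignment: LocusAlignment, path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in alignment.rows.items()]
    SeqIO.write(records, str(path), "fasta")


def consensus_from_phased(dataset: PhasedDataset) -> list[LocusAlignment]:
    """Collapse each individual's two alleles into one IUPAC consensus row.

    Heterozygous sites get the two-base ambiguity code; a site missing or
    gapped in only one allele becomes 'N'; an individual missing an allele
    call at a locus is emitted as an all-'N' row so every locus keeps one
    row per individual.
    """
    out = []
    for loc in dataset.loci:
        rows = {}
        for ind in dataset.individuals:
            seqs = dataset.allele_sequences(ind, loc.locus_name)
            if len(seqs) == 2:
                a, b = seqs
                rows[ind] = "".join(consensus_char(x, y) for x, y in zip(a, b))
            elif len(seqs) == 1:
                rows[ind] = "N" * loc.columns
            else:
                rows[ind] = "N" * loc.columns
        out.append(LocusAlignment(loc.locus_name, rows))
    return out


def concatenate(loci: list[LocusAlignment], row_ids: list[str] | None = None):
    """Concatenate loci into a supermatrix.

    Returns ``(supermatrix, offsets)`` where `offsets` is a DataFrame with
    1-based start/end columns per locus, so supermatrix coordinates can be
    mapped back to locus-local positions. Rows absent from a locus are
    padded with 'N'.
    """
    if not loci:
        raise AlignmentError("no loci to concatenate")
    if row_ids is None:
        seen: dict[str, None] = {}
        for loc in loci:
            for rid in loc.ids:
                seen.setdefault(rid)
        row_ids = list(seen)
    rows = {rid: [] for rid in row_ids}
    offsets = []
    pos = 0
    for loc in loci:
        for rid in row_ids:
            rows[rid].append(loc.rows.get(rid, "N" * loc.columns))
        offsets.append(
            {"locus": loc.locus_name, "start": pos + 1, "end": pos + loc.columns}
        )
        pos += loc.columns
    supermatrix = LocusAlignment("supermatrix", {r: "".join(p) for r, p in rows.items()})
    return supermatrix, pd.DataFrame(offsets)


def supermatrix_to_locus_coord(offsets: pd.DataFrame, column: int) -> tuple[str, int]:
    """Map a 1-based supermatrix column back to (locus, 1-based local column)."""
    for rec in offsets.itertuples():
        if rec.start <= column <= rec.end:
            return rec.locus, column - rec.start + 1
    raise ValueError(f"column {column} outside supermatrix")


def collapse_haplotypes(
    alignment: LocusAlignment, ignore_gaps_missing: bool = True
) -> HaplotypeTable:
    """Merge identical sequences into haplotypes.

    With `ignore_gaps_missing` (the default), every column containing '-' or
    'N' in *any* row is excluded dataset-wide before comparison, so the
    collapse is transitive; sequences identical over the retained columns
    share a haplotype.
    """
    ids = alignment.ids
    ncol = alignment.columns
    if ignore_gaps_missing:
        retained = [
            c
            for c in range(ncol)
            if all(alignment.rows[i][c] not in "-N" for i in ids)
        ]
        if not retained and ncol > 0:
            raise AlignmentError(
                f"{alignment.locus_name}: every column contains a gap or 'N'; "
                "nothing left to compare after dataset-wide exclusion"
            )
    else:
        retained = list(range(ncol))
    key_to_hap: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    membership: dict[str, list[str]] = {}
    for sid in ids:
        key = "".join(alignment.rows[sid][c] for c in retained)
        if key not in key_to_hap:
            hap_id = f"H{len(key_to_hap) + 1}"
            key_to_hap[key] = hap_id
            haplotypes[hap_id] = key
            membership[hap_id] = []
        membership[key_to_hap[key]].append(sid)
    return HaplotypeTable(
        locus_name=alignment.locus_name,
        haplotypes=haplotypes,
        membership=membership,
        retained_sites=[c + 1 for c in retained],
    )


def save_config_json(config_dict: dict, path) -> None:
    Path(path).write_text(json.dumps(config_dict, indent=2, sort_keys=True) + "\n")
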