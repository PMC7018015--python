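"""Named taxonomic hypotheses: partitions of individuals into putative species."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TaxonomyHypothesis:
    """A named assignment of every individual to exactly one taxon.

    Examples are the competing splits of a genus into 2, 3, ... candidate
    species ("2Sa", "3S", "4S"...), each scored side by side by the
    comparison pipeline.
    """

    name: str
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError(f"hypothesis {self.name!r}: empty assignment")

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.assignment.values():
            seen.setdefault(t)
        return list(seen)

    @property
    def individuals(self) -> list[str]:
        return list(self.assignment)

    def members(self, taxon: str) -> set[str]:
        m = {i for i, t in self.assignment.items() if t == taxon}
        if not m:
            raise KeyError(f"hypothesis {self.name!r} has no taxon {taxon!r}")
        return m

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for i, t in self.assignment.items():
            out.setdefault(t, set()).add(i)
        return out

    def check_covers(self, individuals) -> None:
        missing = set(individuals) - set(self.assignment)
        if missing:
            raise ValueError(
                f"hypothesis {self.name!r} does not assign: {sorted(missing)}"
            )

    def restrict(self, individuals) -> "TaxonomyHypothesis":
        keep = set(individuals)
        return TaxonomyHypothesis(
            self.name, {i: t for i, t in self.assignment.items() if i in keep}
        )
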