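"""Choosing the number of clusters K from replicate clustering runs.

Operates purely on tables of log probabilities ln Pr(X|K) across replicate
runs (e.g. Bayesian-clustering output summaries); the clustering program
itself is never invoked. Two selectors are provided — the Evanno ΔK
(second-order rate of change normalised by the replicate standard
deviation) and a formalised plateau rule — plus a consensus combiner that
prefers the plateau call unless ΔK is overwhelmingly dominant, reflecting
the known bias of ΔK towards K = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "load_likelihood_table",
    "evanno_delta_k",
    "plateau_k",
    "consensus_k",
    "DeltaKResult",
    "PlateauResult",
    "ConsensusK",
]


@dataclass
class DeltaKResult:
    profile: pd.DataFrame  # columns K, delta_k
    best_k: int

    def delta(self, k: int) -> float:
        row = self.profile.loc[self.profile["K"] == k, "delta_k"]
        if row.empty:
            raise KeyError(f"no ΔK at K={k}")
        return float(row.iloc[0])


@dataclass
class PlateauResult:
    selected: set[int]
    flags: list[str] = field(default_factory=list)
    gains: pd.DataFrame | None = None

    @property
    def smallest(self) -> int:
        return min(self.selected)


@dataclass
class ConsensusK:
    k: int
    delta_k_choice: int
    plateau_choice: set[int]
    rationale: str


def load_likelihood_table(path) -> pd.DataFrame:
    """Read a CSV of (K, replicate, lnP) rows."""
    df = pd.read_csv(path)
    expected = {"K", "replicate", "lnP"}
    if not expected <= set(df.columns):
        raise ValueError(f"likelihood table needs columns {sorted(expected)}")
    return df


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    table = pd.DataFrame(table)
    missing = {"K", "replicate", "lnP"} - set(table.columns)
    if missing:
        raise ValueError(f"likelihood table missing columns {sorted(missing)}")
    ks = sorted(table["K"].unique())
    if ks != list(range(min(ks), max(ks) + 1)):
        raise ValueError(f"K range must be contiguous, got {ks}")
    return table


def evanno_delta_k(table: pd.DataFrame) -> DeltaKResult:
    """Evanno ΔK profile over the interior K values.

    ΔK(K) = mean over replicates of |L(K+1) - 2 L(K) + L(K-1)| divided by
    the standard deviation of L(K) across replicates. Requires at least
    three consecutive K values, at least two replicates per K, and nonzero
    replicate spread at every interior K.
    """
    table = _validate(table)
    ks = sorted(table["K"].unique())
    if len(ks) < 3:
        raise ValueError("ΔK needs at least 3 consecutive K values")
    by_k = {k: g.sort_values("replicate") for k, g in table.groupby("K")}
    reps = {k: len(g) for k, g in by_k.items()}
    if min(reps.values()) < 2:
        raise ValueError("ΔK needs at least 2 replicates per K")
    rows = []
    for k in ks[1:-1]:
        sd = float(by_k[k]["lnP"].std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero replicate standard deviation at K={k}: ΔK undefined")
        n = min(reps[k - 1], reps[k], reps[k + 1])
        l_prev = by_k[k - 1]["lnP"].to_numpy()[:n]
        l_here = by_k[k]["lnP"].to_numpy()[:n]
        l_next = by_k[k + 1]["lnP"].to_numpy()[:n]
        second = np.abs(l_next - 2 * l_here + l_prev)
        rows.append({"K": k, "delta_k": float(second.mean()) / sd})
    profile = pd.DataFrame(rows)
    best = int(profile.loc[profile["delta_k"].idxmax(), "K"])
    return DeltaKResult(profile, best)


def plateau_k(table: pd.DataFrame, rel_gain_threshold: float = 0.05) -> PlateauResult:
    """Plateau rule: smallest K whose mean-lnP gain to K+1 falls below
    ``rel_gain_threshold`` x (max mean - min mean).

    When the gains just above and below the chosen point differ by less
    than half the threshold band, the call is ambiguous and the tied set
    is returned (mirroring "K = 3 or 4" style conclusions). A flat table
    returns K = min with a "flat" flag; no qualifying K returns the full
    range flagged "no plateau".
    """
    table = _validate(table)
    if not 0 < rel_gain_threshold < 1:
        raise ValueError("rel_gain_threshold must be in (0, 1)")
    means = table.groupby("K")["lnP"].mean().sort_index()
    ks = list(means.index)
    if len(ks) < 2:
        raise ValueError("plateau rule needs at least 2 K values")
    rng = float(means.max() - means.min())
    gains = means.diff().shift(-1).dropna()  # gain from K to K+1
    gains_df = gains.rename("gain").reset_index()
    if rng == 0:
        return PlateauResult({ks[0]}, ["flat lnP curve"], gains_df)
    band = rel_gain_threshold * rng
    qualifying = [int(k) for k, g in gains.items() if g < band]
    if not qualifying:
        return PlateauResult(set(ks), ["no plateau"], gains_df)
    k0 = min(qualifying)
    selected = {k0}
    # extend downward over near-tied gains: plateau onset is ambiguous when
    # the previous gain is within half a band of the qualifying one
    k = k0
    while k - 1 in gains.index and abs(gains[k - 1] - gains[k]) < band / 2:
        k -= 1
        selected.add(k)
    flags = [] if len(selected) == 1 else ["ambiguous plateau onset"]
    return PlateauResult(selected, flags, gains_df)


def consensus_k(
    delta_result: DeltaKResult,
    plateau_result: PlateauResult,
    prefer_smallest: bool = True,
    dominance_ratio: float = 10.0,
) -> ConsensusK:
    """Combine the two selectors into one recommendation.

    Agreement wins outright. On disagreement the plateau call is preferred
    (ΔK is biased towards K = 2) unless the maximal ΔK exceeds
    ``dominance_ratio`` x the median of the ΔK profile, in which case the
    ΔK choice stands. Ambiguous plateau sets resolve to the smallest K when
    ``prefer_smallest`` (the standard preference when several K fit the
    data about equally well).
    """
    plateau_choice = (
        min(plateau_result.selected) if prefer_smallest else max(plateau_result.selected)
    )
    dk = delta_result.best_k
    if dk in plateau_result.selected:
        return ConsensusK(dk, dk, plateau_result.selected, "ΔK and plateau methods agree")
    profile = delta_result.profile["delta_k"]
    median_dk = float(profile.median())
    peak = float(profile.max())
    if median_dk > 0 and peak / median_dk > dominance_ratio:
        return ConsensusK(
            dk,
            dk,
            plateau_result.selected,
            f"ΔK peak ({peak:.1f}) dominates its profile "
            f"(> {dominance_ratio:.0f}x median); overriding plateau call",
        )
    note = "plateau call preferred"
    if dk == 2:
        note += " (ΔK K=2 bias)"
    return ConsensusK(plateau_choice, dk, plateau_result.selected, note)
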