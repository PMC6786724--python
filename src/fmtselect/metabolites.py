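"""Donor ranking from stool metabolomics: SCFA production and bile-acid
conversion.

Donors are profiled by averaging each metabolite over their sampled
timepoints, scored by (i) mean abundance of the three measured short-chain
fatty acids and (ii) the secondary-to-primary bile-acid conversion ratio
(lithocholate + deoxycholate) / (chenodeoxycholate + cholate), ranked
descending on each metric, and selected when inside the top quantile of
both — the donors a function-based trial would call first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCFA_NAMES",
    "DonorMetabolomeTable",
    "BileAcidPanel",
    "donor_mean_profile",
    "scfa_score",
    "bile_conversion_ratio",
    "rank_and_select",
    "read_metabolome_tsv",
]

#: The three SCFAs quantified in donor stool.
SCFA_NAMES = ("butyrate", "isovalerate", "propionate")

#: Preferred chromatography mode per metabolite when a compound was measured
#: in several modes (column named "metabolite|mode"). C-18 negative is kept
#: for lithocholate to match the mode of the other bile acids.
DEFAULT_MODE_PREFERENCE: dict[str, list[str]] = {"lithocholate": ["C18neg"]}


@dataclass(frozen=True)
class BileAcidPanel:
    """Primary (host-made) and secondary (microbially converted) bile acids."""

    primary: frozenset[str] = frozenset({"cholate", "chenodeoxycholate"})
    secondary: frozenset[str] = frozenset({"deoxycholate", "lithocholate"})

    def __post_init__(self) -> None:
        if not self.primary or not self.secondary:
            raise ValueError("both bile-acid classes must be non-empty")
        if self.primary & self.secondary:
            raise ValueError("primary and secondary bile acids must be disjoint")


@dataclass
class DonorMetabolomeTable:
    """Long-format donor metabolome: one row per (donor, timepoint).

    Columns: ``donor_id``, ``timepoint``, then one column per metabolite
    (non-negative platform units; NaN = not measured).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("donor_id", "timepoint"):
            if col not in self.data.columns:
                raise ValueError(f"metabolome table missing column {col!r}")
        dup = self.data.duplicated(subset=["donor_id", "timepoint"])
        if dup.any():
            pairs = self.data.loc[dup, ["donor_id", "timepoint"]].values.tolist()
            raise ValueError(f"duplicate (donor, timepoint) rows: {pairs[:5]}")
        vals = self.data[self.metabolite_names].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("metabolite abundances must be non-negative")

    @property
    def metabolite_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("donor_id", "timepoint")]

    @property
    def donor_ids(self) -> list[str]:
        return list(pd.unique(self.data["donor_id"]))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_metabolome_tsv(path, mode_preference: dict | None = None) -> DonorMetabolomeTable:
    """Read a metabolome TSV, resolving multi-mode metabolite columns.

    Columns named ``"metabolite|mode"`` are collapsed to one column per
    metabolite by the preference list (default keeps C-18 negative for
    lithocholate); with no stated preference the lexicographically first
    mode wins, deterministically.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["donor_id"] = df["donor_id"].astype(str)
    return DonorMetabolomeTable(resolve_modes(df, mode_preference))


def resolve_modes(df: pd.DataFrame, mode_preference: dict | None = None) -> pd.DataFrame:
    pref = dict(DEFAULT_MODE_PREFERENCE)
    if mode_preference:
        pref.update(mode_preference)
    keep: dict[str, str] = {}
    modes: dict[str, list[str]] = {}
    for col in df.columns:
        if "|" in col:
            name, mode = col.split("|", 1)
            modes.setdefault(name, []).append(mode)
    out = df.copy()
    for name, available in modes.items():
        chosen = None
        for want in pref.get(name, []):
            if want in available:
                chosen = want
                break
        if chosen is None:
            chosen = sorted(available)[0]
        out[name] = df[f"{name}|{chosen}"]
        out = out.drop(columns=[f"{name}|{m}" for m in available])
    return out


def donor_mean_profile(
    table: DonorMetabolomeTable, required: list[str] | None = None
) -> pd.DataFrame:
    """Per-donor arithmetic mean of each metabolite across timepoints.

    Missing values are excluded from that metabolite's mean. If ``required``
    metabolites are named, a donor whose values are all missing for one of
    them is an error (their score would be undefined).
    """
    prof = table.data.groupby("donor_id", sort=True)[table.metabolite_names].mean()
    if required:
        missing = [m for m in required if m not in prof.columns]
        if missing:
            raise ValueError(f"metabolites absent from table: {missing}")
        for m in required:
            nan = prof.index[prof[m].isna()]
            if len(nan):
                raise ValueError(
                    f"donor {nan[0]!r} has no measured values for required metabolite {m!r}"
                )
    return prof


def scfa_score(profile: pd.DataFrame, scfas: tuple[str, ...] = SCFA_NAMES) -> pd.Series:
    """Mean of the SCFA abundances per donor, in raw platform units."""
    missing = [m for m in scfas if m not in profile.columns]
    if missing:
        raise ValueError(f"SCFAs missing from profile: {missing}")
    score = profile[list(scfas)].mean(axis=1)
    score.name = "scfa_score"
    return score


def scfa_score_standardized(
    profile: pd.DataFrame, scfas: tuple[str, ...] = SCFA_NAMES
) -> pd.Series:
    """z-score variant: mean of per-metabolite standardized SCFA abundances.

    Useful when platform units differ wildly in scale across metabolites;
    the default raw-unit mean is the primary metric.
    """
    missing = [m for m in scfas if m not in profile.columns]
    if missing:
        raise ValueError(f"SCFAs missing from profile: {missing}")
    sub = profile[list(scfas)]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    score = z.mean(axis=1)
    score.name = "scfa_score_z"
    return score


def bile_conversion_ratio(
    profile: pd.DataFrame, panel: BileAcidPanel | None = None
) -> pd.Series:
    """Secondary-to-primary bile acid ratio per donor.

    ``(lithocholate + deoxycholate) / (chenodeoxycholate + cholate)`` with
    the default panel. A zero denominator with a positive numerator yields
    +inf (complete conversion); 0/0 is an error (no bile acids measured).
    """
    panel = panel or BileAcidPanel()
    needed = sorted(panel.primary | panel.secondary)
    missing = [m for m in needed if m not in profile.columns]
    if missing:
        raise ValueError(f"bile acids missing from profile: {missing}")
    num = profile[sorted(panel.secondary)].sum(axis=1)
    den = profile[sorted(panel.primary)].sum(axis=1)
    both_zero = (num == 0) & (den == 0)
    if both_zero.any():
        raise ValueError(
            f"donor {both_zero.idxmax()!r} has zero primary and secondary bile acids "
            "(conversion ratio undefined)"
        )
    with np.errstate(divide="ignore"):
        ratio = num / den
    ratio.name = "conversion_ratio"
    return ratio


def _descending_rank(scores: pd.Series) -> pd.Series:
    """Rank 1 = highest score; ties broken by donor id lexicographic order."""
    order = sorted(scores.index, key=lambda d: (-scores[d], str(d)))
    return pd.Series({d: i + 1 for i, d in enumerate(order)}, name=f"{scores.name}_rank")


def rank_and_select(
    scfa: pd.Series, conversion: pd.Series, q: float = 0.25
) -> pd.DataFrame:
    """Rank donors descending on both metrics; select the joint top quantile.

    The cutoff is ``ceil(q * n)`` ranks (inclusive); a donor is selected
    when both its SCFA rank and its conversion rank are within the cutoff.
    Returns one row per donor with scores, ranks and the selection flag.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    donors = scfa.index
    if len(donors) < 2:
        raise ValueError("need at least 2 donors to rank")
    if set(donors) != set(conversion.index):
        raise ValueError("scfa and conversion scores cover different donors")
    conversion = conversion.loc[donors]
    cutoff = math.ceil(q * len(donors))
    scfa_rank = _descending_rank(scfa.rename("scfa"))
    conv_rank = _descending_rank(conversion.rename("conversion"))
    out = pd.DataFrame(
        {
            "scfa_score": scfa,
            "conversion_ratio": conversion,
            "scfa_rank": scfa_rank.loc[donors],
            "conversion_rank": conv_rank.loc[donors],
        }
    )
    out["selected"] = (out["scfa_rank"] <= cutoff) & (out["conversion_rank"] <= cutoff)
    out.index.name = "donor_id"
    return out
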