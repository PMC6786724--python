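"""Taxon-panel scoring of donors and its association with patient response.

A :class:`TaxonPanel` is a named set of genera — by default butyrate
producers — whose summed relative abundance in a sample is the donor score.
:func:`response_association` maps each patient to the score of the donor
whose material they received and compares the two response groups with a
two-sided equal-variance t-test, which is how a single pre-specified
hypothesis about donor composition would be tested retrospectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .tables import GenusAbundanceTable, SampleMetadata, normalize_genus_name

__all__ = [
    "TaxonPanel",
    "AssociationResult",
    "default_butyrate_panel",
    "panel_abundance",
    "response_association",
    "donor_patient_difference",
]


@dataclass(frozen=True)
class TaxonPanel:
    """A named set of genera scored by their summed relative abundance."""

    name: str
    genera: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genera", frozenset(normalize_genus_name(g) for g in self.genera)
        )

    @classmethod
    def from_json(cls, path) -> "TaxonPanel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(name=obj["name"], genera=frozenset(obj["genera"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "genera": sorted(self.genera)}, fh, indent=2)
            fh.write("\n")


def default_butyrate_panel() -> TaxonPanel:
    """The packaged genus-level butyrate-producer panel.

    Curated from the prevalent, butyrate-pathway-carrying genera of the
    published genus-level heuristic; species-level Eubacterium taxa are
    excluded because the genus does not share conserved butyrate
    production. Override with any user panel JSON.
    """
    ref = resources.files("fmtselect").joinpath("data/butyrate_producers.json")
    with ref.open() as fh:
        obj = json.load(fh)
    return TaxonPanel(name=obj["name"], genera=frozenset(obj["genera"]))


@dataclass
class AssociationResult:
    """Two-group comparison of donor panel scores by patient response."""

    group_means: dict[str, float]
    t_statistic: float
    p_value: float
    n_per_group: dict[str, int]
    degenerate_variance: bool = False


def panel_abundance(table: GenusAbundanceTable, panel: TaxonPanel) -> pd.Series:
    """Summed relative abundance of the panel's genera per sample.

    Matching is exact after normalization (``g__`` prefix stripped,
    case-folded); panel genera absent from the table contribute 0, so a
    panel member never observed in a cohort simply drops out of the score.
    """
    if not panel.genera:
        raise ValueError("cannot score an empty panel")
    wanted = {g.casefold() for g in panel.genera}
    cols = [
        c
        for c in table.data.columns
        if normalize_genus_name(c).casefold() in wanted
    ]
    score = table.data[cols].sum(axis=1) if cols else pd.Series(0.0, index=table.data.index)
    score.name = "panel_abundance"
    return score


def _scores_by_response(
    donor_scores: pd.Series, links: SampleMetadata
) -> dict[str, np.ndarray]:
    meta = links.data
    groups: dict[str, list[float]] = {"response": [], "no_response": []}
    for patient in links.patients:
        resp = meta.loc[patient, "response"]
        if pd.isna(resp):
            continue
        donor = meta.loc[patient, "linked_donor"]
        if pd.isna(donor):
            raise ValueError(f"patient {patient!r} has a response but no linked donor")
        if donor not in donor_scores.index:
            raise ValueError(f"no donor score for linked donor {donor!r} (patient {patient!r})")
        groups[resp].append(float(donor_scores[donor]))
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def response_association(
    donor_scores: pd.Series, links: SampleMetadata, equal_var: bool = True
) -> AssociationResult:
    """t-test of donor panel scores grouped by the linked patient's response.

    Equal-variance (Student) by default; ``equal_var=False`` gives Welch.
    A zero pooled variance with unequal means is reported as p = 0 with the
    ``degenerate_variance`` flag set.
    """
    groups = _scores_by_response(donor_scores, links)
    a, b = groups["response"], groups["no_response"]
    for label, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"response group {label!r} has fewer than 2 observations")
    degenerate = a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0
    if degenerate:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math_inf_signed(a.mean() - b.mean())
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return AssociationResult(
        group_means={"response": float(a.mean()), "no_response": float(b.mean())},
        t_statistic=t,
        p_value=p,
        n_per_group={"response": len(a), "no_response": len(b)},
        degenerate_variance=degenerate,
    )


def math_inf_signed(diff: float) -> float:
    return float("inf") if diff > 0 else float("-inf")


def donor_patient_difference(
    table: GenusAbundanceTable, panel: TaxonPanel, links: SampleMetadata
) -> pd.Series:
    """Donor panel abundance minus the linked patient's baseline abundance.

    One value per patient, in [-1, 1]; positive when the donor carries more
    of the panel than the patient started with.
    """
    scores = panel_abundance(table, panel)
    meta = links.data
    out = {}
    for patient in links.patients:
        donor = meta.loc[patient, "linked_donor"]
        if pd.isna(donor):
            raise ValueError(f"patient {patient!r} has no linked donor")
        if patient not in scores.index:
            raise ValueError(f"patient {patient!r} has no sample in the table")
        out[patient] = float(scores[donor] - scores[patient])
    return pd.Series(out, name="donor_minus_patient")
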