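"""Synthetic data generators with known ground truth.

Three generators mirror the three kinds of input the pipeline consumes:

* :func:`make_case_control` — compositional genus tables with a planted set
  of differentially abundant genera (lognormal abundances, additive
  log-scale case shift, zero inflation, per-row renormalization);
* :func:`make_metabolome` — donor stool metabolomes with latent per-donor
  SCFA production and bile-acid conversion propensities;
* :func:`make_trial_cohort` — donor/patient cohorts whose binary response
  depends (or, under the null, does not depend) on the donor's taxon-panel
  abundance through a logistic link.

Every generator returns its ground truth alongside the data, and identical
seeds give byte-identical output. One seed sequence per dataset is split
deterministically into per-stage child streams, so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import GenusAbundanceTable, SampleMetadata
from .metabolites import DonorMetabolomeTable, BileAcidPanel, SCFA_NAMES
from .taxa import TaxonPanel

__all__ = [
    "CaseControlSpec",
    "MetabolomeSpec",
    "TrialCohortSpec",
    "CaseControlResult",
    "MetabolomeResult",
    "TrialCohortResult",
    "make_case_control",
    "make_metabolome",
    "make_trial_cohort",
]

#: Spread (natural-log SD) of per-genus baseline mean abundances; spans the
#: several orders of magnitude typical of genus-level gut profiles.
BASELINE_LOG_SD = 2.0


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class CaseControlSpec:
    """Design of a synthetic case-control genus table.

    ``effect_delta`` is the shift added to the natural-log abundance of each
    affected genus in case samples; ``sigma`` the lognormal noise SD;
    ``zero_prob`` the per-entry zero-inflation probability (applied before
    renormalization, so zeros hit the log transform as in real sparse data).
    """

    n_cases: int = 200
    n_controls: int = 200
    n_genera: int = 100
    n_affected: int = 10
    effect_delta: float = 2.0
    sigma: float = 1.0
    zero_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected > self.n_genera:
            raise ValueError(
                f"n_affected ({self.n_affected}) exceeds n_genera ({self.n_genera})"
            )
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if not 0 <= self.zero_prob < 1:
            raise ValueError("zero_prob must be in [0, 1)")
        if min(self.n_cases, self.n_controls) < 2:
            raise ValueError("need at least 2 cases and 2 controls")


@dataclass(frozen=True)
class MetabolomeSpec:
    """Design of a synthetic donor stool metabolome.

    Latent per-donor SCFA level and bile-acid conversion propensity are
    lognormal across donors (log-SD 1); each timepoint observation
    multiplies in lognormal noise of scale ``sigma``.
    """

    n_donors: int = 50
    n_timepoints_range: tuple[int, int] = (1, 3)
    sigma: float = 0.3
    scfa_names: tuple[str, ...] = SCFA_NAMES
    bile_acid_panel: BileAcidPanel = field(default_factory=BileAcidPanel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        lo, hi = self.n_timepoints_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_timepoints_range")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class TrialCohortSpec:
    """Design of a synthetic FMT trial cohort.

    ``panel_effect`` is the log-odds coefficient linking the (centered)
    donor panel abundance to the linked patient's response probability;
    0 gives the null in which response is independent of the donor.
    """

    n_donors: int = 20
    n_patients: int = 100
    panel_effect: float = 0.0
    baseline_response_prob: float = 0.4
    n_background_genera: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_response_prob < 1:
            raise ValueError("baseline_response_prob must be in (0, 1)")
        if self.n_donors < 2 or self.n_patients < 4:
            raise ValueError("cohort too small")


@dataclass
class CaseControlResult:
    table: GenusAbundanceTable
    labels: pd.Series  # sample_id -> "case" | "control"
    affected_genera: list[str]  # ground truth


@dataclass
class MetabolomeResult:
    table: DonorMetabolomeTable
    scfa_latent: pd.Series  # donor_id -> latent SCFA level
    conversion_latent: pd.Series  # donor_id -> latent conversion propensity


@dataclass
class TrialCohortResult:
    table: GenusAbundanceTable
    metadata: SampleMetadata
    donor_panel_truth: pd.Series  # donor sample_id -> constructed panel abundance


def make_case_control(spec: CaseControlSpec) -> CaseControlResult:
    """Generate a compositional genus table with planted case/control effects.

    Per-genus baseline log-means are drawn once; the first ``n_affected``
    genera (in generated order) receive ``+effect_delta`` on the log scale in
    case samples. Entries are ``exp(Normal(mean, sigma))``, zeroed with
    probability ``zero_prob``, then renormalized per row. Rows that would be
    entirely zero have their zero mask redrawn.
    """
    rng_base, rng_noise, rng_zero = _rng_streams(spec.seed, 3)
    n = spec.n_cases + spec.n_controls
    genera = [f"Genus_{i:03d}" for i in range(spec.n_genera)]
    samples = [f"S{i:04d}" for i in range(n)]
    is_case = np.array([True] * spec.n_cases + [False] * spec.n_controls)

    baseline = rng_base.normal(0.0, BASELINE_LOG_SD, size=spec.n_genera)
    mean = np.tile(baseline, (n, 1))
    mean[np.ix_(is_case, np.arange(spec.n_affected))] += spec.effect_delta
    log_abund = mean + rng_noise.normal(0.0, spec.sigma, size=(n, spec.n_genera))
    values = np.exp(log_abund)

    if spec.zero_prob > 0:
        mask = rng_zero.random((n, spec.n_genera)) < spec.zero_prob
        # an all-zero sample is not a composition; redraw its mask
        for i in np.nonzero(mask.all(axis=1))[0]:
            while mask[i].all():
                mask[i] = rng_zero.random(spec.n_genera) < spec.zero_prob
        values = np.where(mask, 0.0, values)

    values /= values.sum(axis=1, keepdims=True)
    table = GenusAbundanceTable(pd.DataFrame(values, index=samples, columns=genera))
    labels = pd.Series(np.where(is_case, "case", "control"), index=samples, name="label")
    return CaseControlResult(table, labels, genera[: spec.n_affected])


# relative magnitudes of the measured metabolites (arbitrary platform units)
_SCFA_SCALE = {"butyrate": 1.0, "propionate": 1.5, "isovalerate": 0.3}
_PRIMARY_SCALE = {"cholate": 1.0, "chenodeoxycholate": 0.8}
_SECONDARY_SCALE = {"deoxycholate": 0.9, "lithocholate": 0.5}
#: donor-to-donor spread (natural-log SD) of latent SCFA level / conversion
LATENT_LOG_SD = 1.0


def make_metabolome(spec: MetabolomeSpec) -> MetabolomeResult:
    """Generate a donor metabolome table with known latent rankings.

    SCFA observations scale with a per-donor latent level; secondary bile
    acids scale with a per-donor latent conversion propensity while primary
    bile acids do not, so the conversion ratio is monotone in the latent
    propensity when ``sigma=0``.
    """
    rng_latent, rng_tp, rng_noise = _rng_streams(spec.seed, 3)
    donors = [f"D{i:03d}" for i in range(spec.n_donors)]
    scfa_latent = pd.Series(
        np.exp(rng_latent.normal(0.0, LATENT_LOG_SD, spec.n_donors)), index=donors
    )
    conv_latent = pd.Series(
        np.exp(rng_latent.normal(0.0, LATENT_LOG_SD, spec.n_donors)), index=donors
    )

    lo, hi = spec.n_timepoints_range
    n_tp = rng_tp.integers(lo, hi + 1, size=spec.n_donors)

    metabolites = (
        list(spec.scfa_names)
        + sorted(spec.bile_acid_panel.primary)
        + sorted(spec.bile_acid_panel.secondary)
    )
    rows = []
    index = []
    for d, donor in enumerate(donors):
        for t in range(n_tp[d]):
            obs = {}
            for m in spec.scfa_names:
                obs[m] = _SCFA_SCALE[m] * scfa_latent[donor] * _lognoise(rng_noise, spec.sigma)
            for m in sorted(spec.bile_acid_panel.primary):
                obs[m] = _PRIMARY_SCALE[m] * _lognoise(rng_noise, spec.sigma)
            for m in sorted(spec.bile_acid_panel.secondary):
                obs[m] = (
                    _SECONDARY_SCALE[m] * conv_latent[donor] * _lognoise(rng_noise, spec.sigma)
                )
            rows.append([obs[m] for m in metabolites])
            index.append((donor, t))
    df = pd.DataFrame(rows, columns=metabolites)
    df.insert(0, "donor_id", [i[0] for i in index])
    df.insert(1, "timepoint", [i[1] for i in index])
    return MetabolomeResult(DonorMetabolomeTable(df), scfa_latent, conv_latent)


def _lognoise(rng: np.random.Generator, sigma: float) -> float:
    return math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0


def make_trial_cohort(spec: TrialCohortSpec, panel: TaxonPanel) -> TrialCohortResult:
    """Generate linked donor/patient samples with binary response labels.

    Donor panel abundances are drawn uniformly over (0.05, 0.95) so the
    cohort spans the range; panel mass is split across the panel genera and
    the remainder across background genera (Dirichlet weights). Each patient
    is linked to one donor, and responds with probability
    ``expit(logit(baseline) + panel_effect * (donor_panel - cohort_mean))``.
    """
    if not panel.genera:
        raise ValueError("panel must be non-empty")
    rng_comp, rng_link, rng_resp = _rng_streams(spec.seed, 3)
    donors = [f"D{i:03d}" for i in range(spec.n_donors)]
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    panel_genera = sorted(panel.genera)
    background = [f"Other_{i:02d}" for i in range(spec.n_background_genera)]
    genera = panel_genera + background

    donor_panel = pd.Series(
        rng_comp.uniform(0.05, 0.95, spec.n_donors), index=donors
    )
    # patients start depleted in the panel, as in the diseased gut
    patient_panel = pd.Series(
        rng_comp.uniform(0.0, 0.3, spec.n_patients), index=patients
    )

    def compose(total: float) -> np.ndarray:
        w_in = rng_comp.dirichlet(np.ones(len(panel_genera)))
        w_out = rng_comp.dirichlet(np.ones(len(background)))
        return np.concatenate([total * w_in, (1.0 - total) * w_out])

    rows = [compose(donor_panel[d]) for d in donors]
    rows += [compose(patient_panel[p]) for p in patients]
    table = GenusAbundanceTable(
        pd.DataFrame(rows, index=donors + patients, columns=genera)
    )

    link = rng_link.integers(0, spec.n_donors, size=spec.n_patients)
    linked_donor = [donors[i] for i in link]
    centered = donor_panel - donor_panel.mean()
    logit0 = math.log(spec.baseline_response_prob / (1 - spec.baseline_response_prob))
    p_resp = 1.0 / (
        1.0 + np.exp(-(logit0 + spec.panel_effect * centered.loc[linked_donor].to_numpy()))
    )
    responded = rng_resp.random(spec.n_patients) < p_resp

    meta = pd.DataFrame(
        {
            "role": ["donor"] * spec.n_donors + ["patient"] * spec.n_patients,
            "study": "synthetic",
            "response": [None] * spec.n_donors
            + ["response" if r else "no_response" for r in responded],
            "linked_donor": [None] * spec.n_donors + linked_donor,
        },
        index=donors + patients,
    )
    return TrialCohortResult(table, SampleMetadata(meta), donor_panel)
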