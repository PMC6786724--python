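"""Retrospective-discovery power simulation for FMT trials.

A completed case-control microbiome dataset serves as the effect-size
model: genera are ranked by signal-to-noise ratio (difference in mean log
abundance between cases and controls divided by the SD of log abundance
over all samples) in the full dataset, and the top-k of that ranking are
the "truly" differentially abundant genera. A hypothetical trial of a given
size and response rate is then simulated by subsampling cases as FMT
responders and controls as non-responders, testing every genus with a
tie-corrected Kruskal-Wallis rank test, adjusting with Benjamini-Hochberg,
and counting how many of the top-k genera come out significant at
q < 0.05. The mean recovered count over replicates is the power proxy.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GenusAbundanceTable

__all__ = [
    "CaseControlDataset",
    "TransformConfig",
    "SnrRanking",
    "TrialDesign",
    "TrialSimResult",
    "DifferentialResult",
    "signal_to_noise",
    "top_k_genera",
    "simulate_trial",
    "differential_genera",
    "recovery_count",
    "run_grid",
]

CASE, CONTROL = "case", "control"


@dataclass
class CaseControlDataset:
    """A genus table plus a case/control label per sample."""

    table: GenusAbundanceTable
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        missing = set(self.table.sample_ids) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")
        bad = set(self.labels.loc[self.table.sample_ids]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be case/control, got {sorted(bad)}")
        self.labels = self.labels.loc[self.table.sample_ids]
        for cls in (CASE, CONTROL):
            if (self.labels == cls).sum() < 2:
                raise ValueError(f"need at least 2 {cls} samples")

    @property
    def cases(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def controls(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.table.data.to_csv(float_format="%.17g").encode())
        h.update(self.labels.to_csv().encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class TransformConfig:
    """Log-transform settings for the SNR statistic.

    A fixed small pseudocount keeps log abundance defined on sparse tables;
    natural log throughout. Recorded in output provenance.
    """

    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def log(self, values: np.ndarray) -> np.ndarray:
        return np.log(values + self.pseudocount)


@dataclass
class SnrRanking:
    """Signed per-genus SNR with a total ordering by |snr| descending.

    ``excluded`` lists genera with zero log-abundance variance, for which
    the statistic is undefined. Ties in |snr| break lexicographically on
    the genus name, so top-k sets are deterministic.
    """

    snr: pd.Series
    excluded: list[str] = field(default_factory=list)

    def ordered_genera(self) -> list[str]:
        return sorted(self.snr.index, key=lambda g: (-abs(self.snr[g]), str(g)))


@dataclass(frozen=True)
class TrialDesign:
    """One grid point: FMT-arm size, response rate and testing thresholds.

    ``n_responders = round(n_fmt * response_rate)`` (banker's rounding);
    both arms must be non-empty unless ``response_rate == 1``.
    """

    n_fmt: int
    response_rate: float
    top_k: int = 10
    q_threshold: float = 0.05
    n_reps: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.response_rate <= 1:
            raise ValueError("response_rate must be in (0, 1]")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")
        if self.n_responders < 1:
            raise ValueError("design yields no responders")
        if self.response_rate < 1 and self.n_nonresponders < 1:
            raise ValueError("design yields no non-responders")

    @property
    def n_responders(self) -> int:
        return round(self.n_fmt * self.response_rate)

    @property
    def n_nonresponders(self) -> int:
        return self.n_fmt - self.n_responders


@dataclass
class DifferentialResult:
    """Per-genus KW p/q values and the significant set at the q threshold."""

    p_values: pd.Series
    q_values: pd.Series
    significant: set[str]
    skipped: list[str]  # untestable genera (constant, e.g. all-zero)


@dataclass
class TrialSimResult:
    """Replicate-level recovery outcomes for one trial design."""

    design: TrialDesign
    recovered_counts: np.ndarray
    significant_sets: list[set[str]]
    top_genera: list[str]
    provenance: dict

    @property
    def mean_recovered(self) -> float:
        return float(self.recovered_counts.mean())

    def summary(self) -> dict:
        q = np.quantile(self.recovered_counts, [0.25, 0.5, 0.75])
        return {
            "n_fmt": self.design.n_fmt,
            "response_rate": self.design.response_rate,
            "n_reps": self.design.n_reps,
            "mean_recovered": self.mean_recovered,
            "q25_recovered": float(q[0]),
            "median_recovered": float(q[1]),
            "q75_recovered": float(q[2]),
        }


def signal_to_noise(
    dataset: CaseControlDataset, cfg: TransformConfig | None = None
) -> SnrRanking:
    """Per-genus SNR: case/control difference in mean log abundance over the
    SD (sample, n-1) of log abundance across all samples.

    Genera whose log abundance is constant over all samples have no defined
    SNR and are excluded (reported in ``excluded``).
    """
    cfg = cfg or TransformConfig()
    cases, controls = dataset.cases, dataset.controls
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 samples per class")
    logv = pd.DataFrame(
        cfg.log(dataset.table.values),
        index=dataset.table.sample_ids,
        columns=dataset.table.genus_names,
    )
    sd = logv.std(axis=0, ddof=1)
    diff = logv.loc[cases].mean(axis=0) - logv.loc[controls].mean(axis=0)
    excluded = list(sd.index[sd == 0.0])
    keep = sd.index[sd > 0.0]
    snr = diff.loc[keep] / sd.loc[keep]
    snr.name = "snr"
    return SnrRanking(snr=snr, excluded=excluded)


def top_k_genera(ranking: SnrRanking, k: int = 10) -> list[str]:
    """The k genera with largest |snr| (all of them when fewer than k)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if ranking.snr.empty:
        raise ValueError("empty SNR ranking")
    return ranking.ordered_genera()[:k]


def simulate_trial(
    dataset: CaseControlDataset, design: TrialDesign, rng: np.random.Generator
) -> tuple[GenusAbundanceTable, pd.Series]:
    """Subsample one hypothetical trial from the dataset.

    Responders are drawn uniformly without replacement from the cases,
    non-responders from the controls.
    """
    cases, controls = dataset.cases, dataset.controls
    if design.n_responders > len(cases):
        raise ValueError(
            f"design needs {design.n_responders} responders but only "
            f"{len(cases)} case samples are available"
        )
    if design.n_nonresponders > len(controls):
        raise ValueError(
            f"design needs {design.n_nonresponders} non-responders but only "
            f"{len(controls)} control samples are available"
        )
    resp = list(rng.choice(cases, size=design.n_responders, replace=False))
    nonresp = list(rng.choice(controls, size=design.n_nonresponders, replace=False))
    sub = dataset.table.subset_samples(resp + nonresp)
    labels = pd.Series(
        ["responder"] * len(resp) + ["non_responder"] * len(nonresp),
        index=resp + nonresp,
        name="response",
    )
    return sub, labels


def differential_genera(
    table: GenusAbundanceTable, labels: pd.Series, q_threshold: float = 0.05
) -> DifferentialResult:
    """Kruskal-Wallis per genus on relative abundances, BH across genera.

    Genera constant across the whole subsample (typically all-zero) are
    untestable and skipped; BH is applied over the genera actually tested.
    """
    groups = labels.loc[table.sample_ids]
    names = pd.unique(groups)
    if len(names) != 2 or (groups == names[0]).sum() == 0 or (groups == names[1]).sum() == 0:
        raise ValueError("need exactly two non-empty groups")
    g1 = table.data.loc[groups == names[0]]
    g2 = table.data.loc[groups == names[1]]
    pvals = {}
    skipped = []
    for genus in table.genus_names:
        a = g1[genus].to_numpy()
        b = g2[genus].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0.0:
            skipped.append(genus)
            continue
        _, p = stats.kruskal(a, b)
        pvals[genus] = p
    if not pvals:
        return DifferentialResult(
            pd.Series(dtype=float), pd.Series(dtype=float), set(), skipped
        )
    p = pd.Series(pvals, name="p")
    reject, q, _, _ = multipletests(p.to_numpy(), alpha=q_threshold, method="fdr_bh")
    q = pd.Series(q, index=p.index, name="q")
    significant = set(p.index[q < q_threshold])
    return DifferentialResult(p, q, significant, skipped)


def recovery_count(significant: set[str], top: list[str] | set[str]) -> int:
    """How many of the top-ranked genera were declared significant."""
    return len(set(significant) & set(top))


def run_grid(
    dataset: CaseControlDataset,
    designs: list[TrialDesign],
    master_seed: int,
    cfg: TransformConfig | None = None,
) -> list[TrialSimResult]:
    """Run the full simulation grid, deterministically in ``master_seed``.

    The dataset-level SNR top-k is computed once per distinct ``top_k``.
    Replicate r of design d uses the RNG sub-stream spawned at (d, r), so
    any replicate is reproducible in isolation and adding designs never
    perturbs earlier ones.
    """
    cfg = cfg or TransformConfig()
    # feasibility check up front: fail before any simulation runs
    for design in designs:
        if design.n_responders > len(dataset.cases):
            raise ValueError(
                f"infeasible design (n_fmt={design.n_fmt}, "
                f"response_rate={design.response_rate}): needs "
                f"{design.n_responders} responders, have {len(dataset.cases)} cases"
            )
        if design.n_nonresponders > len(dataset.controls):
            raise ValueError(
                f"infeasible design (n_fmt={design.n_fmt}, "
                f"response_rate={design.response_rate}): needs "
                f"{design.n_nonresponders} non-responders, have "
                f"{len(dataset.controls)} controls"
            )
    ranking = signal_to_noise(dataset, cfg)
    tops = {k: top_k_genera(ranking, k) for k in {d.top_k for d in designs}}
    data_hash = dataset.content_hash()

    results = []
    for d_idx, design in enumerate(designs):
        top = tops[design.top_k]
        counts = np.empty(design.n_reps, dtype=int)
        sig_sets = []
        for r in range(design.n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(d_idx, r))
            )
            sub, labels = simulate_trial(dataset, design, rng)
            diff = differential_genera(sub, labels, design.q_threshold)
            counts[r] = recovery_count(diff.significant, top)
            sig_sets.append(diff.significant)
        results.append(
            TrialSimResult(
                design=design,
                recovered_counts=counts,
                significant_sets=sig_sets,
                top_genera=list(top),
                provenance={
                    "master_seed": master_seed,
                    "design_index": d_idx,
                    "dataset_hash": data_hash,
                    "pseudocount": cfg.pseudocount,
                    "log_base": "e",
                    "sd_ddof": 1,
                },
            )
        )
    return results
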