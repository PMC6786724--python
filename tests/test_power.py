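import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmtselect import (
    CaseControlDataset,
    CaseControlSpec,
    GenusAbundanceTable,
    TransformConfig,
    TrialDesign,
    differential_genera,
    make_case_control,
    recovery_count,
    run_grid,
    signal_to_noise,
    simulate_trial,
    top_k_genera,
)
from fmtselect.power import SnrRanking


def _dataset(case_rows, control_rows, genera=None):
    rows = case_rows + control_rows
    genera = genera or [f"G{j}" for j in range(len(rows[0]))]
    ids = [f"s{i}" for i in range(len(rows))]
    t = GenusAbundanceTable(pd.DataFrame(rows, index=ids, columns=genera))
    labels = pd.Series(
        ["case"] * len(case_rows) + ["control"] * len(control_rows), index=ids
    )
    return CaseControlDataset(t, labels)


def rank_with_ties(values):
    """Independent average-rank assignment (1-based)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sv = np.asarray(values)[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kw_h_oracle(a, b):
    """Tie-corrected two-group Kruskal-Wallis H from the rank formula."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    r = rank_with_ties(pooled)
    ra, rb = r[: len(a)], r[len(a):]
    h = 12 / (n * (n + 1)) * (
        len(a) * (ra.mean() - (n + 1) / 2) ** 2
        + len(b) * (rb.mean() - (n + 1) / 2) ** 2
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def kw_exact_perm_p(a, b):
    """Exact permutation p-value of H: enumerate all case/control splits."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    h_obs = kw_h_oracle(a, b)
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        h = kw_h_oracle(pooled[sel], pooled[~sel])
        count += h >= h_obs - 1e-12
        total += 1
    return count / total


def kw_exact_perm_interval(a, b):
    """One-atom bracket around the exact permutation p-value of H.

    Returns (P(H >= h_plus), P(H >= h_minus)) where h_plus / h_minus are the
    nearest achievable H values strictly above / below the observed one. A
    continuous reference distribution that agrees with the exact null at the
    resolution of its discrete atoms must land inside this interval.
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    h_obs = kw_h_oracle(a, b)
    hs = []
    for idx in itertools.combinations(range(n), na):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        hs.append(kw_h_oracle(pooled[sel], pooled[~sel]))
    hs = np.array(hs)
    above = hs[hs > h_obs + 1e-12]
    below = hs[hs < h_obs - 1e-12]
    p_lo = (hs >= above.min() - 1e-12).mean() if len(above) else 0.0
    p_hi = (hs >= below.max() - 1e-12).mean() if len(below) else 1.0
    return p_lo, p_hi


class TestSignalToNoise:
    def test_identical_groups_zero_snr(self):
        row = [0.2, 0.3, 0.5]
        ds = _dataset([row, [0.1, 0.4, 0.5]], [row, [0.1, 0.4, 0.5]])
        snr = signal_to_noise(ds).snr
        assert np.allclose(snr, 0.0, atol=1e-12)

    def test_constant_genus_excluded(self):
        ds = _dataset([[0.5, 0.5], [0.5, 0.5]], [[0.5, 0.5], [0.5, 0.5]])
        r = signal_to_noise(ds)
        assert r.excluded == ["G0", "G1"]
        assert r.snr.empty

    def test_closed_form_example(self):
        """Log abundances (pre-pseudocount) cases {-1,-1}, controls {-3,-3}
        on one genus: snr = 2 / sd({-1,-1,-3,-3})."""
        pc = 0.0  # make log(a)+pc exact by solving a = exp(x) - pc
        cfg = TransformConfig(pseudocount=1e-12)
        a_case = math.exp(-1) - 1e-12
        a_ctrl = math.exp(-3) - 1e-12
        # second genus absorbs the remainder to keep rows compositional
        ds = _dataset(
            [[a_case, 1 - a_case]] * 2, [[a_ctrl, 1 - a_ctrl]] * 2
        )
        snr = signal_to_noise(ds, cfg).snr
        sd = np.std([-1, -1, -3, -3], ddof=1)
        assert snr["G0"] == pytest.approx((-1 - (-3)) / sd, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        res = make_case_control(CaseControlSpec(n_cases=15, n_controls=12, n_genera=20, seed=3))
        ds = CaseControlDataset(res.table, res.labels)
        cfg = TransformConfig()
        r = signal_to_noise(ds, cfg)
        logv = np.log(ds.table.values + cfg.pseudocount)
        is_case = (ds.labels == "case").to_numpy()
        for j, g in enumerate(ds.table.genus_names):
            diff = logv[is_case, j].mean() - logv[~is_case, j].mean()
            sd = np.std(logv[:, j], ddof=1)
            assert r.snr[g] == pytest.approx(diff / sd, abs=1e-12)

    def test_too_few_samples_rejected(self):
        ds = _dataset([[0.5, 0.5], [0.4, 0.6]], [[0.3, 0.7], [0.2, 0.8]])
        ds.labels.iloc[:] = ["case", "case", "case", "control"]
        with pytest.raises(ValueError):
            signal_to_noise(CaseControlDataset(ds.table, ds.labels))


class TestTopK:
    def test_fewer_than_k_returns_all(self):
        r = SnrRanking(pd.Series({"A": 1.0, "B": -2.0, "C": 0.5}))
        assert set(top_k_genera(r, 10)) == {"A", "B", "C"}

    def test_largest_absolute_wins(self):
        r = SnrRanking(pd.Series({"A": -5.0, "B": 3.0}))
        assert top_k_genera(r, 1) == ["A"]

    def test_matches_sort_oracle(self, rng):
        vals = pd.Series(rng.normal(0, 1, 30), index=[f"g{i}" for i in range(30)])
        r = SnrRanking(vals)
        got = top_k_genera(r, 7)
        expected = sorted(vals.index, key=lambda g: (-abs(vals[g]), g))[:7]
        assert got == expected

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            top_k_genera(SnrRanking(pd.Series({"A": 1.0})), 0)


class TestSimulateTrial:
    def _ds(self):
        res = make_case_control(CaseControlSpec(n_cases=30, n_controls=30, n_genera=10, seed=5))
        return CaseControlDataset(res.table, res.labels)

    def test_full_response_rate(self):
        ds = self._ds()
        design = TrialDesign(n_fmt=10, response_rate=1.0, n_reps=1)
        sub, labels = simulate_trial(ds, design, np.random.default_rng(0))
        assert (labels == "responder").sum() == 10
        assert (labels == "non_responder").sum() == 0

    def test_oversized_design_rejected(self):
        ds = self._ds()
        with pytest.raises(ValueError, match="responders"):
            simulate_trial(ds, TrialDesign(n_fmt=100, response_rate=0.5, n_reps=1),
                           np.random.default_rng(0))

    def test_draws_distinct_and_label_consistent(self):
        ds = self._ds()
        design = TrialDesign(n_fmt=20, response_rate=0.4, n_reps=1)
        cases, controls = set(ds.cases), set(ds.controls)
        for i in range(300):
            sub, labels = simulate_trial(ds, design, np.random.default_rng(i))
            ids = list(sub.sample_ids)
            assert len(set(ids)) == len(ids) == 20
            assert set(labels.index[labels == "responder"]) <= cases
            assert set(labels.index[labels == "non_responder"]) <= controls
            assert (labels == "responder").sum() == 8

    def test_rounding_is_banker(self):
        assert TrialDesign(n_fmt=10, response_rate=0.25, n_reps=1).n_responders == 2
        assert TrialDesign(n_fmt=6, response_rate=0.25, n_reps=1).n_responders == 2


class TestDifferentialGenera:
    def test_no_signal_when_groups_identical(self):
        t = GenusAbundanceTable(pd.DataFrame(
            [[0.5, 0.5]] * 4, index=[f"s{i}" for i in range(4)], columns=["A", "B"]
        ))
        labels = pd.Series(["r", "r", "n", "n"], index=t.sample_ids)
        res = differential_genera(t, labels)
        assert res.significant == set()
        assert set(res.skipped) == {"A", "B"}

    def test_bh_stepup_matches_stated_example(self, rng):
        """{0.001, 0.02, 0.03, 0.9} -> {0.004, 0.04, 0.04, 0.9}."""
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.02, 0.03, 0.9])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.9], atol=1e-12)
        assert (q < 0.05).sum() == 3

    def test_q_values_match_stepup_oracle(self, rng):
        res = make_case_control(CaseControlSpec(n_cases=20, n_controls=20, n_genera=40, seed=2))
        labels = res.labels.map({"case": "r", "control": "n"})
        out = differential_genera(res.table, labels)
        p = out.p_values.to_numpy()
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_oracle = np.empty(m)
        running = 1.0
        for rank_i in range(m, 0, -1):
            idx = order[rank_i - 1]
            running = min(running, p[idx] * m / rank_i)
            q_oracle[idx] = running
        assert np.allclose(out.q_values.to_numpy(), q_oracle, atol=1e-12)

    def test_kw_p_matches_scipy_and_h_oracle(self, rng):
        a = rng.uniform(0, 1, 6)
        b = rng.uniform(0, 1, 5)
        b[2] = a[1]  # introduce a tie
        t = GenusAbundanceTable(pd.DataFrame(
            np.column_stack([np.concatenate([a, b]), 1 - np.concatenate([a, b])]),
            index=[f"s{i}" for i in range(11)], columns=["G", "rest"],
        ))
        labels = pd.Series(["r"] * 6 + ["n"] * 5, index=t.sample_ids)
        out = differential_genera(t, labels)
        h = kw_h_oracle(a, b)
        assert out.p_values["G"] == pytest.approx(stats.chi2.sf(h, df=1), abs=1e-12)

    def test_empty_group_rejected(self):
        t = GenusAbundanceTable(pd.DataFrame(
            [[0.4, 0.6], [0.3, 0.7]], index=["s0", "s1"], columns=["A", "B"]
        ))
        labels = pd.Series(["r", "r"], index=t.sample_ids)
        with pytest.raises(ValueError, match="two non-empty"):
            differential_genera(t, labels)


class TestRecoveryCount:
    def test_disjoint(self):
        assert recovery_count({"A", "B"}, ["C", "D"]) == 0

    def test_superset(self):
        top = [f"g{i}" for i in range(10)]
        assert recovery_count(set(top) | {"x"}, top) == 10

    def test_matches_intersection_oracle(self, rng):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            sig = set(rng.choice(universe, rng.integers(0, 15), replace=False))
            top = list(rng.choice(universe, 10, replace=False))
            naive = sum(1 for g in top if g in sig)
            assert recovery_count(sig, top) == naive
            assert recovery_count(sig, top) <= min(len(sig), len(top))


class TestRunGrid:
    def _ds(self, **kw):
        res = make_case_control(CaseControlSpec(**kw))
        return CaseControlDataset(res.table, res.labels)

    def test_master_seed_determinism(self):
        ds = self._ds(n_cases=20, n_controls=20, n_genera=15, seed=1)
        designs = [TrialDesign(n_fmt=10, response_rate=0.5, n_reps=5)]
        r1 = run_grid(ds, designs, master_seed=99)
        r2 = run_grid(ds, designs, master_seed=99)
        assert np.array_equal(r1[0].recovered_counts, r2[0].recovered_counts)
        assert r1[0].significant_sets == r2[0].significant_sets
        assert r1[0].provenance["dataset_hash"] == r2[0].provenance["dataset_hash"]

    def test_adding_designs_preserves_earlier_replicates(self):
        ds = self._ds(n_cases=20, n_controls=20, n_genera=15, seed=1)
        d1 = TrialDesign(n_fmt=10, response_rate=0.5, n_reps=4)
        d2 = TrialDesign(n_fmt=12, response_rate=0.5, n_reps=4)
        solo = run_grid(ds, [d1], master_seed=5)
        both = run_grid(ds, [d1, d2], master_seed=5)
        assert np.array_equal(solo[0].recovered_counts, both[0].recovered_counts)

    def test_infeasible_design_fails_before_running(self):
        ds = self._ds(n_cases=10, n_controls=10, n_genera=5, n_affected=2, seed=2)
        with pytest.raises(ValueError, match="infeasible"):
            run_grid(ds, [TrialDesign(n_fmt=50, response_rate=0.5, n_reps=3)], 1)

    def test_null_dataset_recovers_nothing(self):
        ds = self._ds(n_cases=60, n_controls=60, n_genera=30, effect_delta=0.0, seed=4)
        res = run_grid(ds, [TrialDesign(n_fmt=40, response_rate=0.5, n_reps=20)], 3)
        assert res[0].mean_recovered <= 0.5

    def test_strong_effect_recovers_top_hits(self):
        ds = self._ds(n_cases=100, n_controls=100, seed=6)
        res = run_grid(ds, [TrialDesign(n_fmt=100, response_rate=0.5, n_reps=10)], 3)
        assert res[0].mean_recovered >= 8.0


@pytest.mark.parametrize(
    "sizes", [(3, 3), (4, 4), (3, 5), (2, 4)], ids=lambda s: f"{s[0]}v{s[1]}"
)
def test_kw_against_exact_permutation_oracle(sizes, rng):
    """Chi-square KW p agrees with the exhaustive permutation null of H at
    the resolution of its discrete atoms, and is monotone-consistent with
    it."""
    na, nb = sizes
    rows = []
    for rep in range(10):
        vals = rng.uniform(0, 1, na + nb)
        if rep % 2:
            vals[: (na + nb) // 2] = np.round(vals[: (na + nb) // 2], 1)  # ties
        a, b = vals[:na], vals[na:]
        h = kw_h_oracle(a, b)
        p_impl = stats.chi2.sf(h, df=1) if h > 0 else 1.0
        _, p_scipy = stats.kruskal(a, b)
        assert p_impl == pytest.approx(p_scipy, abs=1e-12)
        p_lo, p_hi = kw_exact_perm_interval(a, b)
        assert p_lo - 1e-12 <= p_impl <= p_hi + 1e-12
        rows.append((p_impl, kw_exact_perm_p(a, b)))
    impl, exact = zip(*rows)
    assert stats.spearmanr(impl, exact)[0] > 0.95
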