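"""Association models, percentile analyses and the integrated clinical model."""

import numpy as np
import pandas as pd
import pytest

from polymix.evalrisk import (
    hazard_per_sd,
    integrated_risk_model,
    odds_per_sd,
    percentile_prevalence,
    percentile_ranks,
    risk_equivalent_threshold,
    tail_fraction_scan,
)


def _bare_cohort(n, seed=0, prevalent=None, incident=None, follow=None, clinical=None, event_any=None):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "ancestry": "A",
            "age": rng.uniform(40, 70, n).round(1),
            "sex": rng.integers(0, 2, n),
            "array": "axiom_a",
            "prevalent_case": prevalent if prevalent is not None else np.zeros(n, dtype=int),
            "incident_case": incident if incident is not None else np.zeros(n, dtype=int),
            "follow_up_time": follow if follow is not None else np.full(n, 10.0),
            "clinical_risk_10yr": clinical if clinical is not None else np.full(n, 0.05),
        }
    )
    if event_any is not None:
        data["event_any"] = event_any
    for i in range(1, 11):
        data[f"PC{i}"] = rng.normal(size=n)
    return type("C", (), {"data": data, "covariate_matrix": lambda self=None: data[["age", "sex"]].astype(float), "pc_matrix": lambda self=None: data[[f"PC{i}" for i in range(1, 11)]].to_numpy()})()


class TestOddsPerSD:
    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(1)
        n = 30_000
        s = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-2.0 + 0.7 * s)))).astype(int)
        cohort = _bare_cohort(n, prevalent=y)
        res = odds_per_sd(s, cohort, covariates=pd.DataFrame(index=range(n)))
        assert res.ci_low < np.exp(0.7) < res.ci_high
        assert res.p < 1e-10

    def test_zero_variance_score_rejected(self, cohort_trio):
        with pytest.raises(ValueError, match="zero variance"):
            odds_per_sd(np.zeros(cohort_trio.n), cohort_trio)


class TestHazardPerSD:
    def test_no_events_raises(self):
        cohort = _bare_cohort(100)
        with pytest.raises(ValueError, match="no events"):
            hazard_per_sd(np.random.default_rng(0).normal(size=100), cohort)

    def test_prevalent_excluded(self):
        rng = np.random.default_rng(2)
        n = 4000
        prev = (rng.random(n) < 0.3).astype(int)
        inc = np.where(prev == 1, 0, (rng.random(n) < 0.2).astype(int))
        cohort = _bare_cohort(n, prevalent=prev, incident=inc, follow=rng.uniform(1, 10, n))
        res = hazard_per_sd(rng.standard_normal(n), cohort)
        assert res.n == int((prev == 0).sum())

    def test_slope_recovery(self):
        rng = np.random.default_rng(3)
        n = 30_000
        s = rng.standard_normal(n)
        t = rng.exponential(1.0, n) / (0.05 * np.exp(0.5 * s))
        follow = np.minimum(t, 10.0)
        inc = (t < 10.0).astype(int)
        cohort = _bare_cohort(n, incident=inc, follow=follow)
        res = hazard_per_sd(s, cohort, covariates=pd.DataFrame(index=range(n)))
        assert np.exp(0.45) < res.estimate < np.exp(0.55)


class TestPercentiles:
    def test_ranks_stable_ties(self):
        score = np.array([1.0, 0.5, 1.0, 0.2])
        pct = percentile_ranks(score)
        # ties broken by input order: first 1.0 ranks below second 1.0
        assert pct[0] < pct[2]
        assert pct[3] == 0

    def test_each_bin_one_sample_at_n100(self):
        rng = np.random.default_rng(4)
        tab = percentile_prevalence(rng.normal(size=100), rng.integers(0, 2, 100))
        assert (tab["n"] == 1).all()
        assert len(tab) == 100

    def test_perfect_separation(self):
        n = 2000
        score = np.arange(n, dtype=float)
        outcome = (score >= n * 0.95).astype(int)  # top 5% all cases
        tab = percentile_prevalence(score, outcome)
        assert (tab.loc[tab["percentile"] >= 95, "prevalence"] == 1.0).all()
        assert (tab.loc[tab["percentile"] < 95, "prevalence"] == 0.0).all()

    def test_null_flatness(self):
        from scipy.stats import chi2

        rng = np.random.default_rng(5)
        n = 20_000
        outcome = (rng.random(n) < 0.1).astype(int)
        tab = percentile_prevalence(rng.normal(size=n), outcome)
        p0 = outcome.mean()
        stat = ((tab["cases"] - tab["n"] * p0) ** 2 / (tab["n"] * p0 * (1 - p0))).sum()
        assert chi2.sf(stat, df=99) > 0.01

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            percentile_prevalence(np.arange(50.0), np.zeros(50))


class TestTailScan:
    def test_brute_force_oracle_deterministic_bins(self):
        # outcome assigned deterministically by percentile bin: known bin odds
        n = 10_000
        score = np.arange(n, dtype=float)
        pct = percentile_ranks(score)
        # prevalence by design: middle quintile 10%; top bins ramp upward
        prev = np.where(pct >= 90, 0.6, np.where(pct >= 80, 0.25, 0.10))
        rng = np.random.default_rng(6)
        outcome = (rng.random(n) < prev).astype(int)
        got = tail_fraction_scan(score, outcome, [3.0], direction="top")

        # independent exhaustive scan with statsmodels
        import statsmodels.api as sm

        middle = (pct >= 40) & (pct <= 59)
        best = 0.0
        best_x = 0
        for x in range(1, 100):
            tail = (pct >= 100 - x) & ~middle
            sel = tail | middle
            if outcome[tail].sum() == 0:
                break
            res = sm.Logit(outcome[sel], sm.add_constant(tail[sel].astype(float))).fit(disp=0)
            if np.exp(res.params[1]) < 3.0:
                break
            best, best_x = tail.sum() / n, x
        assert got.loc[0, "percentile_cutoff"] == best_x
        assert got.loc[0, "fraction"] == pytest.approx(best)

    def test_null_score_reports_zero(self):
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            n = 4000
            outcome = (r.random(n) < 0.1).astype(int)
            got = tail_fraction_scan(r.normal(size=n), outcome, [3.0], direction="top")
            hits += got.loc[0, "fraction"] == 0.0
        assert hits >= 19

    def test_threshold_one_bounded(self):
        rng = np.random.default_rng(8)
        n = 20_000
        s = rng.standard_normal(n)
        outcome = (rng.random(n) < 1 / (1 + np.exp(-(-2.2 + 1.2 * s)))).astype(int)
        got = tail_fraction_scan(s, outcome, [1.0], direction="top")
        assert got.loc[0, "fraction"] <= 0.80

    def test_bottom_direction(self):
        rng = np.random.default_rng(9)
        n = 20_000
        s = rng.standard_normal(n)
        outcome = (rng.random(n) < 1 / (1 + np.exp(-(-2.0 + 1.5 * s)))).astype(int)
        got = tail_fraction_scan(s, outcome, [1 / 3], direction="bottom")
        assert got.loc[0, "fraction"] > 0.0
        assert got.loc[0, "odds_ratio"] <= 1 / 3


class TestRiskEquivalent:
    def test_null_comparator_returns_max(self):
        rng = np.random.default_rng(10)
        n = 20_000
        s = rng.standard_normal(n)
        comparator = rng.random(n) < 0.05  # no excess hazard
        t = rng.exponential(1.0, n) / (0.05 * np.exp(0.4 * s))
        cohort = _bare_cohort(n, follow=np.minimum(t, 10.0), incident=(t < 10.0).astype(int))
        x, trace = risk_equivalent_threshold(s, cohort, comparator)
        assert x is not None and x >= 79

    def test_zero_effect_score_returns_none(self):
        rng = np.random.default_rng(11)
        n = 20_000
        s = rng.standard_normal(n)
        comparator = rng.random(n) < 0.05
        rate = 0.05 * np.exp(1.5 * comparator)
        t = rng.exponential(1.0, n) / rate
        cohort = _bare_cohort(n, follow=np.minimum(t, 10.0), incident=(t < 10.0).astype(int))
        x, trace = risk_equivalent_threshold(s, cohort, comparator)
        assert x is None

    def test_empty_comparator(self):
        cohort = _bare_cohort(100)
        with pytest.raises(ValueError):
            risk_equivalent_threshold(np.arange(100.0), cohort, np.zeros(100, dtype=bool))

    def test_analytic_crossing(self):
        # comparator log-hazard +1.0, score slope 0.5/SD: the top-x group
        # matches the comparator where E[z | top-x] * 0.5 = 1.0
        from scipy.stats import norm
        from scipy.optimize import brentq

        rng = np.random.default_rng(12)
        n = 100_000
        s = rng.standard_normal(n)
        comparator = rng.random(n) < 0.10
        rate = 0.02 * np.exp(0.5 * s + 1.0 * comparator)
        t = rng.exponential(1.0, n) / rate
        cohort = _bare_cohort(n, follow=np.minimum(t, 10.0), incident=(t < 10.0).astype(int))
        x, trace = risk_equivalent_threshold(s, cohort, comparator)

        def truncated_mean_gap(xfrac):
            q = norm.isf(xfrac)
            return norm.pdf(q) / xfrac * 0.5 - 1.0

        x_star = 100 * brentq(truncated_mean_gap, 0.001, 0.6)
        assert x is not None
        assert abs(x - x_star) <= 3


class TestIntegratedModel:
    @staticmethod
    def _simulate(seed, gamma_int, n=6000):
        rng = np.random.default_rng(seed)
        s = rng.standard_normal(n)
        clin = np.clip(rng.beta(2, 12, n), 0.001, 0.6)
        rate = 0.01 * np.exp(0.5 * s + 3.0 * clin + gamma_int * s * clin)
        t = rng.exponential(1.0, n) / rate
        cohort = _bare_cohort(n, seed=seed, follow=np.minimum(t, 12.0),
                              incident=(t < 12.0).astype(int), clinical=clin)
        return s, clin, cohort

    def test_null_interaction_coverage(self):
        covered = 0
        reps = 25
        for seed in range(reps):
            s, clin, cohort = self._simulate(200 + seed, 0.0)
            res = integrated_risk_model(s, clin, cohort)
            lo, hi = res.interaction_ci
            covered += lo <= 0.0 <= hi
        assert covered >= reps - 3

    def test_negative_interaction_sign_recovery(self):
        neg = 0
        for seed in range(10):
            s, clin, cohort = self._simulate(300 + seed, -2.0, n=10_000)
            res = integrated_risk_model(s, clin, cohort)
            neg += res.interaction_coef < 0
        assert neg >= 9

    def test_predicted_incidence_monotone_in_score(self):
        s, clin, cohort = self._simulate(77, 0.0, n=8000)
        res = integrated_risk_model(s, clin, cohort)
        for stratum, grp in res.incidence_grid.groupby("stratum"):
            grp = grp.sort_values("percentile")
            total_effect = res.coefs["score"] + res.coefs["interaction"] * grp["percentile"].map(
                lambda p: float(clin.mean())
            )
            if (total_effect > 0).all():
                inc = grp["predicted_10yr_incidence"].to_numpy()
                assert np.all(np.diff(inc) >= -1e-12)

    def test_grid_strata_present(self):
        s, clin, cohort = self._simulate(88, 0.0)
        res = integrated_risk_model(s, clin, cohort)
        assert {"low", "intermediate"} <= set(res.incidence_grid["stratum"])
        assert res.interaction_p >= 0
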