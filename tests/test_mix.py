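import numpy as np
import pandas as pd
import pytest

from polymix.mix import (
    MixModel,
    fit_mixing_weights,
    flatten_weights,
    read_mixmodel,
    stepwise_aic_select,
    tune_best_candidate,
    write_mixmodel,
)
from polymix.score import score_cohort
from polymix.score.scoring import StandardizationConstants
from polymix.shrink.weights import WeightSet


def _weightset_from_cohort(cohort, weights, meta=None):
    v = cohort.variants
    table = pd.DataFrame(
        {
            "rsID": v["variant_id"],
            "chr_name": v["chrom"],
            "chr_position": v["pos"],
            "effect_allele": v["effect_allele"],
            "other_allele": v["other_allele"],
            "effect_weight": weights,
        }
    )
    return WeightSet(table=table, metadata=meta or {})


class TestTuneBestCandidate:
    def test_singleton_returned_unchanged(self, cohort_trio, effects_trio):
        ws = _weightset_from_cohort(cohort_trio, effects_trio.effect_vector("EUR", "cad"))
        best, summary = tune_best_candidate([ws], cohort_trio)
        assert best is ws
        assert len(summary) == 1

    def test_planted_signal_recovery(self, cohort_trio, effects_trio):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            true_w = effects_trio.effect_vector("EUR", "cad")
            planted = _weightset_from_cohort(cohort_trio, true_w, {"p": 0.1, "s": 1.0, "sparse": False})
            permuted = _weightset_from_cohort(
                cohort_trio, rng.permutation(true_w), {"p": 0.2, "s": 1.0, "sparse": False}
            )
            best, _ = tune_best_candidate([permuted, planted], cohort_trio)
            wins += best is planted
        assert wins >= 9

    def test_tiebreak_smaller_p(self, cohort_trio, effects_trio):
        w = effects_trio.effect_vector("EUR", "cad")
        a = _weightset_from_cohort(cohort_trio, w, {"p": 0.5, "s": 1.0, "sparse": False})
        b = _weightset_from_cohort(cohort_trio, w, {"p": 0.1, "s": 1.0, "sparse": False})
        best, _ = tune_best_candidate([a, b], cohort_trio)
        assert best is b

    def test_empty_candidates(self, cohort_trio):
        with pytest.raises(ValueError):
            tune_best_candidate([], cohort_trio)


class TestStepwise:
    def test_noise_component_excluded(self):
        n = 20_000
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            s_info = rng.standard_normal(n)
            s_noise = rng.standard_normal(n)
            p = 1 / (1 + np.exp(-(-1.5 + 0.8 * s_info)))
            y = (rng.random(n) < p).astype(int)
            scores = pd.DataFrame({"info": s_info, "noise": s_noise})
            selected, trace = stepwise_aic_select(scores, y)
            wins += ("info" in selected) and ("noise" not in selected)
        assert wins >= 9

    def test_identical_copies_collapse_to_one(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(3000)
        y = (rng.random(3000) < 1 / (1 + np.exp(-s))).astype(int)
        scores = pd.DataFrame({"a": s, "b": s, "c": s})
        selected, trace = stepwise_aic_select(scores, y)
        assert len(selected) == 1
        assert all(t2 <= t1 + 1e-9 for t1, t2 in zip(trace, trace[1:]))

    def test_matches_exhaustive_search_orthogonal(self):
        from itertools import combinations

        from polymix.mix.glmfit import logit_fit

        n, k = 4000, 4
        rng = np.random.default_rng(3)
        x = rng.standard_normal((n, k))
        q, _ = np.linalg.qr(x)
        comps = pd.DataFrame(q * np.sqrt(n), columns=list("abcd"))
        lin = -1.0 + 0.5 * comps["a"] + 0.25 * comps["b"] + 0.03 * comps["c"]
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)

        best_aic, best_subset = np.inf, None
        for r in range(k + 1):
            for sub in combinations(comps.columns, r):
                aic = logit_fit(comps[list(sub)], y).aic
                if aic < best_aic:
                    best_aic, best_subset = aic, set(sub)
        selected, trace = stepwise_aic_select(comps, y)
        assert set(selected) == best_subset
        assert trace[-1] == pytest.approx(best_aic, abs=1e-6)

    def test_aic_trace_nonincreasing_and_bounded(self):
        from polymix.mix.glmfit import logit_fit

        rng = np.random.default_rng(4)
        comps = pd.DataFrame(rng.standard_normal((2000, 3)), columns=list("abc"))
        lin = -1 + 0.6 * comps["a"]
        y = (rng.random(2000) < 1 / (1 + np.exp(-lin))).astype(int)
        selected, trace = stepwise_aic_select(comps, y)
        assert all(t2 < t1 for t1, t2 in zip(trace, trace[1:]))
        full_aic = logit_fit(comps, y).aic
        null_aic = logit_fit(comps[[]], y).aic
        assert trace[-1] <= full_aic + 1e-9
        assert trace[-1] <= null_aic + 1e-9


class TestMixingWeights:
    def test_coefficient_ratio_recovery(self):
        n = 50_000
        rng = np.random.default_rng(5)
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        lin = -2.0 + 0.6 * s1 + 0.3 * s2
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        model = fit_mixing_weights(pd.DataFrame({"s1": s1, "s2": s2}), y)
        ratio = model.beta["s1"] / model.beta["s2"]
        assert 1.5 < ratio < 2.5

    def test_null_component_wald_calibrated(self):
        import statsmodels.api as sm

        n, inside = 2000, 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(600 + seed)
            s1, s0 = rng.standard_normal(n), rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.5 * s1)))).astype(int)
            res = sm.Logit(y, sm.add_constant(np.column_stack([s1, s0]))).fit(disp=0)
            z = res.params[2] / res.bse[2]
            inside += abs(z) < 3
        assert inside / reps >= 0.95

    def test_single_component_positive_rescaling(self, cohort_trio, effects_trio):
        from polymix.evalrisk import odds_per_sd

        ws = _weightset_from_cohort(cohort_trio, effects_trio.effect_vector("EUR", "cad"))
        sv, consts, _ = score_cohort(cohort_trio, ws)
        y = cohort_trio.data["prevalent_case"].to_numpy()
        covs = cohort_trio.covariate_matrix()
        model = fit_mixing_weights(pd.DataFrame({"c": sv.standardized}), y, covs, constants={"c": consts})
        assert model.beta["c"] > 0
        combined = model.beta["c"] * sv.standardized
        from polymix.score.scoring import standardize_scores
        from polymix.score.scoring import ScoreVector

        sv_c, _ = standardize_scores(
            ScoreVector(sv.sample_ids, combined, sv.ancestry), cohort_trio.pc_matrix()
        )
        or_single = odds_per_sd(sv.standardized, cohort_trio).estimate
        or_combined = odds_per_sd(sv_c.standardized, cohort_trio).estimate
        assert or_combined == pytest.approx(or_single, abs=1e-6)

    def test_serialization_roundtrip(self, tmp_path):
        consts = StandardizationConstants(
            pc_coefs={"EUR": np.arange(11.0)}, mean={"EUR": 0.3}, sd={"EUR": 1.7}
        )
        model = MixModel(
            layer=1, components=["a", "b"], selected=["a"], beta={"a": 0.8},
            covariate_coefs={"const": -2.0}, constants={"a": consts}, aic_trace=[100.0, 98.5],
        )
        path = write_mixmodel(model, tmp_path / "m.json")
        back = read_mixmodel(path)
        assert back.beta == model.beta
        assert back.selected == model.selected
        assert np.array_equal(back.constants["a"].pc_coefs["EUR"], consts.pc_coefs["EUR"])
        assert back.constants["a"].sd["EUR"] == 1.7

    def test_invalid_models(self):
        with pytest.raises(ValueError):
            MixModel(1, ["a"], ["b"], {"b": 1.0}, {}, {}, [1.0]).validate()
        with pytest.raises(ValueError):
            MixModel(1, ["a"], ["a"], {"a": 1.0}, {}, {}, [1.0, 2.0]).validate()


class TestFlatten:
    def _setup_components(self, cohort, effects, n_components=3):
        rng = np.random.default_rng(7)
        true_w = effects.effect_vector("EUR", "cad")
        m = len(true_w)
        comps = {}
        for i in range(n_components):
            w = true_w * (0.5 + rng.random()) + rng.normal(0, np.abs(true_w).mean(), m)
            comps[f"c{i}"] = _weightset_from_cohort(cohort, w)
        return comps

    def test_flatten_equivalence(self, cohort_eur, effects_trio):
        # single ancestry group: the scalar-SD flattening is affine-exact
        cohort = cohort_eur
        comps = self._setup_components(cohort, effects_trio)
        y = cohort.data["prevalent_case"].to_numpy()
        covs = cohort.covariate_matrix()
        scores, consts = {}, {}
        for name, ws in comps.items():
            sv, c, _ = score_cohort(cohort, ws, score_id=name)
            scores[name] = sv.standardized
            consts[name] = c
        frame = pd.DataFrame(scores)
        l1 = fit_mixing_weights(frame, y, covs, constants=consts, layer=1)
        # single-trait layer 2: identity combination of the layer-1 output
        combined_raw = l1.combine(frame)
        from polymix.score.scoring import ScoreVector, standardize_scores

        sv_l1, c_l1 = standardize_scores(
            ScoreVector(cohort.data["sample_id"].to_numpy(), combined_raw,
                        cohort.data["ancestry"].to_numpy()),
            cohort.pc_matrix(),
        )
        l2 = fit_mixing_weights(pd.DataFrame({"cad": sv_l1.standardized}), y, covs,
                                constants={"cad": c_l1}, layer=2)
        flat = flatten_weights({"cad": l1}, l2, {("cad", n): comps[n] for n in comps})
        sv_flat, _, _ = score_cohort(cohort, flat)

        explicit = l2.beta["cad"] * sv_l1.standardized
        r = np.corrcoef(sv_flat.standardized, explicit)[0, 1]
        assert r > 1 - 1e-10

    def test_identity_combination_proportional(self, cohort_trio, effects_trio):
        ws = _weightset_from_cohort(cohort_trio, effects_trio.effect_vector("EUR", "cad"))
        consts = StandardizationConstants(pc_coefs={}, mean={"ALL": 0.0}, sd={"ALL": 2.0})
        l1 = MixModel(1, ["EUR"], ["EUR"], {"EUR": 1.0}, {}, {"EUR": consts}, [0.0])
        l2 = MixModel(2, ["cad"], ["cad"], {"cad": 1.0}, {}, {"cad": consts}, [0.0])
        flat = flatten_weights({"cad": l1}, l2, {("cad", "EUR"): ws})
        merged = flat.table.merge(ws.table, on="rsID", suffixes=("_flat", "_orig"))
        merged = merged[merged["effect_weight_orig"] != 0]
        ratio = merged["effect_weight_flat"] / merged["effect_weight_orig"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_disjoint_union(self):
        rows1 = [("v1", 1, 1, "A", "G", 0.5), ("v2", 1, 2, "A", "G", -0.25)]
        rows2 = [("v3", 1, 3, "T", "C", 0.75)]
        cols = ["rsID", "chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight"]
        wsa = WeightSet(table=pd.DataFrame(rows1, columns=cols))
        wsb = WeightSet(table=pd.DataFrame(rows2, columns=cols))
        consts = StandardizationConstants(pc_coefs={}, mean={"ALL": 0.0}, sd={"ALL": 1.0})
        l1 = MixModel(1, ["A1", "A2"], ["A1", "A2"], {"A1": 1.0, "A2": 2.0}, {},
                      {"A1": consts, "A2": consts}, [0.0])
        l2 = MixModel(2, ["t"], ["t"], {"t": 1.0}, {}, {"t": consts}, [0.0])
        flat = flatten_weights({"t": l1}, l2, {("t", "A1"): wsa, ("t", "A2"): wsb})
        assert set(flat.table["rsID"]) == {"v1", "v2", "v3"}
        w = flat.table.set_index("rsID")["effect_weight"]
        assert w["v1"] == pytest.approx(0.5)
        assert w["v3"] == pytest.approx(1.5)

    def test_allele_conflict_resolution(self):
        cols = ["rsID", "chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight"]
        wsa = WeightSet(table=pd.DataFrame([("v1", 1, 1, "A", "G", 0.5)], columns=cols))
        # same variant, swapped orientation: contributes negated weight
        wsb = WeightSet(table=pd.DataFrame([("v1", 1, 1, "G", "A", 0.2)], columns=cols))
        consts = StandardizationConstants(pc_coefs={}, mean={"ALL": 0.0}, sd={"ALL": 1.0})
        l1 = MixModel(1, ["A1", "A2"], ["A1", "A2"], {"A1": 1.0, "A2": 1.0}, {},
                      {"A1": consts, "A2": consts}, [0.0])
        l2 = MixModel(2, ["t"], ["t"], {"t": 1.0}, {}, {"t": consts}, [0.0])
        flat = flatten_weights({"t": l1}, l2, {("t", "A1"): wsa, ("t", "A2"): wsb})
        assert flat.table.set_index("rsID")["effect_weight"]["v1"] == pytest.approx(0.3)

    def test_roundtrip_through_writer(self, tmp_path, cohort_trio, effects_trio):
        from polymix.shrink import read_weightset, write_weightset

        ws = _weightset_from_cohort(cohort_trio, effects_trio.effect_vector("EUR", "cad"))
        consts = StandardizationConstants(pc_coefs={}, mean={"ALL": 0.0}, sd={"ALL": 1.3})
        l1 = MixModel(1, ["EUR"], ["EUR"], {"EUR": 0.7}, {}, {"EUR": consts}, [0.0])
        l2 = MixModel(2, ["cad"], ["cad"], {"cad": 1.1}, {}, {"cad": consts}, [0.0])
        flat = flatten_weights({"cad": l1}, l2, {("cad", "EUR"): ws})
        path = write_weightset(flat, tmp_path / "flat.tsv")
        back = read_weightset(path)
        assert np.array_equal(back.weights, flat.weights)
        assert (back.table["rsID"] == flat.table["rsID"]).all()
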