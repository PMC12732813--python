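"""Logistic pCR modelling, ROC/Youden operating point, responder triage."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import her2mtgx as hx
from her2mtgx.response_model import SeparationError


def simulate_logit(n=400, beta=0.8, strata=True, seed=0):
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame({"her2": rng.normal(0, 1, n),
                           "luminal": rng.normal(0, 1, n)})
    strat = pd.Series(rng.choice(["A", "B", "C"], n, p=[0.5, 0.3, 0.2])) \
        if strata else None
    offs = {"A": 0.0, "B": 0.3, "C": -0.3}
    eta = -0.2 + beta * scores["her2"] - 0.4 * scores["luminal"]
    if strata:
        eta = eta + strat.map(offs)
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return scores, strat, y


class TestFitLogistic:
    def test_recovers_planted_coefficient(self):
        scores, strat, y = simulate_logit(n=1000, beta=0.8, seed=1)
        fit = hx.fit_logistic(scores, y, strata=strat)
        est, se = fit.coefficients["her2"], fit.se["her2"]
        assert abs(est - 0.8) < 3 * se

    def test_single_stratum_equals_unstratified(self):
        scores, _, y = simulate_logit(n=300, strata=False, seed=2)
        one = pd.Series(["only"] * len(y))
        f1 = hx.fit_logistic(scores, y)
        f2 = hx.fit_logistic(scores, y, strata=one)
        pd.testing.assert_series_equal(f1.coefficients, f2.coefficients,
                                       atol=1e-8)

    def test_odds_ratio_is_exp_coefficient(self):
        scores, strat, y = simulate_logit(seed=3)
        fit = hx.fit_logistic(scores, y, strata=strat)
        np.testing.assert_allclose(fit.odds_ratios["or"],
                                   np.exp(fit.coefficients))
        assert (fit.odds_ratios["ci_low"] <= fit.odds_ratios["ci_high"]).all()

    def test_perfect_separation_rejected(self):
        scores = pd.DataFrame({"her2": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            hx.fit_logistic(scores, y)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(4)
        s = rng.normal(0, 1, 100)
        scores = pd.DataFrame({"a": s, "b": 2 * s})
        y = rng.binomial(1, 0.5, 100)
        with pytest.raises(ValueError, match="singular"):
            hx.fit_logistic(scores, y)

    def test_null_model_type_one_control(self):
        """With no true score effect the 95% CI covers OR=1 in >=93% of
        replicates (light version: 50 seeds, one score)."""
        cover = 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            scores = pd.DataFrame({"her2": rng.normal(0, 1, 400)})
            y = rng.binomial(1, 0.4, 400)
            fit = hx.fit_logistic(scores, y)
            lo, hi = fit.odds_ratios.loc["her2", ["ci_low", "ci_high"]]
            cover += lo <= 1.0 <= hi
        assert cover / 50 >= 0.88


class TestCompareModels:
    def test_identical_models_p_one(self):
        scores, strat, y = simulate_logit(seed=5)
        fit = hx.fit_logistic(scores, y, strata=strat)
        assert hx.compare_models(fit, fit) == 1.0

    def test_strong_effect_detected(self):
        scores, strat, y = simulate_logit(n=800, beta=1.2, seed=6)
        full = hx.fit_logistic(scores, y, strata=strat)
        reduced = hx.fit_logistic(scores[["luminal"]], y, strata=strat)
        assert hx.compare_models(reduced, full) < 0.001

    def test_different_n_rejected(self):
        scores, strat, y = simulate_logit(n=200, seed=7)
        f1 = hx.fit_logistic(scores, y, strata=strat)
        f2 = hx.fit_logistic(scores.iloc[:100], y[:100],
                             strata=strat.iloc[:100])
        with pytest.raises(ValueError):
            hx.compare_models(f2, f1)

    def test_non_nested_rejected(self):
        scores, strat, y = simulate_logit(n=200, seed=8)
        f1 = hx.fit_logistic(scores[["her2"]], y)
        f2 = hx.fit_logistic(scores[["luminal"]], y)
        with pytest.raises(ValueError):
            hx.compare_models(f1, f2)


def pair_counting_auc(probs, y):
    pos = probs[y == 1]
    neg = probs[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = hx.roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert r.youden_j == pytest.approx(1.0)

    def test_matches_pair_counting(self):
        p = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        r = hx.roc_analysis(p, y)
        assert r.auc == pytest.approx(pair_counting_auc(p, y), abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(9)
        p = rng.random(60)
        y = rng.binomial(1, 0.5, 60)
        a1 = hx.roc_analysis(p, y).auc
        a2 = hx.roc_analysis(p, 1 - y).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_rank_sum_transform(self):
        rng = np.random.default_rng(10)
        p = rng.random(80)
        y = rng.binomial(1, 0.4, 80)
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        u = rankdata(p)[y == 1].sum() - n1 * (n1 + 1) / 2
        assert hx.roc_analysis(p, y).auc == pytest.approx(u / (n1 * n0),
                                                          abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hx.roc_analysis([0.1, 0.9], [1, 1])

    def test_tie_breaks_to_lower_threshold(self):
        # thresholds 0.2 and 0.8 both give J=0.5 here; 0.2 must win
        r = hx.roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 1, 0, 1])
        assert r.threshold == pytest.approx(0.2)


class TestClassifyResponders:
    def test_rule_and_partition(self):
        y = np.array([1, 0] * 20)
        probs = np.linspace(0.05, 0.95, 40)
        calls, summary = hx.classify_responders(probs, y, alpha=0.01)
        iv = summary.interval
        cls = calls["responder_class"]
        assert ((calls["probability"] > iv.upper) == (cls == "good")).all()
        assert ((calls["probability"] < iv.lower) == (cls == "bad")).all()
        assert sum(summary.counts.values()) == 40

    def test_all_inside_band_all_regular(self):
        y = np.array([1, 0] * 10)
        probs = np.full(20, 0.5)
        calls, summary = hx.classify_responders(probs, y, alpha=0.01)
        assert summary.counts == {"good": 0, "regular": 20, "bad": 0}
        assert summary.ppv is None and summary.npv is None

    def test_boundary_equality_is_regular(self):
        y = np.array([1, 0] * 10)
        iv = hx.wald_interval(0.5, 20, 0.01)
        probs = np.full(20, iv.upper)
        calls, _ = hx.classify_responders(probs, y, alpha=0.01)
        assert (calls["responder_class"] == "regular").all()

    def test_shrinking_band_never_moves_into_regular(self):
        rng = np.random.default_rng(11)
        y = rng.binomial(1, 0.4, 200)
        probs = rng.random(200)
        # smaller alpha -> larger z -> wider band -> larger regular class
        wide, _ = hx.classify_responders(probs, y, alpha=0.01)
        narrow, _ = hx.classify_responders(probs, y, alpha=0.1)
        moved = (narrow["responder_class"] == "regular") & \
                (wide["responder_class"] != "regular")
        assert not moved.any()

    def test_good_class_enriched_under_strong_effect(self):
        rng = np.random.default_rng(12)
        eta = rng.normal(0, 2, 500)
        p_true = 1 / (1 + np.exp(-eta))
        y = rng.binomial(1, p_true)
        scores = pd.DataFrame({"s": eta})
        fit = hx.fit_logistic(scores, y)
        calls, summary = hx.classify_responders(fit.predict(), y, alpha=0.01)
        assert summary.ppv > y.mean()

    def test_degenerate_rate_rejected(self):
        with pytest.raises(ValueError):
            hx.classify_responders(np.full(5, 0.5), np.ones(5, dtype=int))


class TestCompareClassifiers:
    def test_identical_classifiers_p_one(self):
        t = np.array([1, 1, 1, 0, 0])
        a = np.array([1, 0, 1, 0, 1])
        p, info = hx.compare_classifiers(a, a, t)
        assert p == 1.0
        assert info["no_discordant"]

    def test_one_sided_discordance_closed_form(self):
        t = np.ones(12, dtype=int)
        a = np.r_[np.ones(10, dtype=int), [0, 0]]
        b = np.r_[np.zeros(10, dtype=int), [0, 0]]
        p, info = hx.compare_classifiers(a, b, t)
        assert info["n10"] == 10 and info["n01"] == 0
        assert p == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    def test_order_invariant(self):
        rng = np.random.default_rng(13)
        t = rng.binomial(1, 0.5, 50)
        a = rng.binomial(1, 0.5, 50)
        b = rng.binomial(1, 0.5, 50)
        perm = rng.permutation(50)
        p1, _ = hx.compare_classifiers(a, b, t)
        p2, _ = hx.compare_classifiers(a[perm], b[perm], t[perm])
        assert p1 == pytest.approx(p2)
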