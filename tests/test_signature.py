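"""Gene-level ANOVA, FDR, sigmoid clipping, exclusive selection, scoring."""

import numpy as np
import pandas as pd
import pytest

import her2mtgx as hx
from her2mtgx.signature import GeneModel, MODULES


def groups9():
    return np.repeat(["HER2", "Basal", "Luminal"], 3)


class TestGeneAnova:
    def test_noise_free_gene_r2_one(self):
        x = np.repeat([5.0, 1.0, 2.0], 3)
        m = hx.fit_gene_anova(x, groups9())
        assert m.r2 == pytest.approx(1.0)
        assert m.pvalue == pytest.approx(0.0, abs=1e-12)

    def test_equal_group_means_r2_zero(self):
        x = np.array([1.0, 2.0, 3.0] * 3)  # same values in every group
        m = hx.fit_gene_anova(x, groups9())
        assert m.r2 == pytest.approx(0.0, abs=1e-12)
        assert all(abs(b) < 1e-12 for b in m.coefficients.values())

    def test_toy_matches_brute_force(self):
        x = np.array([7.1, 6.8, 7.4, 2.2, 2.0, 2.6, 4.1, 3.9, 4.4])
        g = groups9()
        m = hx.fit_gene_anova(x, g)
        # independent sums-of-squares computation
        means = {k: x[g == k].mean() for k in MODULES}
        grand = x.mean()
        ss_b = sum(3 * (means[k] - grand) ** 2 for k in MODULES)
        ss_t = ((x - grand) ** 2).sum()
        ss_w = ss_t - ss_b
        f = (ss_b / 2) / (ss_w / 6)
        center = np.mean(list(means.values()))
        assert m.f_statistic == pytest.approx(f, abs=1e-10)
        assert m.r2 == pytest.approx(ss_b / ss_t, abs=1e-10)
        for k in MODULES:
            assert m.coefficients[k] == pytest.approx(means[k] - center,
                                                      abs=1e-10)
        assert sum(m.coefficients.values()) == pytest.approx(0.0, abs=1e-10)

    def test_small_group_rejected(self):
        g = np.array(["HER2", "HER2", "Basal", "Basal", "Luminal"])
        with pytest.raises(ValueError):
            hx.fit_gene_anova(np.arange(5.0), g)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            hx.fit_gene_anova(np.ones(9), groups9())


class TestFdr:
    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(hx.adjust_fdr([0.2, 0.2, 0.2]),
                                   [0.2, 0.2, 0.2])

    def test_hand_bh_example(self):
        # q_i = min over j>=i of p_j * n / j  ->  all 0.04 here
        np.testing.assert_allclose(hx.adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_bounded_by_one(self):
        assert hx.adjust_fdr([0.5, 0.9, 0.99]).max() <= 1.0

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValueError):
            hx.adjust_fdr([0.5, 1.2])


class TestClip:
    def test_odd_at_zero(self):
        assert hx.clip_coefficient(0.0) == 0.0

    def test_asymptote(self):
        assert hx.clip_coefficient(1e6) == pytest.approx(3.0)
        assert abs(hx.clip_coefficient(50.0)) < 3.0

    def test_threshold_crossing_point(self):
        # 2.7 = 3*tanh(beta/3) inverts to beta = 3*atanh(0.9)
        beta = 3.0 * np.arctanh(0.9)
        assert beta == pytest.approx(4.4166, abs=5e-4)
        assert hx.clip_coefficient(beta) == pytest.approx(2.7, abs=1e-12)

    def test_strictly_monotone(self):
        b = np.linspace(-10, 10, 101)
        assert np.all(np.diff(hx.clip_coefficient(b)) > 0)


def _model(gene, clipped, r2=0.9, p=1e-6):
    inv = {k: 3.0 * np.arctanh(np.clip(v / 3.0, -0.999999, 0.999999))
           for k, v in clipped.items()}
    return GeneModel(gene=gene, coefficients=inv,
                     clipped=dict(clipped), r2=r2, f_statistic=50.0, pvalue=p)


class TestSelection:
    def test_rule_application(self):
        m = _model("A", {"HER2": 2.9, "Basal": -1.0, "Luminal": -1.9})
        sig = hx.select_informative_genes([m])
        assert sig.modules["HER2"] == [("A", pytest.approx(2.9))]

    def test_exclusivity_excludes_second_positive(self):
        m = _model("B", {"HER2": 2.9, "Basal": 0.1, "Luminal": -3.0})
        sig = hx.select_informative_genes([m])
        assert sig.genes() == []

    def test_quality_filters(self):
        good = {"HER2": 2.9, "Basal": -1.0, "Luminal": -1.9}
        low_r2 = _model("C", good, r2=0.2)
        high_q = _model("D", good, p=0.5)
        sig = hx.select_informative_genes([low_r2, high_q])
        assert sig.genes() == []

    def test_raising_w_min_never_adds(self):
        rng = np.random.default_rng(15)
        models = []
        for i in range(200):
            c = {k: float(np.clip(rng.normal(0, 2), -2.99, 2.99))
                 for k in MODULES}
            models.append(_model(f"g{i}", c))
        prev = None
        for w_min in (2.0, 2.4, 2.7, 2.9):
            got = set(hx.select_informative_genes(models, w_min=w_min).genes())
            if prev is not None:
                assert got <= prev
            prev = got

    def test_recovery_on_synthetic_cohort(self, default_cohort):
        counts, _, _, truth = default_cohort
        tpm = hx.compute_tpm(counts)
        sig = hx.build_signature(tpm, truth.group_labels)
        planted = truth.module_membership
        n_hit = sum(len(set(sig.genes(m)) & set(planted[m])) for m in MODULES)
        n_planted = sum(len(planted[m]) for m in MODULES)
        n_false = len(sig.genes()) - n_hit
        assert n_hit / n_planted >= 0.9
        assert n_false <= 0.01 * max(1, len(sig.genes()))


class TestScoring:
    def expr(self, genes, n=6, seed=16):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(0, 1, (len(genes), n)), index=genes,
                            columns=[f"s{i}" for i in range(n)])

    def sig3(self, w=(1.0, 1.0)):
        return hx.SignatureModel(modules={
            "HER2": [("h1", w[0]), ("h2", w[1])],
            "Basal": [("b1", 1.0)],
            "Luminal": [("l1", 1.0)],
        })

    def test_equal_weights_plain_mean(self):
        expr = self.expr(["h1", "h2", "b1", "l1"])
        ms = hx.score_samples(expr, self.sig3())
        z = expr.sub(expr.mean(axis=1), axis=0).div(
            expr.std(axis=1, ddof=0), axis=0)
        np.testing.assert_allclose(ms.scores["HER2"],
                                   z.loc[["h1", "h2"]].mean(axis=0))

    def test_single_gene_module_is_that_z(self):
        expr = self.expr(["h1", "h2", "b1", "l1"])
        ms = hx.score_samples(expr, self.sig3())
        row = expr.loc["b1"]
        z = (row - row.mean()) / row.std(ddof=0)
        np.testing.assert_allclose(ms.scores["Basal"], z)

    def test_missing_gene_dropped_with_warning(self):
        expr = self.expr(["h1", "b1", "l1"])
        with pytest.warns(UserWarning, match="h2"):
            ms = hx.score_samples(expr, self.sig3())
        assert ms.dropped_genes == {"HER2": ["h2"]}

    def test_empty_module_rejected(self):
        expr = self.expr(["h1", "h2", "b1"])
        with pytest.raises(ValueError, match="Luminal"):
            hx.score_samples(expr, self.sig3())

    def test_gene_order_and_nonmodule_duplication_invariance(self):
        expr = self.expr(["h1", "h2", "b1", "l1", "x1"])
        ms1 = hx.score_samples(expr, self.sig3())
        shuffled = expr.iloc[::-1]
        extra = pd.concat([shuffled, expr.loc[["x1"]].rename(
            index={"x1": "x2"})])
        ms2 = hx.score_samples(extra, self.sig3())
        pd.testing.assert_frame_equal(ms1.scores, ms2.scores)

    def test_profile_tie_priority(self):
        # b1 and l1 identical -> Basal and Luminal scores tie exactly;
        # the tie must resolve to Basal (priority HER2 > Basal > Luminal)
        row = np.array([3.0, 1.0, 2.0, 5.0])
        expr = pd.DataFrame([-row, row, row],
                            index=["h1", "b1", "l1"],
                            columns=[f"s{i}" for i in range(4)])
        sig = hx.SignatureModel(modules={"HER2": [("h1", 1.0)],
                                         "Basal": [("b1", 1.0)],
                                         "Luminal": [("l1", 1.0)]})
        ms = hx.score_samples(expr, sig)
        above = ms.scores["Basal"] > ms.scores["HER2"]
        assert (ms.profile[above] == "Basal").all()
        assert (ms.profile[~above] == "HER2").all()

    def test_her2_score_separates_planted_group(self, default_cohort):
        counts, _, _, truth = default_cohort
        tpm = hx.compute_tpm(counts)
        sig = hx.build_signature(tpm, truth.group_labels)
        ms = hx.score_samples(np.log2(tpm + 1.0), sig)
        is_her2 = (truth.group_labels == "HER2").astype(int)
        roc = hx.roc_analysis(ms.scores["HER2"], is_her2)
        assert roc.auc > 0.95
        # argmax profile recovers the planted groups almost perfectly
        agreement = (ms.profile == truth.group_labels).mean()
        assert agreement > 0.95


class TestPublishedBundle:
    def test_thirty_one_genes(self):
        sig = hx.bundle_published_signature()
        assert len(sig.genes()) == 31
        assert [len(sig.modules[m]) for m in MODULES] == [8, 7, 16]

    def test_marker_memberships(self):
        sig = hx.bundle_published_signature()
        assert "ERBB2" in sig.genes("HER2")
        assert "ESR1" in sig.genes("Luminal")

    def test_modules_disjoint(self):
        sig = hx.bundle_published_signature()
        genes = sig.genes()
        assert len(genes) == len(set(genes))

    def test_unit_weights(self):
        sig = hx.bundle_published_signature()
        assert all(w == 1.0 for m in MODULES for _, w in sig.modules[m])
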