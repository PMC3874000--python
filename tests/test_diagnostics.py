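"""Diagnostics: probit transform, ROC, likelihood ratios, logistic pairs."""

import numpy as np
import pytest
from scipy import optimize
from scipy import stats as sps

from ihcquant.diagnostics import (
    binormal_roc,
    empirical_roc,
    fit_logistic_pair,
    operating_point,
    probit_transform,
)
from ihcquant.stats import mann_whitney_u


class TestProbit:
    def test_median_maps_to_zero(self):
        assert probit_transform([50.0])[0] == pytest.approx(0.0)

    def test_upper_tail_quantile(self):
        assert probit_transform([97.5])[0] == pytest.approx(1.959964, abs=1e-4)

    def test_strictly_monotone(self):
        x = np.linspace(0, 100, 51)
        t = probit_transform(x)
        assert np.all(np.diff(t) > 0)
        assert np.isfinite(t).all()  # boundary values clamped

    def test_rank_int_mode(self):
        x = np.array([5.0, 1.0, 3.0])
        t = probit_transform(x, mode="rank_INT")
        expected = sps.norm.ppf((sps.rankdata(x) - 0.5) / 3)
        np.testing.assert_allclose(t, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            probit_transform([101.0])

    def test_roc_invariant_under_probit(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 100, 60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        a1 = empirical_roc(scores, labels).auc_empirical
        a2 = empirical_roc(probit_transform(scores), labels).auc_empirical
        assert a1 == pytest.approx(a2)


class TestEmpiricalRoc:
    def test_pair_counting_example(self):
        scores = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        assert empirical_roc(scores, labels).auc_empirical == pytest.approx(0.75)

    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1])
        roc = empirical_roc(scores, labels)
        assert roc.auc_empirical == 1.0

    def test_endpoints_and_monotone_points(self):
        rng = np.random.default_rng(5)
        roc = empirical_roc(rng.normal(size=30), rng.integers(0, 2, 30))
        pts = np.array([(s, f) for _, s, f, _, _ in roc.operating_points])
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_auc_equals_rank_statistic_identity(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=40)
        labels = np.array([0] * 25 + [1] * 15)
        roc = empirical_roc(scores, labels)
        u, _ = mann_whitney_u(scores[labels == 1], scores[labels == 0],
                              method="normal_approx")
        assert roc.auc_empirical == pytest.approx(u / (25 * 15))

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = empirical_roc(scores, labels).auc_empirical
        with np.errstate(all="ignore"):
            b = empirical_roc(-scores, labels).auc_empirical
        assert a == pytest.approx(1.0 - b)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 1, 200)])
        labels = np.array([0] * 200 + [1] * 200)
        rng.shuffle(labels)
        roc_auc = empirical_roc(scores, labels).auc_empirical
        assert abs(roc_auc - 0.5) <= 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1.0, 2.0], [1, 1])


class TestBinormalRoc:
    def test_equal_means_half_auc(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(0, 1, 100)
        labels = np.array([0, 1] * 50)
        _, _, auc = binormal_roc(scores, labels)
        a, _, _ = binormal_roc(scores, labels)
        assert abs(auc - 0.5) < 0.1
        # exact symmetry when moments match by construction
        s = np.concatenate([scores, scores])
        y = np.array([0] * 100 + [1] * 100)
        a, b, auc = binormal_roc(s, y)
        assert (a, b) == (0.0, 1.0)
        assert auc == pytest.approx(0.5)

    def test_closed_form_unit_shift(self):
        # per-class moments m0=0, s0=1, m1=1, s1=1 -> AUC = Phi(1/sqrt(2))
        rng = np.random.default_rng(17)
        n = 100_000
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        labels = np.array([0] * n + [1] * n)
        a, b, auc = binormal_roc(scores, labels)
        assert auc == pytest.approx(sps.norm.cdf(1 / np.sqrt(2)), abs=0.01)
        # simulation consistency: empirical AUC close to binormal AUC
        emp = empirical_roc(scores, labels).auc_empirical
        assert abs(emp - auc) <= 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            binormal_roc([1.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])


class TestOperatingPoint:
    def test_direct_formula(self):
        # sens 0.7, spec 0.6 -> LR+ = 1.75
        pos = np.concatenate([np.full(7, 2.0), np.full(3, 0.0)])
        neg = np.concatenate([np.full(6, 0.5), np.full(4, 2.0)])
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 10 + [0] * 10)
        sens, spec, lr_plus, lr_minus = operating_point(scores, labels, 1.0)
        assert (sens, spec) == (0.7, 0.6)
        assert lr_plus == pytest.approx(1.75)
        assert lr_minus == pytest.approx(0.3 / 0.6)

    def test_perfect_specificity_flags_infinite_lr(self):
        scores = np.array([1.0, 1.0, 3.0, 0.5, 0.5])
        labels = np.array([1, 1, 1, 0, 0])
        sens, spec, lr_plus, _ = operating_point(scores, labels, 2.0)
        assert spec == 1.0
        assert np.isinf(lr_plus)

    def test_counting_oracle(self):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        c = float(np.median(scores))
        sens, spec, _, _ = operating_point(scores, labels, c)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        assert sens == pytest.approx(sum(1 for v in pos if v > c) / len(pos))
        assert spec == pytest.approx(sum(1 for v in neg if v <= c) / len(neg))


def nll(beta, X, y):
    eta = X @ beta
    return np.sum(np.logaddexp(0.0, eta) - y * eta)


class TestLogisticPair:
    def test_null_predictors_give_chance_accuracy(self):
        rng = np.random.default_rng(23)
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = np.array([0, 1] * (n // 2))
        model = fit_logistic_pair(x1, x2, y)
        assert abs(model.pct_correct - 50.0) <= 10.0

    def test_separable_clusters_flagged_and_perfect(self):
        x1 = np.concatenate([np.zeros(20), np.ones(20) * 10])
        x2 = np.concatenate([np.zeros(20), np.ones(20) * 10])
        y = np.array([0] * 20 + [1] * 20)
        model = fit_logistic_pair(x1, x2, y)
        assert model.separation_flag
        assert model.pct_correct == 100.0

    def test_coefficients_match_direct_likelihood_maximization(self):
        rng = np.random.default_rng(29)
        n = 120
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        eta = -0.3 + 0.8 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_logistic_pair(x1, x2, y)
        assert not model.separation_flag
        X = np.column_stack([np.ones(n), x1, x2])
        res = optimize.minimize(nll, np.zeros(3), args=(X, y), method="BFGS",
                                options={"gtol": 1e-10})
        np.testing.assert_allclose(
            [model.beta0, model.beta1, model.beta2], res.x, atol=1e-4
        )

    def test_adding_informative_marker_keeps_accuracy(self):
        """Combining two informative markers never loses more than noise vs one."""
        rng = np.random.default_rng(31)
        n = 300
        y = np.array([0, 1] * (n // 2)).astype(float)
        x1 = rng.gamma((1.66 + y * 2.43) ** 2 / 3.4, scale=1.0)
        x2 = rng.normal(y * 1.0, 1.0)
        solo = fit_logistic_pair(x1, np.zeros(n), y)
        pair = fit_logistic_pair(x1, x2, y)
        assert pair.pct_correct >= solo.pct_correct - 3.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_pair([1.0, 2.0], [1.0, 2.0], [1, 1])
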