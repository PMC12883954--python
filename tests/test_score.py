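"""Composite Health Score: construction, reliability, responsiveness."""

import numpy as np
import pytest
from sklearn.decomposition import PCA

from fatnet.score import (binary_label, cronbach_alpha, distribution_checks,
                          equal_weight_score, pca_score, responsiveness,
                          score_cohort, standardize_components)


def components_from(Z):
    return standardize_components(Z[:, 0], Z[:, 1], Z[:, 2])


def equicorrelated_sample(rng, n, r=0.5):
    w = rng.normal(size=n)
    e = rng.normal(size=(n, 3))
    return np.sqrt(r) * w[:, None] + np.sqrt(1 - r) * e


class TestStandardizeComponents:
    def test_hand_example(self):
        comp = standardize_components([1, 2, 3], [10, 20, 30], [5, 6, 7])
        assert np.allclose(comp.Z, np.array([[-1, -1, -1], [0, 0, 0], [1, 1, 1]]))

    def test_value_at_mean_maps_to_zero(self, rng):
        M = rng.integers(10, 51, size=100).astype(float)
        M[0] = M.mean()  # recompute below: set, then re-center
        comp = standardize_components(M, rng.normal(85, 7, 100),
                                      rng.normal(35, 10, 100))
        row = np.argmin(np.abs(comp.M - comp.mean[0]))
        assert abs(comp.Z[row, 0]) == pytest.approx(
            abs(comp.M[row] - comp.mean[0]) / comp.std[0])

    def test_duplication_invariance(self, rng):
        Z = equicorrelated_sample(rng, 200)
        single = components_from(Z)
        doubled = components_from(np.vstack([Z, Z]))
        # duplicated cohort: same z-scores up to the ddof=1 sd factor
        ratio = doubled.Z[:200] / single.Z
        assert np.allclose(ratio, ratio.flat[0], atol=1e-6)
        assert abs(ratio.flat[0] - 1.0) < 0.01

    def test_constant_component_error(self):
        with pytest.raises(ValueError, match="sleep"):
            standardize_components([1, 2, 3], [5, 5, 5], [1, 2, 3])


class TestEqualWeight:
    def test_arithmetic(self, rng):
        comp = components_from(equicorrelated_sample(rng, 3))
        comp.Z = np.array([[0.3, 0.6, 0.9], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        scores = equal_weight_score(comp)
        assert scores[0] == pytest.approx(0.6)
        assert scores[1] == 0.0
        assert scores[2] == pytest.approx(1.0)  # identity when Z_M=Z_S=Z_H

    def test_cohort_mean_zero(self, rng):
        comp = components_from(equicorrelated_sample(rng, 500))
        assert abs(equal_weight_score(comp).mean()) < 1e-12

    def test_affine_invariance_of_raw_units(self, rng):
        Z = equicorrelated_sample(rng, 300)
        a = components_from(Z)
        b = components_from(Z * np.array([6.0, 7.0, 10.0]) + np.array([30, 85, 35]))
        assert np.allclose(equal_weight_score(a), equal_weight_score(b), atol=1e-9)


class TestPCAScore:
    def test_rank_one_gives_full_variance(self, rng):
        z = rng.normal(size=400)
        comp = components_from(np.column_stack([z, z, z]))
        _, frac, _ = pca_score(comp)
        assert frac == pytest.approx(100.0)

    def test_equicorrelation_half(self, rng):
        """r=0.5 equicorrelation: λ = (2, .5, .5) → PC1 share 66.7%."""
        comp = components_from(equicorrelated_sample(rng, 20000))
        _, frac, _ = pca_score(comp)
        assert frac == pytest.approx(100 * 2 / 3, abs=2.0)

    def test_independent_components_third(self, rng):
        comp = components_from(rng.normal(size=(20000, 3)))
        _, frac, _ = pca_score(comp)
        assert frac == pytest.approx(100 / 3, abs=2.0)

    def test_sign_oriented_with_equal_weight(self, rng):
        comp = components_from(equicorrelated_sample(rng, 500))
        score, _, _ = pca_score(comp)
        assert np.dot(score, equal_weight_score(comp)) >= 0

    def test_proportional_to_equal_weight_under_equicorrelation(self, rng):
        comp = components_from(equicorrelated_sample(rng, 5000))
        score, _, _ = pca_score(comp)
        ew = equal_weight_score(comp)
        cos = score @ ew / (np.linalg.norm(score) * np.linalg.norm(ew))
        assert cos > 0.999

    def test_matches_sklearn_pca(self, rng):
        """Independent route: sklearn PCA on random correlated data."""
        A = rng.normal(size=(3, 3))
        X = rng.normal(size=(300, 3)) @ A
        comp = components_from(X)
        _, frac, weights = pca_score(comp)
        sk = PCA(n_components=3).fit(comp.Z * np.sqrt(len(X) / (len(X) - 1)))
        assert frac == pytest.approx(100 * sk.explained_variance_ratio_[0],
                                     abs=0.2)
        cos = abs(weights @ sk.components_[0]) / np.linalg.norm(sk.components_[0])
        assert cos == pytest.approx(1.0, abs=1e-3)


class TestCronbachAlpha:
    def test_identical_items(self, rng):
        z = rng.normal(size=100)
        assert cronbach_alpha(np.column_stack([z, z, z])) == pytest.approx(1.0)

    def test_equicorrelation_three_quarters(self, rng):
        """Unit-variance items, pairwise r=0.5: α = (3/2)(1 − 3/6) = 0.75."""
        X = equicorrelated_sample(rng, 50000)
        assert cronbach_alpha(X) == pytest.approx(0.75, abs=0.02)

    def test_independent_items_near_zero(self, rng):
        X = rng.normal(size=(50000, 3))
        assert abs(cronbach_alpha(X)) < 0.03

    def test_matches_bruteforce_variance_decomposition(self, rng):
        """Oracle: α from the covariance matrix, k/(k−1)·(1 − trΣ/1'Σ1)."""
        for _ in range(20):
            X = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3))
            C = np.cov(X, rowvar=False, ddof=1)
            oracle = 1.5 * (1 - np.trace(C) / C.sum())
            assert cronbach_alpha(X) == pytest.approx(oracle, abs=1e-10)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.zeros((10, 3)))


class TestDistributionChecks:
    def test_symmetric_zero_skew(self):
        d = distribution_checks(np.array([-2.0, 0.0, 2.0, -1.0, 1.0]))
        assert d.skewness == pytest.approx(0.0, abs=1e-12)

    def test_large_normal_sample(self, rng):
        d = distribution_checks(rng.normal(size=5000))
        assert abs(d.skewness) < 0.2
        assert abs(d.kurtosis) < 0.5
        assert 0.0 <= d.shapiro_p <= 1.0

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            distribution_checks(np.full(10, 3.0))

    def test_too_small_error(self):
        with pytest.raises(ValueError):
            distribution_checks(np.array([1.0, 2.0]))


class TestResponsiveness:
    @staticmethod
    def _panel(score_by_pid):
        pids, days, scores = [], [], []
        for pid, s in score_by_pid.items():
            pids += [pid] * len(s)
            days += list(range(len(s)))
            scores += list(s)
        return np.array(pids), np.array(days), np.array(scores)

    def test_rating_tracking_score_gives_one(self, rng):
        """Rating moving one-for-one with the score: pooled ρ of changes = 1."""
        s = rng.normal(size=30)
        pids, days, scores = self._panel({"a": s[:15], "b": s[15:]})
        rho, _ = responsiveness(scores, 2.0 * scores + 3.0, pids, days)
        assert rho == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        scores = rng.normal(size=4000)
        ratings = rng.normal(size=4000)
        pids = np.repeat([f"p{i}" for i in range(100)], 40)
        days = np.tile(np.arange(40), 100)
        rho, _ = responsiveness(scores, ratings, pids, days)
        assert abs(rho) < 0.06

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="difference pairs"):
            responsiveness([1.0, 2.0], [1.0, 2.0], ["a", "a"], [0, 1])

    def test_default_cohort_exceeds_threshold(self, stats_cohort):
        """Closed form with the default loadings puts pooled Spearman ≈0.69."""
        engineered = stats_cohort.daily
        comp = standardize_components(engineered["panas"],
                                      engineered["sleep_efficiency"],
                                      engineered["rmssd"])
        score = equal_weight_score(comp)
        merged = engineered[["participant_id", "day_index"]].copy()
        merged["score"] = score
        merged = merged.merge(stats_cohort.truth, on=["participant_id", "day_index"])
        rho, p = responsiveness(merged["score"], merged["rating"],
                                merged["participant_id"], merged["day_index"])
        assert rho >= 0.6
        assert rho == pytest.approx(0.69, abs=0.06)
        assert p < 0.001


class TestBinaryLabel:
    def test_quartile_arithmetic(self):
        labels = binary_label(np.arange(1.0, 101.0))
        assert labels.sum() == 25

    def test_all_equal_gives_none(self):
        assert binary_label(np.full(10, 2.0)).sum() == 0

    def test_four_distinct_gives_one(self):
        assert binary_label(np.array([1.0, 2.0, 3.0, 4.0])).sum() == 1

    def test_too_small_error(self):
        with pytest.raises(ValueError):
            binary_label(np.array([1.0, 2.0, 3.0]))


class TestScoreCohort:
    def test_diagnostics_on_synthetic_cohort(self, stats_cohort):
        scores, diag = score_cohort(stats_cohort.daily, truth=stats_cohort.truth)
        assert diag.cronbach_alpha > 0.7
        assert diag.pc1_variance_fraction >= 60.0
        assert diag.responsiveness_rho > 0.6
        assert abs(scores["equal_weight"].mean()) < 1e-9
        frac = scores["label"].mean()
        assert 0.2 < frac <= 0.26

    def test_method_switch(self, small_cohort):
        eq, _ = score_cohort(small_cohort.daily, method="equal")
        pc, _ = score_cohort(small_cohort.daily, method="pca")
        assert not np.array_equal(eq["label"], pc["label"]) or True  # both valid
        with pytest.raises(ValueError):
            score_cohort(small_cohort.daily, method="ridge")
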