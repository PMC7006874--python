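"""Tests of pairwise/partial correlations, level composites, the
closed-form composite correlation, off-diagonal means and the bootstrap
ordering test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vascade.cascade import (
    DEFAULT_LEVEL_SPEC,
    bonferroni_alpha,
    bootstrap_cascade,
    build_level_composites,
    cascade_analysis,
    cascade_from_matrix,
    closed_form_composite_corr,
    level_matrix_from_R,
    offdiag_means,
    paired_t_segregation,
    partial_correlation,
    partial_correlation_closed_form,
    pearson_one_tailed,
)
from vascade.synthetic import CascadeParams, generate_subjects

LATENT_SPEC = [[("vascular", 1)], [("structure", 1)],
               [("function", 1)], [("cognition", 1)]]


def _subject_frame(rng, n=60) -> pd.DataFrame:
    """Correlated variables covering the default level spec."""
    base = rng.standard_normal(n)
    def noisy(w, scale=1.0):
        return scale * (w * base + np.sqrt(1 - w**2) * rng.standard_normal(n))
    return pd.DataFrame({
        "prefx": noisy(0.6, 0.1),
        "cortical_thickness": noisy(0.5, 0.2) + 2.5,
        "wmsa": -noisy(0.5, 1.0),
        "assoc_segregation": noisy(0.55, 0.2) + 0.4,
        "sm_segregation": noisy(0.35, 0.2) + 0.3,
        "episodic_memory": noisy(0.45),
        "reasoning": noisy(0.5),
    })


class TestPearsonOneTailed:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(30)
        r, p = pearson_one_tailed(x, 2 * x + 1, "positive")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_t_distribution_oracle(self, rng):
        x = rng.standard_normal(40)
        y = 0.4 * x + rng.standard_normal(40)
        r, p = pearson_one_tailed(x, y, "positive")
        n = 40
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert p == pytest.approx(float(stats.t.sf(t, n - 2)), abs=1e-12)
        # scipy's two-sided p halves to the one-tailed value for r > 0
        r_sp, p_sp = stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp / 2, abs=1e-10)

    def test_wrong_direction_gives_large_p(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + 0.5 * rng.standard_normal(40)
        _, p = pearson_one_tailed(x, y, "negative")
        assert p >= 0.5

    def test_pairwise_complete_drops_missing(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        x_miss = x.copy()
        x_miss[3] = np.nan
        r_full, _ = pearson_one_tailed(x[np.arange(30) != 3],
                                       y[np.arange(30) != 3], "positive")
        r_miss, _ = pearson_one_tailed(x_miss, y, "positive")
        assert r_miss == pytest.approx(r_full, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_one_tailed(np.ones(10), np.arange(10.0), "positive")


class TestPartialCorrelation:
    def test_residual_method_equals_closed_form(self, rng):
        x = rng.standard_normal(50)
        z = 0.5 * x + rng.standard_normal(50)
        y = 0.4 * x + 0.3 * z + rng.standard_normal(50)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        assert partial_correlation(x, y, z) == pytest.approx(
            partial_correlation_closed_form(rxy, rxz, ryz), abs=1e-12)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(50)
        z = rng.standard_normal((50, 2))
        y = 0.4 * x + 0.3 * z[:, 0] + rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        expected = pingouin.partial_corr(df, x="x", y="y",
                                         covar=["z1", "z2"])["r"].iloc[0]
        assert partial_correlation(x, y, z) == pytest.approx(expected, abs=1e-9)

    def test_published_age_partial_matches_table(self, study_R):
        """Partialing age out of the pulse-elasticity/lesion correlation
        via the closed form reproduces the published age-partialed value
        to last-digit rounding (-0.180)."""
        r = partial_correlation_closed_form(
            study_R.loc["prefx", "wmsa"],
            study_R.loc["prefx", "age"],
            study_R.loc["wmsa", "age"])
        assert r == pytest.approx(-0.181, abs=5e-4)
        assert r == pytest.approx(-0.180, abs=2e-3)

    def test_uncorrelated_covariate_leaves_r(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)
        assert partial_correlation(x, y, z) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_collinear_covariates_rejected(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        z = rng.standard_normal(30)
        with pytest.raises(ValueError):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestPairedT:
    def test_identical_vectors(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError):
            paired_t_segregation(x, x)  # zero-variance differences

    def test_matches_textbook_formula(self, rng):
        a = rng.standard_normal(25)
        b = a + 0.3 + 0.5 * rng.standard_normal(25)
        t, p = paired_t_segregation(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), d.size - 1),
                                  abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t_segregation(np.ones(5), np.ones(6))


class TestBonferroni:
    def test_six_constructs(self):
        assert bonferroni_alpha(0.05, 6) == pytest.approx(0.05 / 6)
        assert round(bonferroni_alpha(0.05, 6), 4) == 0.0083

    @pytest.mark.parametrize("alpha, m, expected", [
        (0.05, 1, 0.05), (0.05, 5, 0.01),
    ])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 6)


class TestLevelComposites:
    def test_single_variable_level_is_signed_z(self, rng):
        df = _subject_frame(rng)
        comp = build_level_composites(df)
        z = (df["prefx"] - df["prefx"].mean()) / df["prefx"].std(ddof=0)
        assert np.allclose(comp["vascular"], z)

    def test_sign_flip_encoded_in_spec(self, rng):
        df = _subject_frame(rng)
        spec = [[("prefx", -1)], *DEFAULT_LEVEL_SPEC[1:]]
        a = build_level_composites(df)
        b = build_level_composites(df, spec)
        assert np.allclose(a["vascular"], -b["vascular"])

    def test_duplicated_variable_composite_correlates_one(self, rng):
        df = _subject_frame(rng)
        df["prefx2"] = 3.0 * df["prefx"] - 1.0
        spec = [[("prefx", 1), ("prefx2", 1)], *DEFAULT_LEVEL_SPEC[1:]]
        comp = build_level_composites(df, spec)
        assert np.corrcoef(comp["vascular"], df["prefx"])[0, 1] == \
            pytest.approx(1.0)

    def test_missing_variable_rejected(self, rng):
        df = _subject_frame(rng).drop(columns="reasoning")
        with pytest.raises(ValueError, match="reasoning"):
            build_level_composites(df)


class TestClosedFormCompositeCorr:
    def test_single_variable_levels_return_entry(self, study_R):
        r = closed_form_composite_corr(study_R, [("prefx", 1)],
                                       [("assoc_segregation", 1)])
        assert r == pytest.approx(0.525)

    def test_vascular_to_cognition_two_apart(self, study_R):
        """(0.234 + 0.092)/sqrt(2 + 2*0.431) rounds to .19."""
        r = closed_form_composite_corr(
            study_R, [("prefx", 1)],
            [("episodic_memory", 1), ("reasoning", 1)])
        assert r == pytest.approx((0.234 + 0.092) / np.sqrt(2 + 2 * 0.431),
                                  abs=1e-12)
        assert round(abs(r), 2) == 0.19

    def test_identity_with_subject_level_computation(self, rng):
        """Closed form on the sample correlation matrix equals the
        subject-level composite correlation exactly."""
        df = _subject_frame(rng, n=80)
        cols = [v for level in DEFAULT_LEVEL_SPEC for v, _ in level]
        R = df[cols].corr()
        comp = build_level_composites(df)
        sample = np.corrcoef(comp.to_numpy(), rowvar=False)
        closed = level_matrix_from_R(R)
        assert np.allclose(sample, closed, atol=1e-12)

    def test_non_positive_variance_rejected(self):
        R = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            closed_form_composite_corr(R, [("a", 1), ("b", 1)], [("a", 1)])


class TestOffdiagMeans:
    def test_hand_matrix(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.5
        m[1, 2] = m[2, 1] = 0.6
        m[2, 3] = m[3, 2] = 0.55
        m[0, 2] = m[2, 0] = 0.4
        m[1, 3] = m[3, 1] = 0.45
        m[0, 3] = m[3, 0] = 0.2
        m1, m2, m3 = offdiag_means(m)
        assert (m1, m2, m3) == (pytest.approx(0.55), pytest.approx(0.425),
                                pytest.approx(0.2))

    def test_equal_entries_equal_means(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        m1, m2, m3 = offdiag_means(m)
        assert m1 == m2 == m3 == pytest.approx(0.3)

    def test_published_matrix_reproduces_printed_summary(self, study_R):
        """The 2-off mean rounds to .45 and the 3-off value to .19."""
        result = cascade_from_matrix(study_R)
        assert round(result.m_raw[1], 2) == 0.45
        assert round(result.m_raw[2], 2) == 0.19


class TestBootstrap:
    def _cohort(self, seed=0, n=80, paths=(-0.6, 0.7, 0.7, 0.7)):
        return generate_subjects(
            CascadeParams(n_subjects=n, path_coefficients=paths, seed=seed))

    def test_reproducible_under_seed(self):
        df = self._cohort()
        a = bootstrap_cascade(df, LATENT_SPEC, n_boot=300, seed=11)
        b = bootstrap_cascade(df, LATENT_SPEC, n_boot=300, seed=11)
        assert a.bootstrap_p == b.bootstrap_p

    def test_invariant_to_row_order(self):
        df = self._cohort()
        shuffled = df.sample(frac=1.0, random_state=4)
        a = bootstrap_cascade(df, LATENT_SPEC, n_boot=300, seed=11)
        b = bootstrap_cascade(shuffled, LATENT_SPEC, n_boot=300, seed=11)
        assert a.bootstrap_p == b.bootstrap_p

    def test_small_and_large_b_agree_within_binomial_error(self):
        df = self._cohort(seed=2, n=60, paths=(-0.4, 0.5, 0.5, 0.5))
        small = bootstrap_cascade(df, LATENT_SPEC, n_boot=200, seed=5)
        large = bootstrap_cascade(df, LATENT_SPEC, n_boot=10_000, seed=6)
        for key, p_large in large.bootstrap_p.items():
            se = np.sqrt(max(p_large * (1 - p_large), 1e-4) / 200)
            assert abs(small.bootstrap_p[key] - p_large) <= 3 * se + 1e-9

    def test_strong_cascade_orders_means(self):
        df = self._cohort(seed=3, n=200)
        res = bootstrap_cascade(df, LATENT_SPEC, n_boot=1000, seed=7)
        m1, m2, m3 = res.m_fisher
        assert m1 > m2 > m3
        assert res.bootstrap_p["m1_minus_m3"] < 0.05

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_cascade(self._cohort(n=5), LATENT_SPEC, n_boot=200)


def test_cascade_analysis_matches_direct_corrcoef(rng):
    df = _subject_frame(rng)
    res = cascade_analysis(df)
    comp = build_level_composites(df)
    assert np.allclose(res.matrix, np.corrcoef(comp.to_numpy(), rowvar=False))
    assert res.n == len(df)
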