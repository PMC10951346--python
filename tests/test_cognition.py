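"""d-prime, control-referenced z-scores, composites, age norms, outlier screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from tgckit import battery
from tgckit.cognition import (
    AgeNorm,
    AgeNormRegressor,
    ControlZScorer,
    age_corrected_z,
    composites,
    control_z,
    dprime,
    dprime_from_counts,
    fit_age_norm,
    impairment_label,
    remove_outliers,
    score_cohort,
)


class TestDprime:
    @pytest.mark.parametrize("h,f,expected,tol", [
        (0.5, 0.5, 0.0, 1e-12),
        (0.841345, 0.158655, 2.0, 1e-4),
        (0.9, 0.1, 2.5631, 1e-3),
    ])
    def test_reference_values(self, h, f, expected, tol):
        assert dprime(h, f) == pytest.approx(expected, abs=tol)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_antisymmetry(self, h, f):
        assert dprime(h, f) == pytest.approx(-dprime(f, h), abs=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dprime(1.2, 0.5)

    def test_extreme_rate_correction(self):
        # 60/60 hits -> 1 - 1/120; 0/120 false alarms -> 1/240
        expected = norm.ppf(1 - 1 / 120) - norm.ppf(1 / 240)
        assert dprime_from_counts(60, 0, 0, 120) == pytest.approx(expected)

    def test_boundary_rate_rejected_without_correction(self):
        with pytest.raises(ValueError, match="infinite"):
            dprime(1.0, 0.1)


@pytest.fixture(scope="module")
def scorer(cohort):
    return ControlZScorer().fit(cohort[cohort["group"] == "control"])


class TestControlZ:
    def test_control_sample_standardised(self, cohort, scorer):
        z = scorer.transform(cohort[cohort["group"] == "control"])
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1).abs(), 1.0, atol=1e-12)

    def test_raw_at_control_mean_is_zero(self, scorer):
        assert control_z(scorer.means_["bnt_correct"], scorer, "bnt_correct") == 0.0

    def test_one_sd_above_mean(self, scorer):
        raw = scorer.means_["bnt_correct"] + scorer.sds_["bnt_correct"]
        assert control_z(raw, scorer, "bnt_correct") == pytest.approx(1.0)

    def test_higher_is_worse_flipped(self, scorer):
        t = "tmt_a_time_per_connection"
        raw = scorer.means_[t] + scorer.sds_[t]  # one SD slower
        assert control_z(raw, scorer, t) == pytest.approx(-1.0)

    def test_unknown_test_rejected(self, scorer):
        with pytest.raises(KeyError):
            control_z(0.0, scorer, "nonexistent_test")


class TestComposites:
    def test_all_zero(self):
        z = pd.DataFrame(0.0, index=range(3), columns=list(battery.TESTS))
        out = composites(z)
        assert (out == 0.0).all().all()

    def test_verbal_memory_mean(self):
        z = pd.DataFrame(0.0, index=[0], columns=list(battery.TESTS))
        z.loc[0, ["cvlt_total_recall", "cvlt_dprime", "cvlt_pct_retained"]] = [1, 0, -1]
        assert composites(z).loc[0, "verbal_memory"] == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_mean_oracle(self, seed):
        r = np.random.default_rng(seed)
        z = pd.DataFrame(
            r.standard_normal((4, len(battery.TESTS))), columns=list(battery.TESTS)
        )
        out = composites(z)
        for d in battery.DOMAINS:
            members = battery.tests_in_domain(d)
            np.testing.assert_allclose(out[d], z[members].mean(axis=1))
        np.testing.assert_allclose(
            out["global_cognition"], out[list(battery.DOMAINS)].mean(axis=1)
        )

    def test_permutation_invariance_within_domain(self, rng):
        z = pd.DataFrame(
            rng.standard_normal((5, len(battery.TESTS))), columns=list(battery.TESTS)
        )
        shuffled = z[list(reversed(z.columns))]
        pd.testing.assert_frame_equal(composites(z), composites(shuffled))

    def test_empty_domain_flags_global_missing(self):
        cols = [t for t in battery.TESTS if battery.DOMAIN_MAP[t] != "language"]
        z = pd.DataFrame(0.0, index=[0], columns=cols)
        out = composites(z)
        assert np.isnan(out.loc[0, "language"])
        assert np.isnan(out.loc[0, "global_cognition"])


class TestAgeNorm:
    def test_perfect_linear_data_is_degenerate(self):
        ages = np.array([60.0, 65.0, 70.0, 75.0, 80.0])
        with pytest.raises(ValueError, match="degenerate|residual"):
            fit_age_norm(ages, 2.0 - 0.02 * ages)

    def test_parameter_recovery(self, rng):
        n = 10_000
        ages = rng.uniform(60, 85, n)
        d = 2.0 - 0.02 * ages + rng.normal(0, 0.5, n)
        norm_ = fit_age_norm(ages, d)
        assert norm_.intercept == pytest.approx(2.0, abs=0.05)
        assert norm_.slope == pytest.approx(-0.02, abs=0.001)
        assert norm_.resid_sd == pytest.approx(0.5, abs=0.02)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_age_norm([70.0, 75.0], [1.0, 0.5])

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_age_norm([70.0] * 5, [1.0, 0.9, 1.1, 1.2, 0.8])

    def test_applied_back_to_controls(self, rng):
        n = 500
        ages = rng.uniform(60, 85, n)
        d = 2.0 - 0.02 * ages + rng.normal(0, 0.5, n)
        est = AgeNormRegressor().fit(ages, d)
        z = est.transform(ages, d)
        assert abs(z.mean()) < 1e-9
        # residual SD uses n-2, so the z SD (ddof=1) is sqrt((n-2)/(n-1))
        assert z.std(ddof=1) == pytest.approx(np.sqrt((n - 2) / (n - 1)), abs=1e-9)

    def test_shift_invariance(self, rng):
        ages = rng.uniform(60, 85, 200)
        d = 1.5 - 0.01 * ages + rng.normal(0, 0.4, 200)
        z1 = AgeNormRegressor().fit(ages, d).transform(ages, d)
        z2 = AgeNormRegressor().fit(ages, d + 5.0).transform(ages, d + 5.0)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_z_on_and_below_the_line(self):
        norm_ = AgeNorm(intercept=2.0, slope=-0.02, resid_sd=0.5, n_controls=50)
        assert age_corrected_z(2.0 - 0.02 * 70, 70.0, norm_) == pytest.approx(0.0)
        assert age_corrected_z(2.0 - 0.02 * 70 - 0.5, 70.0, norm_) == pytest.approx(-1.0)


class TestImpairmentLabel:
    @pytest.mark.parametrize("z,expected", [
        (-1.0, "impaired"),   # boundary is impaired
        (-0.999, "not_impaired"),
        (0.3, "not_impaired"),
        (-2.5, "impaired"),
    ])
    def test_boundary_convention(self, z, expected):
        assert impairment_label(z) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            impairment_label(np.nan)


class TestRemoveOutliers:
    def test_hand_computed_example(self):
        # {0,0,0,0,100}: mean 20, SD 44.7 -> 100 lies within 3 SD
        kept, removed = remove_outliers([0, 0, 0, 0, 100])
        assert list(kept) == [0, 0, 0, 0, 100]
        assert removed == []

    def test_normal_tail_fraction(self, rng):
        v = rng.standard_normal(10_000)
        kept, removed = remove_outliers(v)
        frac = len(removed) / len(v)
        assert 0.0005 < frac < 0.01  # ~0.27% beyond 3 SD

    def test_zero_variance_unchanged(self):
        kept, removed = remove_outliers([5.0, 5.0, 5.0, 5.0])
        assert list(kept) == [5.0] * 4 and removed == []

    def test_removed_ids_logged(self):
        vals = np.concatenate([np.zeros(50), [1000.0]])
        ids = [f"P{i}" for i in range(51)]
        _, removed = remove_outliers(vals, ids=ids)
        assert removed == ["P50"]


class TestScoreCohort:
    def test_score_columns_present(self, scored):
        for col in ("dprime_2back", "age_corrected_z", "impairment",
                    "global_cognition", *battery.DOMAINS):
            assert col in scored.columns

    def test_controls_near_zero_patients_impaired(self, scored):
        ctrl = scored[scored["group"] == "control"]
        pat = scored[scored["group"] != "control"]
        assert abs(ctrl["global_cognition"].mean()) < 0.2
        assert pat["global_cognition"].mean() < -0.5
        assert pat["age_corrected_z"].mean() < ctrl["age_corrected_z"].mean()

    def test_impairment_consistent_with_z(self, scored):
        imp = scored["impairment"] == "impaired"
        np.testing.assert_array_equal(imp, scored["age_corrected_z"] <= -1.0)
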