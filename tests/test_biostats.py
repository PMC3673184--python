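import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cdexposure import (
    compare_groups,
    geometric_mean,
    lod_substitute,
    lognormal_from_gm_sd,
    pct_over_threshold,
    ratio_report,
    summarize_cohort,
)


class TestLodSubstitution:
    def test_below_lod_becomes_lod_over_sqrt2(self):
        assert lod_substitute(0.02) == pytest.approx(0.05 / np.sqrt(2))

    def test_detected_values_unchanged(self):
        assert lod_substitute(0.40) == 0.40

    def test_value_at_lod_is_detected(self):
        # substitution applies strictly below the limit
        assert lod_substitute(0.05) == 0.05

    def test_vectorised(self):
        out = lod_substitute([0.01, 0.05, 1.0])
        np.testing.assert_allclose(out, [0.05 / np.sqrt(2), 0.05, 1.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lod_substitute(-0.1)


class TestGeometricMean:
    def test_log_spaced_sample(self):
        assert geometric_mean([1, 10, 100]) == pytest.approx(10.0)

    def test_constant_sample(self):
        assert geometric_mean([2.7, 2.7, 2.7]) == pytest.approx(2.7)

    def test_monte_carlo_lognormal(self):
        rng = np.random.default_rng(11)
        sample = rng.lognormal(np.log(2.10), 0.8, size=100_000)
        assert geometric_mean(sample) == pytest.approx(2.10, rel=0.01)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            geometric_mean([1.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1e4, allow_nan=False), min_size=1, max_size=30)
    )
    def test_never_exceeds_arithmetic_mean(self, values):
        assert geometric_mean(values) <= np.mean(values) * (1 + 1e-12)


class TestLognormalInversion:
    def test_closed_form_example(self):
        pars = lognormal_from_gm_sd(0.40, 0.46)
        assert pars["mu"] == pytest.approx(np.log(0.40))
        assert pars["sigma"] == pytest.approx(0.74960, abs=1e-4)

    def test_zero_sd_is_degenerate(self):
        assert lognormal_from_gm_sd(1.5, 0.0)["sigma"] == 0.0

    def test_moments_round_trip_by_simulation(self):
        gm, sd = 2.10, 2.91
        pars = lognormal_from_gm_sd(gm, sd)
        rng = np.random.default_rng(3)
        sample = rng.lognormal(pars["mu"], pars["sigma"], size=400_000)
        assert geometric_mean(sample) == pytest.approx(gm, rel=0.01)
        assert np.std(sample, ddof=1) == pytest.approx(sd, rel=0.03)

    def test_analytic_round_trip(self):
        # the inversion is the exact inverse of the (GM, SD) moment map
        for gm, sd in [(0.33, 0.36), (1.04, 1.61), (3.07, 3.79)]:
            pars = lognormal_from_gm_sd(gm, sd)
            mu, s2 = pars["mu"], pars["sigma"] ** 2
            assert np.exp(mu) == pytest.approx(gm, rel=1e-12)
            var = np.exp(2 * mu + s2) * (np.exp(s2) - 1)
            assert np.sqrt(var) == pytest.approx(sd, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            lognormal_from_gm_sd(0.0, 1.0)
        with pytest.raises(ValueError):
            lognormal_from_gm_sd(1.0, -1.0)


class TestThresholdExceedance:
    def test_all_below(self):
        assert pct_over_threshold([0.1, 0.2], 1.0) == 0.0

    def test_inclusive_bound(self):
        assert pct_over_threshold([1.0, 1.0], 1.0) == 100.0

    def test_matches_analytic_lognormal_tail(self):
        mu, sigma, tau = np.log(1.5), 0.8, 2.0
        rng = np.random.default_rng(5)
        sample = rng.lognormal(mu, sigma, size=100_000)
        expected = 100 * (1 - stats.norm.cdf((np.log(tau) - mu) / sigma))
        assert pct_over_threshold(sample, tau) == pytest.approx(expected, abs=0.6)


class TestCompareGroups:
    @staticmethod
    def _frame(**groups):
        return pd.concat(
            [
                pd.DataFrame({"smoking_category": name, "ucd_ug_per_g": values})
                for name, values in groups.items()
            ],
            ignore_index=True,
        )

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.1, 50)
        report = compare_groups(self._frame(a=base, b=base), "smoking_category")
        assert not report["significant"]

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.5, 200)
        report = compare_groups(
            self._frame(never=base, heavy=10 * base), "smoking_category"
        )
        assert report["significant"] and report["p_value"] <= 0.05

    def test_dunnett_returns_k_minus_1_comparisons(self):
        rng = np.random.default_rng(2)
        groups = {
            name: rng.lognormal(0, 0.4, 40)
            for name in ("never", "former", "light_moderate", "heavy")
        }
        report = compare_groups(self._frame(**groups), "smoking_category")
        assert report["test"] == "anova+dunnett(log10)"
        assert report["reference"] == "never"
        assert len(report["comparisons"]) == 3

    def test_degenerate_group_reported_not_crashed(self):
        rng = np.random.default_rng(4)
        report = compare_groups(
            self._frame(a=np.full(10, 2.0), b=rng.lognormal(0, 0.3, 10)),
            "smoking_category",
        )
        assert report["degenerate"] == ["a"]

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            compare_groups(self._frame(a=[1.0, 2.0]), "smoking_category")


def test_type_one_error_rate_is_nominal():
    # two same-distribution groups, 1,000 replicates: rejections near 5%
    rng = np.random.default_rng(2024)
    rejections = 0
    n_sims = 1000
    for _ in range(n_sims):
        frame = pd.concat(
            [
                pd.DataFrame({"g": "a", "ucd_ug_per_g": rng.normal(1.0, 0.2, 30)}),
                pd.DataFrame({"g": "b", "ucd_ug_per_g": rng.normal(1.0, 0.2, 30)}),
            ],
            ignore_index=True,
        )
        rejections += compare_groups(frame, "g")["significant"]
    rate = 100 * rejections / n_sims
    assert 3.0 <= rate <= 7.0


class TestRatioReport:
    @staticmethod
    def _summary(rows):
        return pd.DataFrame(
            [
                {"locality": "bangkok", "sex": "male", "age_band": "40-59",
                 "smoking_category": cat, "gm": gm}
                for cat, gm in rows
            ]
        )

    def test_reported_ratios(self):
        out = ratio_report(self._summary([("never", 0.49), ("light_moderate", 0.92)]))
        assert out["ratio"].tolist() == [1.9]
        out = ratio_report(self._summary([("never", 1.50), ("heavy", 2.12)]))
        assert out["ratio"].tolist() == [1.4]

    def test_identity_ratio(self):
        out = ratio_report(self._summary([("never", 0.7), ("heavy", 0.7)]))
        assert out["ratio"].tolist() == [1.0]

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="never"):
            ratio_report(self._summary([("heavy", 2.12)]))


def test_summarize_cohort_basic():
    rng = np.random.default_rng(9)
    frame = pd.DataFrame(
        {
            "locality": "mae_sot",
            "sex": "female",
            "age_band": "40-59",
            "smoking_category": "never",
            "ucd_ug_per_g": rng.lognormal(np.log(2.0), 0.7, 500),
        }
    )
    out = summarize_cohort(frame)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["n"] == 500
    assert row["gm"] == pytest.approx(2.0, rel=0.1)
    assert 0 <= row["pct_ge_1"] <= 100
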