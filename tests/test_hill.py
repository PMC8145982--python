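import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hepoxy.hill import (
    REFERENCE_PIG,
    ConversionCoefficients,
    HillParams,
    apply_conversion,
    compare_models,
    derive_conversion,
    fit_hill,
    hill_so2,
    logit_reading,
    p50_from_scaled_form,
)

from .oracles import bisect_root

FITTED = HillParams(1.67, 34.0)


class TestHillCurve:
    def test_half_saturation_at_p50(self):
        assert hill_so2(REFERENCE_PIG.p50, REFERENCE_PIG) == pytest.approx(50.0)

    def test_limits(self):
        assert hill_so2(0.0, REFERENCE_PIG) == 0.0
        assert hill_so2(1e9, REFERENCE_PIG) == pytest.approx(100.0, abs=1e-6)

    def test_strictly_increasing(self):
        po2 = np.linspace(0.1, 400.0, 1000)
        assert np.all(np.diff(hill_so2(po2, REFERENCE_PIG)) > 0)

    def test_scaled_printed_form_matches_p50_form(self):
        """The two printed reference-curve forms agree to <0.01%."""
        assert p50_from_scaled_form() == pytest.approx(32.929, abs=5e-4)
        po2 = np.linspace(1.0, 300.0, 600)
        scaled = (0.13534 * po2) ** 3.02 / (91.2 + (0.13534 * po2) ** 3.02) * 100.0
        direct = hill_so2(po2, HillParams(3.02, p50_from_scaled_form()))
        np.testing.assert_allclose(scaled, direct, rtol=1e-10)


class TestLogit:
    def test_symmetry_point(self):
        assert logit_reading(50.0) == 0.0

    def test_antisymmetry(self):
        assert logit_reading(75.0) == pytest.approx(-logit_reading(25.0))

    def test_out_of_range_rejected(self):
        for v in (0.0, 100.0, -3.0):
            with pytest.raises(ValueError):
                logit_reading(v)

    def test_exact_linearization_of_hill_curve(self):
        """logit(hill) vs ln(PO2) has slope n and intercept -n ln(P50)."""
        params = HillParams(1.67, 34.0)
        po2 = np.linspace(5.0, 300.0, 80)
        slope, intercept = np.polyfit(np.log(po2), logit_reading(hill_so2(po2, params)), 1)
        assert slope == pytest.approx(1.67, abs=1e-6)
        assert intercept == pytest.approx(-1.67 * np.log(34.0), abs=1e-6)


class TestConversion:
    def test_identity_when_reference_equals_fitted(self):
        cc = derive_conversion(REFERENCE_PIG, REFERENCE_PIG)
        assert cc.c == pytest.approx(1.0) and cc.r == pytest.approx(1.0)
        v = np.linspace(1.0, 99.0, 50)
        np.testing.assert_allclose(apply_conversion(v, cc), v, rtol=1e-12)

    def test_printed_constants_from_printed_parameters(self):
        cc = derive_conversion(REFERENCE_PIG, FITTED)
        assert round(cc.r, 2) == 1.81
        assert round(cc.c, 2) == 1.10

    def test_composition_identity_on_po2_grid(self):
        """apply_conversion(hill(fitted)) equals hill(reference) to 10 decimals."""
        cc = derive_conversion(REFERENCE_PIG, FITTED)
        po2 = np.linspace(0.5, 400.0, 2000)
        lhs = apply_conversion(hill_so2(po2, FITTED), cc)
        rhs = hill_so2(po2, REFERENCE_PIG)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_inverse_composition_round_trip(self):
        fwd = derive_conversion(REFERENCE_PIG, FITTED)
        back = derive_conversion(FITTED, REFERENCE_PIG)
        v = np.linspace(0.5, 99.5, 200)
        np.testing.assert_allclose(
            apply_conversion(apply_conversion(v, fwd), back), v, atol=1e-10
        )

    def test_endpoints_fixed_and_strictly_increasing(self):
        cc = derive_conversion(REFERENCE_PIG, FITTED)
        assert apply_conversion(0.0, cc) == 0.0
        assert apply_conversion(100.0, cc) == 100.0
        v = np.linspace(0.1, 99.9, 500)
        assert np.all(np.diff(apply_conversion(v, cc)) > 0)

    def test_reading_mapping_to_half_saturation_by_bisection(self):
        """The reading converting to exactly 50% SO2, found by bisection,
        coincides with the fitted curve evaluated at the reference P50."""
        cc = derive_conversion(REFERENCE_PIG, FITTED)
        root = bisect_root(lambda v: apply_conversion(v, cc) - 50.0, 1.0, 99.0)
        assert apply_conversion(root, cc) == pytest.approx(50.0, abs=1e-9)
        assert root == pytest.approx(hill_so2(REFERENCE_PIG.p50, FITTED), abs=1e-8)

    @given(v=st.floats(0.5, 99.5))
    def test_conversion_stays_inside_percent_range(self, v):
        cc = derive_conversion(REFERENCE_PIG, FITTED)
        out = apply_conversion(v, cc)
        assert 0.0 < out < 100.0

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ConversionCoefficients(c=-1.0, r=1.0)


def _dataset(params_by_group, n=39, cv=0.0, seed=0, po2_range=(5.0, 300.0)):
    rng = np.random.default_rng(seed)
    po2 = np.exp(rng.uniform(np.log(po2_range[0]), np.log(po2_range[1]), n))
    groups = rng.choice(sorted(params_by_group), n)
    reading = np.array(
        [hill_so2(p, params_by_group[g]) for p, g in zip(po2, groups)]
    )
    if cv > 0:
        reading = np.clip(reading * (1 + rng.normal(0, cv, n)), 0.2, 99.8)
    else:
        reading = np.clip(reading, 1e-3, 100 - 1e-3)
    return pd.DataFrame({"po2": po2, "reading": reading, "ph_group": groups})


class TestFitHill:
    def test_noise_free_pooled_recovery(self):
        df = _dataset({"a": FITTED, "b": FITTED}, n=40, cv=0.0, seed=2)
        fit3 = fit_hill(df, model=3)
        assert fit3.pooled.n == pytest.approx(FITTED.n, abs=1e-6)
        assert fit3.pooled.p50 == pytest.approx(FITTED.p50, abs=1e-5)
        # per-group models coincide when the truth is shared
        fit1 = fit_hill(df, model=1)
        fit2 = fit_hill(df, model=2)
        for f in (fit1, fit2):
            for p in f.params.values():
                assert p.n == pytest.approx(FITTED.n, abs=1e-4)
                assert p.p50 == pytest.approx(FITTED.p50, abs=1e-3)

    def test_two_group_p50_recovery(self):
        truth = {"lo_ph": HillParams(1.9, 40.8), "hi_ph": HillParams(1.9, 32.7)}
        df = _dataset(truth, n=60, cv=0.0, seed=3)
        fit1 = fit_hill(df, model=1)
        assert fit1.params["lo_ph"].p50 == pytest.approx(40.8, abs=1e-3)
        assert fit1.params["hi_ph"].p50 == pytest.approx(32.7, abs=1e-3)
        shared_n = fit1.params["lo_ph"].n
        fit2 = fit_hill(df, model=2)
        for g in truth:
            assert fit2.params[g].n == pytest.approx(shared_n, abs=1e-3)

    def test_fix_n_constrains_coefficient(self):
        df = _dataset({"a": FITTED}, n=30, cv=0.01, seed=4)
        fit = fit_hill(df, model=3, fix_n=3.02)
        assert all(p.n == 3.02 for p in fit.params.values())
        assert fit.n_params == 1

    def test_insufficient_points_rejected(self):
        df = _dataset({"a": FITTED}, n=3, cv=0.0, seed=5)
        with pytest.raises(ValueError):
            fit_hill(df, model=3)

    def test_readings_at_bounds_rejected(self):
        df = pd.DataFrame({"po2": [10, 20, 30, 40], "reading": [0.0, 50, 60, 70]})
        with pytest.raises(ValueError):
            fit_hill(df, model=3)

    def test_logit_and_raw_fits_agree_noise_free(self):
        """In the noise-free limit the raw-scale fit matches the logit line."""
        df = _dataset({"a": FITTED}, n=40, cv=0.0, seed=6)
        fit = fit_hill(df, model=3)
        slope, intercept = np.polyfit(
            np.log(df["po2"]), logit_reading(df["reading"].to_numpy()), 1
        )
        assert fit.pooled.n == pytest.approx(slope, abs=1e-5)
        assert fit.pooled.p50 == pytest.approx(np.exp(-intercept / slope), abs=1e-4)


class TestCompareModels:
    def test_identical_fits_give_p_one(self):
        # two duplicated groups: the per-group model collapses onto the pooled one
        df = _dataset({"a": FITTED, "b": FITTED}, n=40, cv=0.0, seed=7)
        fit3 = fit_hill(df, model=3)
        fit1 = fit_hill(df, model=1)
        f, p = compare_models(fit3, fit1, df)
        assert f == pytest.approx(0.0, abs=1e-6)
        assert p > 0.999

    def test_strong_group_difference_detected(self):
        truth = {"lo": HillParams(2.5, 41.0), "hi": HillParams(2.9, 33.0)}
        df = _dataset(truth, n=60, cv=0.01, seed=8)
        f3 = fit_hill(df, model=3)
        f2 = fit_hill(df, model=2)
        _, p = compare_models(f3, f2, df)
        assert p < 0.001

    def test_rss_monotone_in_nesting(self):
        df = _dataset({"lo": HillParams(1.8, 38.0), "hi": HillParams(1.6, 31.0)}, n=50, cv=0.02, seed=9)
        f3, f1, f2 = fit_hill(df, 3), fit_hill(df, 1), fit_hill(df, 2)
        assert f3.rss >= f1.rss >= f2.rss

    def test_non_nested_pair_rejected(self):
        df = _dataset({"a": FITTED, "b": FITTED}, n=40, cv=0.01, seed=10)
        f2 = fit_hill(df, model=2)
        f1 = fit_hill(df, model=1)
        with pytest.raises(ValueError, match="nested"):
            compare_models(f2, f1, df)
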