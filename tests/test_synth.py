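import numpy as np
import pandas as pd
import pytest

from hepoxy.hill import HillParams, hill_so2
from hepoxy.stats import coefficient_of_variation, log_linear_fit
from hepoxy.synth import (
    HEPATIC_ARTERY,
    SELECTIVE_RIGHT_ARTERY,
    BypassExperimentSpec,
    OcclusionPhase,
    OcclusionScenario,
    PhantomSeriesSpec,
    make_bypass_dataset,
    make_hemodilution_dataset,
    make_occlusion_series,
    make_phantom_series,
)


@pytest.fixture(scope="module")
def series(grid, basis_hb_only, mc_record):
    return make_phantom_series(
        PhantomSeriesSpec(n_phantoms=16), seed=0, record=mc_record, basis=basis_hb_only
    )


class TestPhantomSeries:
    def test_reproducible_for_fixed_seed(self, grid, basis_hb_only, mc_record):
        a, _ = make_phantom_series(
            PhantomSeriesSpec(n_phantoms=2), 5, mc_record, basis_hb_only
        )
        b, _ = make_phantom_series(
            PhantomSeriesSpec(n_phantoms=2), 5, mc_record, basis_hb_only
        )
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.spectrum.values, sb.spectrum.values)

    def test_titration_monotonicity(self, series):
        samples, _ = series
        hb = [s.hb_um for s in samples]
        mus = [s.mean_mu_s_prime for s in samples]
        assert np.all(np.diff(hb) > 0)
        assert np.all(np.diff(mus) < 0)

    def test_absorption_range_endpoints(self, series):
        """Wavelength-mean mu_a spans the phantom design range."""
        samples, _ = series
        assert samples[0].mean_mu_a == pytest.approx(3.87, rel=0.2)
        assert samples[-1].mean_mu_a == pytest.approx(9.35, rel=0.2)
        assert samples[0].mean_mu_s_prime == pytest.approx(17.33, abs=1e-6)
        assert samples[-1].mean_mu_s_prime == pytest.approx(5.96, abs=1e-6)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSeriesSpec(hb_start_um=100.0, hb_end_um=50.0)

    def test_manifest_provenance(self, series):
        _, manifest = series
        assert manifest["seed"] == 0
        assert len(manifest["hb_um"]) == 16


class TestBypass:
    def test_zero_cv_lies_on_generating_curve(self):
        spec = BypassExperimentSpec(noise_cv=0.0)
        data = make_bypass_dataset(spec, seed=1)
        expected = hill_so2(data.table["po2"].to_numpy(), spec.generating)
        np.testing.assert_allclose(data.table["reading"], expected, rtol=1e-12)

    def test_replicate_cvs_land_in_reported_band(self):
        data = make_bypass_dataset(BypassExperimentSpec(), seed=2)
        cvs = [coefficient_of_variation(s) for s in data.replicate_sets]
        assert min(cvs) >= 0.7 - 0.25
        assert max(cvs) <= 1.6 + 0.25
        assert len(data.replicate_sets[0]) == 20

    def test_blood_gas_saturation_uses_reference_curve(self):
        spec = BypassExperimentSpec()
        data = make_bypass_dataset(spec, seed=3)
        np.testing.assert_allclose(
            data.table["so2_reference"],
            hill_so2(data.table["po2"].to_numpy(), spec.reference),
            rtol=1e-12,
        )

    def test_model3_recovery_single_dataset(self):
        from hepoxy.hill import fit_hill

        spec = BypassExperimentSpec()
        data = make_bypass_dataset(spec, seed=4)
        fit = fit_hill(data.table, model=3)
        assert fit.pooled.p50 == pytest.approx(spec.generating.p50, abs=3 * 1.2)
        assert fit.pooled.n == pytest.approx(spec.generating.n, abs=3 * 0.15)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            BypassExperimentSpec(noise_cv=0.2)


class TestOcclusion:
    def test_zero_noise_deltas_exact(self):
        scen = OcclusionScenario(noise_sd_pct=0.0)
        series, _ = make_occlusion_series(scen, seed=0)
        base = series[series["phase"] == "baseline"]["reading"].mean()
        occ = series[series["phase"] == "occlusion"]["reading"].mean()
        assert occ - base == pytest.approx(-44.4, abs=1e-9)

    def test_hepatic_artery_delta_across_seeds(self):
        """Estimated occlusion drop stays within the reported spread."""
        deltas = []
        for seed in range(50):
            series, _ = make_occlusion_series(HEPATIC_ARTERY, seed)
            sub = series[series["lobe"] == "monitored"]
            base = sub[sub["phase"] == "baseline"]["reading"].mean()
            occ = sub[sub["phase"] == "occlusion"]["reading"].mean()
            deltas.append(occ - base)
        assert np.mean(deltas) == pytest.approx(-44.4, abs=6.9)

    def test_selective_scenario_has_opposite_signed_lobes(self):
        series, _ = make_occlusion_series(SELECTIVE_RIGHT_ARTERY, seed=1)
        occ = series[series["phase"] == "occlusion"]
        right = occ[occ["lobe"] == "monitored"]["reading"].mean()
        left = occ[occ["lobe"] == "contralateral"]["reading"].mean()
        base = series[series["phase"] == "baseline"]
        rb = base[base["lobe"] == "monitored"]["reading"].mean()
        lb = base[base["lobe"] == "contralateral"]["reading"].mean()
        assert right - rb < 0 < left - lb

    def test_recovery_returns_to_baseline_mean(self):
        scen = OcclusionScenario(noise_sd_pct=0.0)
        series, _ = make_occlusion_series(scen, seed=0)
        rec = series[series["phase"] == "recovery"]["reading"].mean()
        assert rec == pytest.approx(scen.baseline_pct, abs=1e-9)

    def test_empty_scenario_rejected(self):
        with pytest.raises(ValueError):
            OcclusionScenario(phases=())


class TestHemodilution:
    def test_zero_noise_gives_unit_slope(self):
        df, _ = make_hemodilution_dataset(
            seed=0, analyzer_sd_g_dl=0.0, optical_proportional_sd=0.0
        )
        fit = log_linear_fit(df["hb_bloodgas_g_dl"], df["hb_visdrs_g_dl"])
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_default_r_squared_band_across_seeds(self):
        """Defaults emulate the in-vivo dispersion: R^2 in a broad 0.7-0.95 band."""
        r2 = []
        for seed in range(10):
            df, _ = make_hemodilution_dataset(seed=seed)
            r2.append(log_linear_fit(df["hb_bloodgas_g_dl"], df["hb_visdrs_g_dl"]).r_squared)
        assert all(0.7 <= v <= 0.95 for v in r2)

    def test_has_33_points_and_fio2_levels(self):
        df, _ = make_hemodilution_dataset(seed=1)
        assert len(df) == 33
        assert set(df["fio2"]) == {0.21, 0.3, 1.0}

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_hemodilution_dataset(n_points=3)
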