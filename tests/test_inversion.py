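import numpy as np
import pytest

from hepoxy.chromophores import ChromophoreConcentrations, OpticalProperties, compose_mu_a
from hepoxy.forward import scaled_reflectance
from hepoxy.inversion import (
    SCATTER_REF_WAVELENGTH,
    InversionConfig,
    ReferenceMeasurement,
    compare_biliverdin_modes,
    invert_spectrum,
    percent_error,
    phantom_cross_validation,
)
from hepoxy.scattering import power_law_mu_s_prime
from hepoxy.spectra import SpectralGrid, Spectrum
from hepoxy.synth import make_liver_spectrum_set


class TestPercentError:
    def test_exact_match_is_zero(self):
        assert percent_error(9.35, 9.35) == 0.0

    def test_arithmetic(self):
        assert percent_error(9.5235, 9.35) == pytest.approx(1.8556, abs=1e-3)

    def test_matches_independent_absolute_relative_oracle(self, rng):
        for _ in range(100):
            extracted = rng.uniform(0.1, 30.0)
            expected = rng.uniform(0.1, 30.0)
            oracle = abs(extracted - expected) / expected * 100.0
            assert percent_error(extracted, expected) == pytest.approx(oracle, rel=1e-12)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            percent_error(1.0, 0.0)


def _tissue_target(grid, basis, record, hb=120.0, so2=0.65, a=9.0, b=1.2, bili=0.0):
    conc = ChromophoreConcentrations(hb, so2, bili)
    mu_a = compose_mu_a(conc, basis, grid)
    mus = power_law_mu_s_prime(a, b, SCATTER_REF_WAVELENGTH, grid)
    props = OpticalProperties(grid, mu_a, mus)
    spectrum = Spectrum(grid, scaled_reflectance(record, props).reflectance)
    return props, spectrum


@pytest.fixture(scope="module")
def tissue_reference(grid, basis_hb_only, mc_record):
    props, spectrum = _tissue_target(
        grid, basis_hb_only, mc_record, hb=80.0, so2=0.9, a=12.0, b=1.0
    )
    return ReferenceMeasurement(props, spectrum, "tissue-ref")


class TestInvertSpectrum:
    def test_noise_free_round_trip(self, grid, basis_hb_only, mc_record, tissue_reference):
        """Self-consistency: parameters of a model-generated spectrum recover."""
        props, spectrum = _tissue_target(grid, basis_hb_only, mc_record)
        res = invert_spectrum(
            spectrum, tissue_reference, basis_hb_only, InversionConfig(), mc_record
        )
        assert res.converged
        assert res.concentrations.total_hb == pytest.approx(120.0, rel=0.01)
        assert abs(res.concentrations.so2 - 0.65) < 0.01
        assert res.mean_mu_a == pytest.approx(props.mean_mu_a, rel=0.01)
        assert res.mean_mu_s_prime == pytest.approx(props.mean_mu_s_prime, rel=0.02)

    def test_target_equals_reference(self, grid, basis_hb_only, mc_record, tissue_reference):
        res = invert_spectrum(
            tissue_reference.spectrum,
            tissue_reference,
            basis_hb_only,
            InversionConfig(),
            mc_record,
        )
        assert res.concentrations.total_hb == pytest.approx(80.0, rel=0.01)
        assert abs(res.concentrations.so2 - 0.9) < 0.01
        assert res.mean_mu_s_prime == pytest.approx(
            tissue_reference.props.mean_mu_s_prime, rel=0.02
        )

    def test_monotone_identifiability_in_hb(self, grid, basis_hb_only, mc_record, tissue_reference):
        recovered = []
        for hb in (60.0, 110.0, 160.0):
            _, spectrum = _tissue_target(grid, basis_hb_only, mc_record, hb=hb)
            res = invert_spectrum(
                spectrum, tissue_reference, basis_hb_only, InversionConfig(), mc_record
            )
            recovered.append(res.concentrations.total_hb)
        assert recovered[0] < recovered[1] < recovered[2]

    def test_grid_mismatch_rejected(self, grid, basis_hb_only, mc_record, tissue_reference):
        other = SpectralGrid(np.arange(450.0, 600.0))
        bad = Spectrum(other, np.ones(len(other)))
        with pytest.raises(ValueError, match="grid"):
            invert_spectrum(bad, tissue_reference, basis_hb_only, InversionConfig(), mc_record)

    def test_all_zero_spectrum_rejected(self, grid, basis_hb_only, mc_record, tissue_reference):
        zero = Spectrum(grid, np.zeros(len(grid)))
        with pytest.raises(ValueError, match="zero"):
            invert_spectrum(zero, tissue_reference, basis_hb_only, InversionConfig(), mc_record)


class TestCrossValidation:
    def test_singleton_set_rejected(self, grid, basis_hb_only, mc_record, tissue_reference):
        with pytest.raises(ValueError):
            phantom_cross_validation(
                [(tissue_reference.props, tissue_reference.spectrum)],
                basis_hb_only,
                InversionConfig(),
                mc_record,
            )

    def test_two_identical_phantoms_have_zero_error(self, grid, basis_hb_only, mc_record):
        props, spectrum = _tissue_target(grid, basis_hb_only, mc_record, hb=90.0, so2=1.0)
        cv = phantom_cross_validation(
            [(props, spectrum), (props, spectrum)],
            basis_hb_only,
            InversionConfig(),
            mc_record,
        )
        assert cv.avg_mu_a_percent_error < 0.1
        assert cv.avg_mu_s_prime_percent_error < 0.5


@pytest.fixture(scope="module")
def liver_reference(grid, basis, mc_record):
    props, spectrum = _tissue_target(
        grid, basis, mc_record, hb=80.0, so2=0.9, a=12.0, b=1.0, bili=0.0
    )
    return ReferenceMeasurement(props, spectrum, "liver-ref")


class TestBiliverdinModes:
    def test_bili_free_spectra_agree_between_modes(
        self, grid, basis, mc_record, liver_reference
    ):
        spectra, _, _ = make_liver_spectrum_set(
            mc_record, basis, hb_levels_um=(70.0, 130.0), biliverdin_um=0.0, seed=0
        )
        table = compare_biliverdin_modes(
            spectra, liver_reference, basis, InversionConfig(), mc_record
        )
        np.testing.assert_allclose(table["mu_a_with"], table["mu_a_without"], rtol=0.01)
        np.testing.assert_allclose(table["hb_with"], table["hb_without"], rtol=0.02)

    def test_omitting_biliverdin_biases_low_hb_scatter_most(
        self, grid, basis, mc_record, liver_reference
    ):
        """With real biliverdin in the tissue, the uncorrected inversion
        deviates more at low hemoglobin, mirroring the in-vivo behavior."""
        spectra, truths, _ = make_liver_spectrum_set(
            mc_record, basis, hb_levels_um=(40.0, 100.0), biliverdin_um=40.0, seed=0
        )
        table = compare_biliverdin_modes(
            spectra, liver_reference, basis, InversionConfig(), mc_record
        )
        assert table[[c for c in table.columns if c.startswith("converged")]].all().all()
        # corrected mode recovers the true hemoglobin
        for hb_fit, truth in zip(table["hb_with"], truths):
            assert hb_fit == pytest.approx(truth.total_hb, rel=0.02)
        # uncorrected mode is biased low: the missing absorber is absorbed
        # into less hemoglobin and less scattering
        hb_bias = table["hb_without"] - np.array([t.total_hb for t in truths])
        assert np.all(hb_bias < 0)
        musp_diff = np.abs(table["mu_s_prime_with"] - table["mu_s_prime_without"])
        assert musp_diff.iloc[0] > musp_diff.iloc[1]  # worst at low Hb

    def test_empty_dataset_rejected(self, basis, mc_record, liver_reference):
        with pytest.raises(ValueError):
            compare_biliverdin_modes([], liver_reference, basis, InversionConfig(), mc_record)
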