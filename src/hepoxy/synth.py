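"""Synthetic experiment generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure of the corresponding bench or animal experiment:

* a 16-phantom hemoglobin titration series (absorber rises 46.36 to
  112.01 uM while the fixed number of microspheres is diluted, so the mean
  reduced scattering falls 17.33 to 5.96 cm^-1), rendered to calibrated
  spectra through the forward model;
* extracorporeal-bypass saturation sweeps: (PO2, vis-DRS reading) pairs on
  a generating Hill curve with CV-level multiplicative noise, plus
  20-replicate steady-state sets for variability analysis;
* in-vivo hemodilution: paired blood-gas vs optically derived hemoglobin;
* vascular-occlusion time courses with per-phase saturation drops.

All generators are deterministic in their seed and return provenance
metadata (spec + seed) alongside the data. Readings are multiplicative-noise
quantities (the experiments report CV-of-mean stability); occlusion time
series use additive noise on the saturation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chromophores import (
    ChromophoreConcentrations,
    ExtinctionSpectrum,
    OpticalProperties,
    compose_mu_a,
)
from .forward import PhotonPathRecord, scaled_reflectance, self_calibrate
from .hill import HillParams, REFERENCE_PIG, hill_so2, PH_GROUPS
from .scattering import MiePhantomSpec, density_for_mean_mu_s_prime, mie_mu_s_prime
from .spectra import SpectralGrid, Spectrum


def _led_instrument_shape(grid: SpectralGrid) -> np.ndarray:
    """Broadband white-LED-like throughput shape (arbitrary units, positive)."""
    wl = grid.wavelengths
    blue = np.exp(-0.5 * ((wl - 450.0) / 12.0) ** 2)
    phosphor = np.exp(-0.5 * ((wl - 560.0) / 60.0) ** 2)
    return 0.8 * blue + phosphor + 0.05


# ---------------------------------------------------------------------------
# phantom titration series


@dataclass(frozen=True)
class PhantomSeriesSpec:
    """Successive Hb titration with fixed total sphere count.

    Each titration adds hemoglobin stock, growing the bath volume, so the
    Hb concentration rises while the sphere number density falls by the
    same volume factor (sphere number conserved).
    """

    n_phantoms: int = 16
    hb_start_um: float = 46.36
    hb_end_um: float = 112.01
    mu_s_prime_start: float = 17.33
    mu_s_prime_end: float = 5.96
    so2: float = 1.0
    sphere: MiePhantomSpec = field(default_factory=MiePhantomSpec)
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_phantoms < 2:
            raise ValueError("need at least 2 phantoms")
        if self.hb_end_um <= self.hb_start_um:
            raise ValueError("titration must increase Hb (end > start)")
        if self.mu_s_prime_end >= self.mu_s_prime_start:
            raise ValueError("titration must dilute scatterers (end < start)")


@dataclass
class PhantomSample:
    props: OpticalProperties
    spectrum: Spectrum  # calibrated (tissue channel / self-calibration channel)
    hb_um: float
    so2: float
    mean_mu_a: float
    mean_mu_s_prime: float


def make_phantom_series(
    spec: PhantomSeriesSpec,
    seed: int,
    record: PhotonPathRecord,
    basis: list[ExtinctionSpectrum],
    grid: SpectralGrid | None = None,
) -> tuple[list[PhantomSample], dict]:
    """Generate the titration series and its calibrated spectra.

    Volumes grow linearly across titrations by the factor that carries the
    wavelength-mean mu_s' from its start to its end value; the Hb stock
    concentration is solved so the endpoints match the spec. Measured
    spectra are forward-model reflectances times an LED instrument shape,
    divided by the concurrently "acquired" self-calibration channel, with
    optional multiplicative Gaussian noise.
    """
    grid = grid or SpectralGrid.default()
    rng = np.random.default_rng(seed)
    n = spec.n_phantoms
    vol_factor = spec.mu_s_prime_start / spec.mu_s_prime_end
    volumes = np.linspace(1.0, vol_factor, n)
    stock = (spec.hb_end_um * vol_factor - spec.hb_start_um) / (vol_factor - 1.0)
    hb = (spec.hb_start_um + stock * (volumes - 1.0)) / volumes

    d_start = density_for_mean_mu_s_prime(spec.sphere, grid, spec.mu_s_prime_start)
    unit_mus = mie_mu_s_prime(spec.sphere.with_density(d_start), grid)
    instrument = _led_instrument_shape(grid)
    selfcal = Spectrum(grid, instrument * 0.85, name="self-calibration")

    samples = []
    for i in range(n):
        mu_a = compose_mu_a(ChromophoreConcentrations(float(hb[i]), spec.so2), basis, grid)
        mus = unit_mus / volumes[i]
        props = OpticalProperties(grid, mu_a, mus)
        refl = scaled_reflectance(record, props).reflectance
        noise = 1.0 + rng.normal(0.0, spec.noise_cv, len(grid)) if spec.noise_cv > 0 else 1.0
        raw = Spectrum(grid, refl * instrument * noise, name=f"phantom_{i:02d}")
        cal = self_calibrate(raw, selfcal)
        samples.append(
            PhantomSample(
                props=props,
                spectrum=cal,
                hb_um=float(hb[i]),
                so2=spec.so2,
                mean_mu_a=props.mean_mu_a,
                mean_mu_s_prime=props.mean_mu_s_prime,
            )
        )
    manifest = {
        "generator": "make_phantom_series",
        "seed": seed,
        "spec": asdict(spec),
        "hb_um": hb.tolist(),
        "mean_mu_a": [s.mean_mu_a for s in samples],
        "mean_mu_s_prime": [s.mean_mu_s_prime for s in samples],
        "mc_seed": record.config.seed,
    }
    return samples, manifest


# ---------------------------------------------------------------------------
# ex-vivo bypass sweeps


@dataclass(frozen=True)
class BypassExperimentSpec:
    """Saturation sweep on extracorporeal perfusion.

    PO2 placement is log-uniform over ``po2_range`` so both shoulders of
    the dissociation sigmoid are populated (delivered O2 fraction spanned
    2-100% in the experiment, but the realized PO2 values are not fixed).
    Readings follow the generating Hill curve with multiplicative Gaussian
    noise at the steady-state CV level. Each condition also emits a
    20-replicate steady-state set.
    """

    n_points: int = 39
    po2_range_mmhg: tuple[float, float] = (5.0, 300.0)
    ph_groups: tuple[str, str] = PH_GROUPS
    hb_levels_g_dl: tuple[float, ...] = (12.0, 9.0, 6.0, 3.0)
    replicates_per_set: int = 20
    noise_cv: float = 0.0115
    generating: HillParams = field(default_factory=lambda: HillParams(1.67, 34.0))
    reference: HillParams = REFERENCE_PIG

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv <= 0.05:
            raise ValueError("noise CV must be within [0, 0.05]")
        if self.po2_range_mmhg[0] <= 0:
            raise ValueError("PO2 must be positive")


@dataclass
class BypassDataset:
    table: pd.DataFrame  # po2, reading, ph_group, hb_g_dl, so2_reference
    replicate_sets: list[np.ndarray]
    manifest: dict


def make_bypass_dataset(spec: BypassExperimentSpec, seed: int) -> BypassDataset:
    rng = np.random.default_rng(seed)
    n = spec.n_points
    lo, hi = spec.po2_range_mmhg
    po2 = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    ph = rng.choice(spec.ph_groups, n)
    hb = rng.choice(spec.hb_levels_g_dl, n)
    clean = hill_so2(po2, spec.generating)
    reading = clean * (1.0 + rng.normal(0.0, spec.noise_cv, n)) if spec.noise_cv > 0 else clean
    reading = np.clip(reading, 0.05, 99.95)
    table = pd.DataFrame(
        {
            "po2": po2,
            "reading": reading,
            "ph_group": ph,
            "hb_g_dl": hb,
            "so2_reference": hill_so2(po2, spec.reference),
        }
    )
    replicate_sets = [
        np.clip(c * (1.0 + rng.normal(0.0, spec.noise_cv, spec.replicates_per_set)), 0.05, 99.95)
        for c in clean
    ]
    manifest = {"generator": "make_bypass_dataset", "seed": seed, "spec": asdict(spec)}
    return BypassDataset(table, replicate_sets, manifest)


# ---------------------------------------------------------------------------
# vascular occlusion time courses


@dataclass(frozen=True)
class OcclusionPhase:
    label: str
    duration_s: float
    delta_pct: float  # saturation change vs baseline; 0 for baseline/recovery


@dataclass(frozen=True)
class OcclusionScenario:
    """Piecewise-constant saturation time course around vessel occlusions.

    Default effect sizes: hepatic-artery occlusion -44.4%, portal-vein
    occlusion -54.3%, selective right-artery occlusion -14.7% in the right
    lobe with +4.8% in the still-perfused left lobe.
    """

    phases: tuple[OcclusionPhase, ...] = (
        OcclusionPhase("baseline", 120.0, 0.0),
        OcclusionPhase("occlusion", 120.0, -44.4),
        OcclusionPhase("recovery", 120.0, 0.0),
    )
    baseline_pct: float = 75.0
    noise_sd_pct: float = 2.0
    sample_interval_s: float = 6.0
    contralateral_delta_pct: float | None = None  # second lobe, if selective

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("scenario needs at least one phase")
        if not 0.0 < self.baseline_pct < 100.0:
            raise ValueError("baseline saturation must be in (0, 100)")


HEPATIC_ARTERY = OcclusionScenario()
PORTAL_VEIN = OcclusionScenario(
    phases=(
        OcclusionPhase("baseline", 120.0, 0.0),
        OcclusionPhase("occlusion", 120.0, -54.3),
        OcclusionPhase("recovery", 120.0, 0.0),
    )
)
SELECTIVE_RIGHT_ARTERY = OcclusionScenario(
    phases=(
        OcclusionPhase("baseline", 120.0, 0.0),
        OcclusionPhase("occlusion", 120.0, -14.7),
        OcclusionPhase("recovery", 120.0, 0.0),
    ),
    contralateral_delta_pct=4.8,
)


def make_occlusion_series(scenario: OcclusionScenario, seed: int) -> tuple[pd.DataFrame, dict]:
    """Time series of (t, lobe, phase, reading) with additive noise.

    The monitored lobe follows the scenario's per-phase deltas; if
    ``contralateral_delta_pct`` is set, a second lobe is emitted whose
    occlusion-phase delta has the given (opposite-signed) value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for phase in scenario.phases:
        n = max(2, int(round(phase.duration_s / scenario.sample_interval_s)))
        times = t + np.arange(n) * scenario.sample_interval_s
        t = times[-1] + scenario.sample_interval_s
        lobes = {"monitored": phase.delta_pct}
        if scenario.contralateral_delta_pct is not None:
            lobes["contralateral"] = (
                scenario.contralateral_delta_pct if phase.delta_pct != 0.0 else 0.0
            )
        for lobe, delta in lobes.items():
            mean = np.clip(scenario.baseline_pct + delta, 0.5, 99.5)
            vals = mean + rng.normal(0.0, scenario.noise_sd_pct, n)
            for ti, v in zip(times, vals):
                rows.append(
                    {
                        "t_s": ti,
                        "lobe": lobe,
                        "phase": phase.label,
                        "reading": float(np.clip(v, 0.0, 100.0)),
                    }
                )
    manifest = {"generator": "make_occlusion_series", "seed": seed, "spec": asdict(scenario)}
    return pd.DataFrame(rows), manifest


# ---------------------------------------------------------------------------
# in-vivo hemodilution


def make_hemodilution_dataset(
    n_points: int = 33,
    fio2_levels: tuple[float, ...] = (0.21, 0.3, 1.0),
    seed: int = 0,
    hb_range_g_dl: tuple[float, float] = (12.0, 2.5),
    analyzer_sd_g_dl: float = 0.15,
    optical_proportional_sd: float = 0.18,
) -> tuple[pd.DataFrame, dict]:
    """Paired (blood-gas Hb, optically derived Hb) during progressive anemia.

    True hemoglobin declines across the protocol; the blood-gas analyzer
    adds small additive noise while the optical estimate carries a
    proportional error, so the log-log regression of optical on blood-gas
    values has a slope near one with R^2 well below one (matching the
    dispersion seen in vivo).
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    truth = np.linspace(hb_range_g_dl[0], hb_range_g_dl[1], n_points)
    fio2 = np.array([fio2_levels[i % len(fio2_levels)] for i in range(n_points)])
    hb_bg = np.clip(truth + rng.normal(0.0, analyzer_sd_g_dl, n_points), 0.2, None)
    hb_vis = truth * np.exp(rng.normal(0.0, optical_proportional_sd, n_points))
    df = pd.DataFrame(
        {"hb_bloodgas_g_dl": hb_bg, "hb_visdrs_g_dl": hb_vis, "fio2": fio2, "hb_true_g_dl": truth}
    )
    manifest = {
        "generator": "make_hemodilution_dataset",
        "seed": seed,
        "n_points": n_points,
        "fio2_levels": list(fio2_levels),
        "analyzer_sd_g_dl": analyzer_sd_g_dl,
        "optical_proportional_sd": optical_proportional_sd,
    }
    return df, manifest


# ---------------------------------------------------------------------------
# liver-like spectra for the biliverdin comparison


def make_liver_spectrum_set(
    record: PhotonPathRecord,
    basis: list[ExtinctionSpectrum],
    hb_levels_um: tuple[float, ...] = (40.0, 70.0, 100.0, 130.0, 160.0),
    so2: float = 0.7,
    biliverdin_um: float = 30.0,
    scatter_a: float = 9.0,
    scatter_b: float = 1.0,
    seed: int = 0,
    noise_cv: float = 0.0,
    grid: SpectralGrid | None = None,
) -> tuple[list[Spectrum], list[ChromophoreConcentrations], dict]:
    """Tissue-like calibrated spectra with a known biliverdin content."""
    from .scattering import power_law_mu_s_prime
    from .inversion import SCATTER_REF_WAVELENGTH

    grid = grid or SpectralGrid.default()
    rng = np.random.default_rng(seed)
    mus = power_law_mu_s_prime(scatter_a, scatter_b, SCATTER_REF_WAVELENGTH, grid)
    spectra, truths = [], []
    for hb in hb_levels_um:
        conc = ChromophoreConcentrations(hb, so2, biliverdin_um)
        props = OpticalProperties(grid, compose_mu_a(conc, basis, grid), mus)
        refl = scaled_reflectance(record, props).reflectance
        noise = 1.0 + rng.normal(0.0, noise_cv, len(grid)) if noise_cv > 0 else 1.0
        spectra.append(Spectrum(grid, refl * noise, name=f"liver_hb{hb:g}"))
        truths.append(conc)
    manifest = {
        "generator": "make_liver_spectrum_set",
        "seed": seed,
        "hb_levels_um": list(hb_levels_um),
        "so2": so2,
        "biliverdin_um": biliverdin_um,
        "scatter": [scatter_a, scatter_b],
    }
    return spectra, truths, manifest
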