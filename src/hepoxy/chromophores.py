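"""Chromophore extinction bases and Beer–Lambert absorption composition.

The absorbers modeled are oxyhemoglobin, deoxyhemoglobin and biliverdin (the
dominant bile pigment in liver). Extinction tables are bundled as CSV package
data on a per-tetramer micromolar basis (hemoglobin molar mass 64,500 g/mol,
so 1 g/dL corresponds to ~155 uM tetramer). Tables are base-10 molar
extinction; the natural-log conversion ln(10) is applied inside
:func:`compose_mu_a` so that the returned absorption coefficient mu_a is on
the natural-log scale used by photon transport.

The bundled tables are synthetic tabulations: smooth Gaussian-band
parameterizations that reproduce the standard landmark features of the
hemoglobin visible spectrum (Soret edge, oxy Q-band doublet at 542/577 nm,
deoxy single band at 555 nm, red-tail ordering deoxy > oxy) with band-mean
amplitude consistent with liver-phantom absorption levels. The biliverdin
shape is likewise a synthetic stand-in (broad 377/670-nm bands); no standard
tabulation for it is bundled. User-supplied tables in the same CSV dialect
(columns ``wavelength_nm, epsilon_cm1_per_M``) are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import SpectralGrid, Spectrum

#: Tetramer micromolar per g/dL of hemoglobin (molar mass 64,500 g/mol).
UM_TETRAMER_PER_G_DL = 1.0e5 / 64500.0 * 100.0  # = 155.04 uM per g/dL

LN10 = float(np.log(10.0))

CHROMOPHORE_NAMES = ("oxyhemoglobin", "deoxyhemoglobin", "biliverdin")

_DATA_FILES = {
    "oxyhemoglobin": "hbo2_extinction_synthetic.csv",
    "deoxyhemoglobin": "hb_extinction_synthetic.csv",
    "biliverdin": "biliverdin_extinction_synthetic.csv",
}


def g_dl_to_um(hb_g_dl):
    """Hemoglobin g/dL -> uM tetramer."""
    return np.asarray(hb_g_dl, dtype=float) * UM_TETRAMER_PER_G_DL


def um_to_g_dl(hb_um):
    """Hemoglobin uM tetramer -> g/dL."""
    return np.asarray(hb_um, dtype=float) / UM_TETRAMER_PER_G_DL


@dataclass
class ExtinctionSpectrum:
    """Molar extinction (base-10) of one chromophore, in cm^-1 uM^-1."""

    grid: SpectralGrid
    epsilon: np.ndarray
    chromophore_name: str

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != (len(self.grid),):
            raise ValueError("epsilon length must match grid")
        if np.any(eps < 0) or not np.all(np.isfinite(eps)):
            raise ValueError("epsilon must be finite and non-negative")
        if self.chromophore_name not in CHROMOPHORE_NAMES:
            raise ValueError(
                f"unknown chromophore {self.chromophore_name!r}; "
                f"expected one of {CHROMOPHORE_NAMES}"
            )
        self.epsilon = eps

    def on_grid(self, grid: SpectralGrid) -> "ExtinctionSpectrum":
        if grid == self.grid:
            return self
        s = Spectrum(self.grid, self.epsilon, name=self.chromophore_name)
        try:
            resampled = s.interp_to(grid)
        except ValueError as err:
            raise ValueError(
                f"extinction table for {self.chromophore_name!r} does not cover "
                f"the requested grid: {err}"
            ) from None
        return ExtinctionSpectrum(grid, resampled.values, self.chromophore_name)


@dataclass(frozen=True)
class ChromophoreConcentrations:
    """Total hemoglobin (uM tetramer), saturation fraction and biliverdin (uM)."""

    total_hb: float
    so2: float
    biliverdin: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.total_hb, self.so2, self.biliverdin]).all():
            raise ValueError("concentrations must be finite")
        if self.total_hb < 0 or self.biliverdin < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError(f"so2 must be in [0, 1], got {self.so2}")


@dataclass
class OpticalProperties:
    """Paired absorption and reduced scattering coefficients, cm^-1."""

    grid: SpectralGrid
    mu_a: np.ndarray
    mu_s_prime: np.ndarray

    def __post_init__(self) -> None:
        mua = np.asarray(self.mu_a, dtype=float)
        musp = np.asarray(self.mu_s_prime, dtype=float)
        n = len(self.grid)
        if mua.shape != (n,) or musp.shape != (n,):
            raise ValueError("mu_a and mu_s_prime must match the grid length")
        if np.any(mua < 0):
            raise ValueError("mu_a must be non-negative")
        if np.any(musp <= 0):
            raise ValueError("mu_s_prime must be strictly positive")
        self.mu_a = mua
        self.mu_s_prime = musp

    @property
    def mean_mu_a(self) -> float:
        """Wavelength-averaged mu_a over the grid (cm^-1)."""
        return float(np.mean(self.mu_a))

    @property
    def mean_mu_s_prime(self) -> float:
        """Wavelength-averaged mu_s' over the grid (cm^-1)."""
        return float(np.mean(self.mu_s_prime))


def load_extinction(name: str, path=None, grid: SpectralGrid | None = None) -> ExtinctionSpectrum:
    """Load a bundled (or user ``path``) extinction table, optionally resampled.

    Bundled tables cover 400–700 nm at 1-nm steps and are stored in
    cm^-1 M^-1; values are converted to the cm^-1 uM^-1 working basis.
    """
    if name not in CHROMOPHORE_NAMES:
        raise ValueError(f"unknown chromophore {name!r}")
    if path is None:
        with resources.as_file(
            resources.files("hepoxy.data").joinpath(_DATA_FILES[name])
        ) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    eps_per_um = df.iloc[:, 1].to_numpy(dtype=float) * 1e-6
    ext = ExtinctionSpectrum(SpectralGrid(df.iloc[:, 0].to_numpy(dtype=float)), eps_per_um, name)
    return ext.on_grid(grid) if grid is not None else ext


def default_basis(grid: SpectralGrid | None = None, include_biliverdin: bool = True):
    """The bundled extinction basis on ``grid`` (default analysis grid)."""
    grid = grid or SpectralGrid.default()
    names = CHROMOPHORE_NAMES if include_biliverdin else CHROMOPHORE_NAMES[:2]
    return [load_extinction(n, grid=grid) for n in names]


def compose_mu_a(
    conc: ChromophoreConcentrations,
    basis: list[ExtinctionSpectrum],
    grid: SpectralGrid,
) -> np.ndarray:
    """Beer–Lambert absorption coefficient mu_a(lambda) in cm^-1.

    mu_a = ln(10) * [ C_Hb * (SO2 * eps_HbO2 + (1-SO2) * eps_Hb)
                      + C_biliverdin * eps_bv ]

    Exactly linear in each concentration component. ``basis`` must contain
    oxy- and deoxyhemoglobin; biliverdin is required only when
    ``conc.biliverdin > 0``.
    """
    by_name: dict[str, ExtinctionSpectrum] = {}
    for ext in basis:
        by_name[ext.chromophore_name] = ext.on_grid(grid)
    for required in ("oxyhemoglobin", "deoxyhemoglobin"):
        if required not in by_name:
            raise ValueError(f"basis is missing chromophore {required!r}")
    mu = conc.total_hb * (
        conc.so2 * by_name["oxyhemoglobin"].epsilon
        + (1.0 - conc.so2) * by_name["deoxyhemoglobin"].epsilon
    )
    if conc.biliverdin > 0:
        if "biliverdin" not in by_name:
            raise ValueError("basis is missing chromophore 'biliverdin'")
        mu = mu + conc.biliverdin * by_name["biliverdin"].epsilon
    else:
        mu = mu + 0.0
    return LN10 * mu
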