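"""Reduced scattering models: Mie microsphere phantoms and power-law tissue.

Phantom scattering is computed from Lorenz–Mie theory for homogeneous
spheres (known diameter, refractive indices and number density), with the
anisotropy factor g evaluated from the full partial-wave series:

    mu_s'(lambda) = N * Csca(lambda) * (1 - g(lambda))

with N in spheres/mL and Csca in cm^2. Tissue scattering, whose
microstructure is not sphere-like, uses the conventional power law
mu_s'(lambda) = a * (lambda / lambda_ref)^(-b).

The Mie coefficients a_n, b_n are evaluated with the standard downward
recurrence for the logarithmic derivative of the Riccati–Bessel function
(numerically stable for the size parameters of 1-um spheres in the visible,
x ~ 6-10). Spectral dispersion of the sphere/medium indices is not modeled
(constant-index approximation; sub-percent effect over 435-630 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import SpectralGrid


@dataclass(frozen=True)
class MiePhantomSpec:
    """Microsphere suspension: 1-um polystyrene in water by default."""

    sphere_diameter_um: float = 1.0
    sphere_refractive_index: float = 1.59
    medium_refractive_index: float = 1.33
    number_density_per_ml: float = 1.0e9

    def __post_init__(self) -> None:
        if self.sphere_diameter_um <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.sphere_refractive_index <= 1.0:
            raise ValueError("sphere refractive index must exceed 1")
        if self.medium_refractive_index < 1.0:
            raise ValueError("medium refractive index must be >= 1")
        if self.number_density_per_ml < 0:
            raise ValueError("number density must be non-negative")

    def with_density(self, number_density_per_ml: float) -> "MiePhantomSpec":
        return MiePhantomSpec(
            self.sphere_diameter_um,
            self.sphere_refractive_index,
            self.medium_refractive_index,
            number_density_per_ml,
        )


def mie_efficiencies(x: float, m: float) -> tuple[float, float, float]:
    """Scattering efficiency Qsca, extinction Qext and anisotropy g.

    Parameters
    ----------
    x : size parameter 2*pi*r*n_medium/lambda (lambda in vacuum).
    m : relative refractive index n_sphere/n_medium.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x

    # Downward recurrence for the logarithmic derivative D_n(mx).
    nstart = nmax + 16
    D = np.zeros(nstart + 1)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)

    # Upward Riccati-Bessel recurrences: psi (regular), chi (irregular).
    a = np.zeros(nmax + 1, dtype=complex)
    b = np.zeros(nmax + 1, dtype=complex)
    psi_nm1, psi_n = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_nm1, chi_n = -np.sin(x), np.cos(x)  # chi_{-1}, chi_0
    for n in range(1, nmax + 1):
        psi_np = (2 * n - 1) / x * psi_n - psi_nm1
        chi_np = (2 * n - 1) / x * chi_n - chi_nm1
        psi_nm1, psi_n = psi_n, psi_np
        chi_nm1, chi_n = chi_n, chi_np
        xi_n = psi_n - 1j * chi_n
        xi_nm1 = psi_nm1 - 1j * chi_nm1
        ta = D[n] / m + n / x
        tb = D[n] * m + n / x
        a[n] = (ta * psi_n - psi_nm1) / (ta * xi_n - xi_nm1)
        b[n] = (tb * psi_n - psi_nm1) / (tb * xi_n - xi_nm1)

    n = np.arange(1, nmax + 1)
    an, bn = a[1:], b[1:]
    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(an) ** 2 + np.abs(bn) ** 2))
    qext = (2.0 / x**2) * np.sum((2 * n + 1) * (an + bn).real)
    asym = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (an[:-1] * np.conj(an[1:]) + bn[:-1] * np.conj(bn[1:])).real
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * (an * np.conj(bn)).real)
    g = (4.0 / x**2) * asym / qsca
    return float(qsca), float(qext), float(g)


def mie_mu_s_prime(spec: MiePhantomSpec, grid: SpectralGrid) -> np.ndarray:
    """Reduced scattering mu_s'(lambda) in cm^-1 for a sphere suspension."""
    radius_cm = spec.sphere_diameter_um * 1e-4 / 2.0
    m = spec.sphere_refractive_index / spec.medium_refractive_index
    out = np.empty(len(grid))
    for i, wl_nm in enumerate(grid.wavelengths):
        x = 2.0 * np.pi * radius_cm * spec.medium_refractive_index / (wl_nm * 1e-7)
        qsca, _, g = mie_efficiencies(x, m)
        csca = qsca * np.pi * radius_cm**2
        out[i] = spec.number_density_per_ml * csca * (1.0 - g)
    return out


def density_for_mean_mu_s_prime(
    spec: MiePhantomSpec, grid: SpectralGrid, target_mean: float
) -> float:
    """Number density (per mL) giving wavelength-mean mu_s' = ``target_mean``."""
    per_sphere = mie_mu_s_prime(spec.with_density(1.0), grid)
    return float(target_mean / per_sphere.mean())


def power_law_mu_s_prime(
    a: float, b: float, ref_wavelength_nm: float, grid: SpectralGrid
) -> np.ndarray:
    """mu_s'(lambda) = a * (lambda/lambda_ref)^(-b), cm^-1; mu_s'(ref) = a."""
    if a <= 0:
        raise ValueError("scatter amplitude a must be positive")
    if b < 0:
        raise ValueError("scatter power b must be non-negative")
    return a * (grid.wavelengths / ref_wavelength_nm) ** (-b)


def fit_power_law(
    grid: SpectralGrid, mu_s_prime: np.ndarray, ref_wavelength_nm: float = 500.0
) -> tuple[float, float]:
    """Least-squares (a, b) of the power law to an arbitrary mu_s' curve."""
    mu = np.asarray(mu_s_prime, dtype=float)
    x = np.log(grid.wavelengths / ref_wavelength_nm)
    # log-linear seed, then refine on the linear scale
    slope, intercept = np.polyfit(x, np.log(mu), 1)
    res = least_squares(
        lambda p: power_law_mu_s_prime(p[0], p[1], ref_wavelength_nm, grid) - mu,
        x0=[float(np.exp(intercept)), float(max(-slope, 0.0))],
        bounds=([1e-6, 0.0], [np.inf, 10.0]),
    )
    return float(res.x[0]), float(res.x[1])
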