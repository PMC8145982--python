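"""Independent reference implementations used only as test oracles.

Each oracle deliberately takes a different algorithmic route from the
package code it checks: the Mie oracle evaluates Riccati–Bessel functions
through scipy's spherical Bessel routines (the package uses pure
recurrences), the diffusion oracle is a closed-form dipole solution, and
the concordance oracle is the direct textbook formula.
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn


def mie_qsca_g_bessel(x: float, m: float) -> tuple[float, float]:
    """Mie Qsca and anisotropy g via scipy spherical Bessel functions."""
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    n = np.arange(1, nmax + 1)

    def riccati(kind, rho):
        if kind == "psi":
            f = spherical_jn(n, rho)
            fp = spherical_jn(n, rho, derivative=True)
            return rho * f, f + rho * fp
        j, jp = spherical_jn(n, rho), spherical_jn(n, rho, derivative=True)
        y, yp = spherical_yn(n, rho), spherical_yn(n, rho, derivative=True)
        h = j - 1j * y
        hp = jp - 1j * yp
        return rho * h, h + rho * hp

    psi_x, dpsi_x = riccati("psi", x)
    psi_mx, dpsi_mx = riccati("psi", m * x)
    xi_x, dxi_x = riccati("xi", x)

    a = (m * psi_mx * dpsi_x - psi_x * dpsi_mx) / (m * psi_mx * dxi_x - xi_x * dpsi_mx)
    b = (psi_mx * dpsi_x - m * psi_x * dpsi_mx) / (psi_mx * dxi_x - m * xi_x * dpsi_mx)

    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    asym = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = (4.0 / x**2) * asym / qsca
    return float(qsca), float(g)


def diffusion_reflectance(rho_cm: float, mu_a: float, mu_s_prime: float) -> float:
    """Semi-infinite dipole diffusion reflectance R(rho) per cm^2 (matched)."""
    mut = mu_a + mu_s_prime
    z0 = 1.0 / mut
    d = 1.0 / (3.0 * mut)
    mueff = np.sqrt(3.0 * mu_a * mut)
    zb = 2.0 * d
    r1 = np.sqrt(rho_cm**2 + z0**2)
    r2 = np.sqrt(rho_cm**2 + (z0 + 2.0 * zb) ** 2)
    return float(
        (1.0 / (4.0 * np.pi))
        * (
            z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
            + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
        )
    )


def ccc_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance by the direct definition, population moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    return float(2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2))


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope/intercept/R^2 from the summation formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = syy - 2 * slope * sxy - 2 * intercept * sy + slope**2 * sxx + 2 * slope * intercept * sx + n * intercept**2
    ss_tot = syy - sy * sy / n
    return float(slope), float(intercept), float(1.0 - ss_res / ss_tot)


def bisect_root(f, lo: float, hi: float, tol: float = 1e-12, maxit: int = 200) -> float:
    """Plain bisection; f(lo) and f(hi) must bracket a sign change."""
    flo = f(lo)
    if flo == 0:
        return lo
    for _ in range(maxit):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0 or (hi - lo) < tol:
            return mid
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)
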