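"""Agreement and variability statistics.

Lin's concordance correlation coefficient (CCC) with a standard error
adjusted for within-subject replicate measurements, the Meng–Rosenthal–Rubin
z test for comparing two overlapping dependent correlations, the coefficient
of variation of steady-state replicate sets, and log-scale linear regression
for concentration agreement.

Replicate adjustment: the published asymptotic SE of the CCC assumes
independent pairs. When the same animal contributes several pairs, the
effective sample size is reduced with a design-effect correction,
n_eff = N / (1 + (m_bar - 1) * ICC), with the intraclass correlation
estimated by one-way ANOVA on the pair means. This is a documented
assumption (the exact correction used in the source studies is not public);
``replicate_adjust=False`` falls back to plain N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def _fisher_z(r: float) -> float:
    return float(np.arctanh(r))


@dataclass
class CCCResult:
    ccc: float
    se: float
    ci95: tuple[float, float]
    pearson_r: float
    n: int
    n_eff: float


def icc_oneway(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation ICC(1), clipped to [0, 1)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    n = values.size
    if k < 2 or k == n:
        return 0.0
    grand = values.mean()
    sizes = np.array([(groups == g).sum() for g in labels], dtype=float)
    means = np.array([values[groups == g].mean() for g in labels])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((values[groups == g] - m) ** 2) for g, m in zip(labels, means)))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)  # balanced-design average group size
    if msw <= 0:
        return 1.0 - 1e-9
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(np.clip(icc, 0.0, 1.0 - 1e-9))


def lin_ccc(
    x: Sequence[float],
    y: Sequence[float],
    subject: Sequence | None = None,
    replicate_adjust: bool = True,
) -> CCCResult:
    """Lin's concordance correlation coefficient with SE and Fisher-z 95% CI.

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),
    using population (1/n) moments as in the original derivation. Always
    |ccc| <= |pearson r|. The SE uses Lin's asymptotic variance of the
    Fisher-transformed CCC with the replicate-adjusted effective n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    if sx2 == 0 or sy2 == 0:
        raise ValueError("degenerate input: zero variance")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    d = float(x.mean() - y.mean())
    ccc = 2.0 * sxy / (sx2 + sy2 + d * d)
    r = sxy / np.sqrt(sx2 * sy2)

    n_eff = float(n)
    if replicate_adjust and subject is not None:
        subject = np.asarray(subject)
        if subject.shape != x.shape:
            raise ValueError("subject labels must match the data length")
        k = np.unique(subject).size
        m_bar = n / k
        icc = icc_oneway((x + y) / 2.0, subject)
        n_eff = n / (1.0 + (m_bar - 1.0) * icc)

    # Lin (1989, corr. 2000) variance of the Fisher-transformed CCC
    u = d / (sx2 * sy2) ** 0.25
    rc = ccc
    if abs(r) < 1e-12 or abs(abs(rc) - 1.0) < 1e-12:
        var_z = 0.0
    else:
        var_z = (
            (1 - r * r) * rc * rc / ((1 - rc * rc) * r * r)
            + 2 * rc**3 * (1 - rc) * u * u / (r * (1 - rc * rc) ** 2)
            - rc**4 * u**4 / (2 * r * r * (1 - rc * rc) ** 2)
        ) / max(n_eff - 2.0, 1.0)
        var_z = max(var_z, 0.0)
    se_z = float(np.sqrt(var_z))
    if se_z == 0.0:
        lo = hi = rc
    else:
        z = _fisher_z(np.clip(rc, -1 + 1e-15, 1 - 1e-15))
        lo, hi = np.tanh(z - 1.959964 * se_z), np.tanh(z + 1.959964 * se_z)
    # delta-method SE on the ccc scale
    se_ccc = se_z * (1 - rc * rc)
    return CCCResult(float(rc), float(se_ccc), (float(lo), float(hi)), float(r), n, n_eff)


def meng_test(r_xy1: float, r_xy2: float, r_12: float, n: int) -> tuple[float, float]:
    """Meng–Rosenthal–Rubin test for two correlations sharing variable x.

    ``r_xy1`` and ``r_xy2`` correlate x with predictors 1 and 2; ``r_12``
    is the correlation between the predictors. Returns (z, two-sided p).
    """
    for r in (r_xy1, r_xy2, r_12):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = _fisher_z(r_xy1), _fisher_z(r_xy2)
    r2bar = (r_xy1**2 + r_xy2**2) / 2.0
    f = min(1.0, (1.0 - r_12) / (2.0 * (1.0 - r2bar)))
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_12) * h))
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent: 100 * sd / mean (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(m))


@dataclass
class LogLinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float


def log_linear_fit(x: Sequence[float], y: Sequence[float]) -> LogLinearFit:
    """Ordinary least squares of ln(y) on ln(x); R^2 on the log scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-linear fit requires strictly positive values")
    res = sps.linregress(np.log(x), np.log(y))
    return LogLinearFit(
        float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.stderr)
    )
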