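"""Hill-equation oxygen dissociation modeling and the vis-DRS conversion.

The blood-gas reference curve for pigs is

    SO2(PO2) = 100 * (PO2/P50)^n / (1 + (PO2/P50)^n)     [%]

with n = 3.02 and P50 = 32.929 mmHg. vis-DRS tissue readings follow a Hill
curve of their own (shallower n, shifted P50); because both are Hill
sigmoids, their logits are linear in ln(PO2), and equating the two curves
gives a closed-form correction of a reading v to true saturation. With the
saturation odds q(v) = v / (100 - v),

    SO2(v) = 100 * X / (1 + X),     X = c * q(v)^r

with exponent r = n_ref / n_fit (ratio of Hill coefficients) and outer
coefficient c = (P50_fit / P50_ref)^n_ref capturing the P50 shift. The
equivalent parameterization with the coefficient inside the power,
a = c^(1/r), is also reported. Writing the same map with inverted odds,
SO2 = 100 / (1 + c^-1 ((100-v)/v)^r); the coefficient enters reciprocally
there — keeping c on the odds is what makes the composition identity
apply_conversion(hill(po2; fitted)) == hill(po2; reference) exact.

Three nested fitting models handle the two pH condition groups:
model 3 pools everything (one n, one P50); model 1 shares n but lets P50
vary by group; model 2 is fully per-group. Model comparison uses the
extra-sum-of-squares F test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

#: Reference pig oxygen-dissociation parameters (blood-gas SO2 curve).
REFERENCE_N = 3.02
REFERENCE_P50_MMHG = 32.929

#: Constants of the equivalent scaled printed form
#: SO2 = (s*PO2)^n / (d + (s*PO2)^n) * 100.
REFERENCE_SCALE = 0.13534
REFERENCE_DENOM = 91.2

PH_GROUPS = ("ph_7.1-7.25", "ph_7.3-7.4")


@dataclass(frozen=True)
class HillParams:
    """Hill coefficient (cooperativity) and P50 (mmHg)."""

    n: float
    p50: float

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p50 <= 0:
            raise ValueError("Hill coefficient and P50 must be positive")


REFERENCE_PIG = HillParams(REFERENCE_N, REFERENCE_P50_MMHG)


def p50_from_scaled_form(scale: float = REFERENCE_SCALE, denom: float = REFERENCE_DENOM, n: float = REFERENCE_N) -> float:
    """P50 implied by the scaled form: denom^(1/n) / scale."""
    return denom ** (1.0 / n) / scale


def hill_so2(po2, params: HillParams):
    """Saturation in percent for oxygen partial pressure ``po2`` (mmHg)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("PO2 must be non-negative")
    ratio = (po2 / params.p50) ** params.n
    return 100.0 * ratio / (1.0 + ratio)


def logit_reading(reading):
    """ln(v / (100 - v)) for a percent reading v strictly inside (0, 100)."""
    v = np.asarray(reading, dtype=float)
    if np.any(v <= 0) or np.any(v >= 100):
        raise ValueError("logit is undefined at 0% and 100%; reading must be in (0, 100)")
    return np.log(v / (100.0 - v))


@dataclass(frozen=True)
class ConversionCoefficients:
    """Closed-form vis-DRS -> SO2 correction on the saturation odds.

    SO2(v) = 100 X/(1+X) with X = c (v/(100-v))^r; c = (P50_fit/P50_ref)^n_ref,
    r = n_ref/n_fit.
    """

    c: float
    r: float
    reference: HillParams = REFERENCE_PIG
    fitted: HillParams | None = None

    def __post_init__(self) -> None:
        if self.c <= 0 or self.r <= 0:
            raise ValueError("conversion coefficients must be positive")

    @property
    def a(self) -> float:
        """Inner-coefficient parameterization: SO2 = 100/(1 + (a (100-v)/v)^r)."""
        return self.c ** (1.0 / self.r)


def derive_conversion(reference: HillParams, fitted: HillParams) -> ConversionCoefficients:
    """Solve the two Hill equations for SO2 as a function of the reading.

    r = n_reference / n_fitted; c = (P50_fitted / P50_reference)^n_reference.
    Identity when reference == fitted.
    """
    r = reference.n / fitted.n
    c = (fitted.p50 / reference.p50) ** reference.n
    return ConversionCoefficients(c=c, r=r, reference=reference, fitted=fitted)


def apply_conversion(reading, coeff: ConversionCoefficients):
    """Corrected SO2 (percent) for vis-DRS reading(s) in [0, 100].

    Strictly increasing; maps (0, 100) onto (0, 100) with the endpoints
    fixed by continuity.
    """
    v = np.asarray(reading, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    if np.any(v < 0) or np.any(v > 100):
        raise ValueError("reading must be within [0, 100] percent")
    out = np.empty_like(v)
    interior = (v > 0) & (v < 100)
    out[v <= 0] = 0.0
    out[v >= 100] = 100.0
    vi = v[interior]
    x = coeff.c * (vi / (100.0 - vi)) ** coeff.r
    out[interior] = 100.0 * x / (1.0 + x)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# fitting


@dataclass
class HillFit:
    """Result of :func:`fit_hill`: per-group parameters and fit diagnostics."""

    model: int | str
    params: dict[str, HillParams]
    std_errors: dict[str, HillParams]
    rss: float
    r_squared: float
    n_obs: int
    n_params: int
    converged: bool
    pooled: HillParams | None = None

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_params


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(data)
    required = {"po2", "reading"}
    if not required.issubset(df.columns):
        raise ValueError(f"fit dataset must have columns {sorted(required)}")
    if np.any(df["po2"].to_numpy() <= 0):
        raise ValueError("PO2 values must be positive")
    v = df["reading"].to_numpy(dtype=float)
    if np.any(v <= 0) or np.any(v >= 100):
        raise ValueError("readings must lie strictly inside (0, 100) percent")
    if "ph_group" not in df.columns:
        df = df.assign(ph_group="pooled")
    return df


def _logit_seed(po2: np.ndarray, reading: np.ndarray) -> HillParams:
    """Initialize (n, p50) from the logit-vs-ln(PO2) linearization."""
    slope, intercept = np.polyfit(np.log(po2), logit_reading(reading), 1)
    n = max(slope, 0.05)
    p50 = float(np.exp(-intercept / n)) if n > 0 else float(np.median(po2))
    return HillParams(float(n), float(np.clip(p50, 1e-3, 1e4)))


def fit_hill(
    data: pd.DataFrame,
    model: int = 3,
    fix_n: float | None = None,
    min_points_per_group: int = 4,
) -> HillFit:
    """Nonlinear least squares of the Hill curve on the reading (percent) scale.

    model 3: one (n, P50) pooled over groups.
    model 1: shared n, per-group P50.
    model 2: per-group (n, P50).
    ``fix_n`` freezes the Hill coefficient (e.g. at the reference 3.02),
    giving the smaller model of a fixed-vs-fitted comparison.

    R^2 and parameter standard errors are computed on the reading scale;
    the logit linearization is used only to seed the optimizer.
    """
    df = _prepare(data)
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    groups = sorted(df["ph_group"].unique()) if model in (1, 2) else ["pooled"]
    if model in (1, 2):
        counts = df.groupby("ph_group").size()
        if (counts < min_points_per_group).any():
            raise ValueError(
                f"each group needs >= {min_points_per_group} points, got {dict(counts)}"
            )
    elif len(df) < min_points_per_group:
        raise ValueError(f"need >= {min_points_per_group} points")

    po2 = df["po2"].to_numpy(dtype=float)
    v = df["reading"].to_numpy(dtype=float)
    gidx = (
        np.zeros(len(df), dtype=int)
        if model == 3
        else df["ph_group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    )
    seed_all = _logit_seed(po2, v)
    seeds = {
        g: _logit_seed(*(lambda m: (po2[m], v[m]))(gidx == i)) if model in (1, 2) else seed_all
        for i, g in enumerate(groups)
    }

    # parameter vector layout
    if model == 3:
        x0 = [seed_all.n, seed_all.p50]
        unpack = lambda x: {groups[0]: HillParams(x[0], x[1])}
    elif model == 1:
        x0 = [seed_all.n] + [seeds[g].p50 for g in groups]
        unpack = lambda x: {g: HillParams(x[0], x[1 + i]) for i, g in enumerate(groups)}
    else:
        x0 = []
        for g in groups:
            x0 += [seeds[g].n, seeds[g].p50]
        unpack = lambda x: {g: HillParams(x[2 * i], x[2 * i + 1]) for i, g in enumerate(groups)}

    if fix_n is not None:
        # drop every n entry from the free vector; only P50s remain
        if model == 2:
            raise ValueError("fix_n applies to shared-n models (1 and 3) only")
        x0 = x0[1:]
        base_unpack = unpack
        if model == 3:
            unpack = lambda x: {groups[0]: HillParams(fix_n, x[0])}
        else:
            unpack = lambda x: {g: HillParams(fix_n, x[i]) for i, g in enumerate(groups)}

    def residuals(x: np.ndarray) -> np.ndarray:
        par = unpack(x)
        pred = np.empty_like(v)
        for i, g in enumerate(groups):
            m = gidx == i
            pred[m] = hill_so2(po2[m], par[g])
        return pred - v

    n_free = len(x0)
    lo = np.full(n_free, 1e-3)
    hi = np.full(n_free, 1e4)
    res = least_squares(
        residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
        ftol=1e-12, xtol=1e-12, max_nfev=2000,
    )
    params = unpack(res.x)
    rss = float(2.0 * res.cost)
    tss = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    # asymptotic standard errors from the jacobian at the optimum
    dof = len(v) - n_free
    se_vec = np.full(n_free, np.nan)
    if dof > 0:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * rss / dof
            se_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    se_params = unpack(np.where(np.isfinite(se_vec), np.maximum(se_vec, 1e-12), 1e-12))
    if fix_n is not None:
        se_params = {g: HillParams(1e-12, p.p50) for g, p in se_params.items()}

    return HillFit(
        model=model if fix_n is None else f"{model}-fixed-n",
        params=params,
        std_errors=se_params,
        rss=rss,
        r_squared=float(r2),
        n_obs=len(v),
        n_params=n_free,
        converged=bool(res.status > 0),
        pooled=params[groups[0]] if model == 3 else None,
    )


def compare_models(fit_small: HillFit, fit_large: HillFit, data: pd.DataFrame) -> tuple[float, float]:
    """Extra-sum-of-squares F test for nested Hill fits: returns (F, p).

    The smaller model must have fewer free parameters (nesting order
    3 within 1 within 2, or a fixed-n model within its fitted version). A
    larger model can never fit worse; if the optimizer returns a marginally
    larger RSS the statistic is clamped at zero (p = 1).
    """
    df = _prepare(data)
    if fit_small.n_params >= fit_large.n_params:
        raise ValueError("models are not nested: the first must have fewer parameters")
    if fit_small.n_obs != len(df) or fit_large.n_obs != len(df):
        raise ValueError("fits were not produced from the supplied data")
    df_num = fit_large.n_params - fit_small.n_params
    df_den = fit_large.df_resid
    if df_den <= 0:
        raise ValueError("large model has no residual degrees of freedom")
    f_stat = max(0.0, (fit_small.rss - fit_large.rss) / df_num / (fit_large.rss / df_den))
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return float(f_stat), p
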