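"""Photon-transport forward model for the 6-around-1 surface probe.

One "white" Monte Carlo run (zero absorption, reference reduced scattering
mu_s'_ref, Henyey–Greenstein phase function) is stored as a record of
detected-photon exit radii and path lengths. Reflectance for arbitrary
optical properties is then obtained without re-running transport:

* absorption by Beer attenuation of each stored path,
* scattering by similarity rescaling — for a medium with mu_s'(lambda) the
  stored geometry shrinks/stretches by k = mu_s'_ref / mu_s'(lambda), so a
  photon recorded at exit radius r with path L contributes at radius r*k
  with path L*k.

The probe (ring of illumination fibers around one detection fiber at 1.2 mm
centre-to-centre) is idealized, by reciprocity, as a pencil source at the
origin with a smooth raised-cosine collection window over exit radius
centred on the source–detector separation. The smooth window keeps the
reflectance continuously differentiable in the scatter parameters, which
gradient-based inversion requires. The medium is homogeneous and
semi-infinite; Fresnel reflection at the tissue/probe-face interface and a
fibre-NA acceptance cone are applied at the boundary.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .chromophores import OpticalProperties
from .spectra import SpectralGrid, Spectrum

#: Default reference reduced scattering for the stored run (cm^-1).
DEFAULT_MU_S_PRIME_REF = 15.0

#: Similarity-scaling validity band (ratio to the reference mu_s').
SCALING_VALIDITY_BAND = 3.0


@dataclass(frozen=True)
class ProbeGeometry:
    """Surface-probe geometry; defaults match the liver oximetry probe."""

    sds_mm: float = 1.2
    fiber_core_diameter_um: float = 200.0
    numerical_aperture: float | None = 0.22
    n_illumination_fibers: int = 6
    probe_index: float = 1.45

    def __post_init__(self) -> None:
        if self.sds_mm <= 0:
            raise ValueError("source-detector separation must be positive")
        if self.fiber_core_diameter_um <= 0:
            raise ValueError("fiber core diameter must be positive")

    @property
    def sds_cm(self) -> float:
        return self.sds_mm * 0.1

    @property
    def window_halfwidth_cm(self) -> float:
        # ring-source x disc-detector radial sensitivity, collapsed to a
        # raised-cosine window one core diameter wide on either side
        return self.fiber_core_diameter_um * 1e-4

    def collection_weight(self, r_cm: np.ndarray) -> np.ndarray:
        """Smooth radial collection window W(r), 1 at the SDS, 0 outside."""
        u = (np.asarray(r_cm) - self.sds_cm) / self.window_halfwidth_cm
        w = 0.5 * (1.0 + np.cos(np.pi * np.clip(u, -1.0, 1.0)))
        return np.where(np.abs(u) < 1.0, w, 0.0)


@dataclass(frozen=True)
class TransportConfig:
    """Monte Carlo run settings; the seed is recorded in every output."""

    n_photons: int = 300_000
    seed: int = 20210521
    tissue_refractive_index: float = 1.38
    max_pathlength_cm: float = 25.0
    anisotropy: float = 0.9
    record_radius_cm: float = 0.6
    kill_radius_cm: float = 3.0
    kill_depth_cm: float = 3.0
    matched_boundary: bool = False

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be positive")
        if not -1.0 < self.anisotropy < 1.0:
            raise ValueError("anisotropy must be in (-1, 1)")


@dataclass
class ReflectanceSpectrum:
    """Detected reflectance fraction per wavelength (dimensionless)."""

    grid: SpectralGrid
    reflectance: np.ndarray
    mc_standard_error: np.ndarray | None = None
    metadata: dict | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (len(self.grid),):
            raise ValueError("reflectance length must match grid")
        if not np.all(np.isfinite(r)) or np.any(r < 0) or np.any(r > 1):
            raise ValueError("reflectance must be finite and within [0, 1]")
        self.reflectance = r

    def as_spectrum(self, name: str = "reflectance") -> Spectrum:
        return Spectrum(self.grid, self.reflectance, name=name)


@dataclass
class PhotonPathRecord:
    """Exit radius / path length / weight of every recorded photon.

    Arrays are sorted by exit radius so that the scaled collection window
    maps to a contiguous slice.
    """

    exit_radius_cm: np.ndarray
    pathlength_cm: np.ndarray
    weight: np.ndarray
    n_launched: int
    mu_s_prime_ref: float
    geometry: ProbeGeometry
    config: TransportConfig

    @property
    def n_recorded(self) -> int:
        return self.exit_radius_cm.size

    @property
    def n_detected(self) -> int:
        """Photons inside the unscaled (k=1) collection window."""
        return int(np.count_nonzero(self.geometry.collection_weight(self.exit_radius_cm) > 0))

    def detected_pathlengths(self) -> np.ndarray:
        return self.pathlength_cm[self.geometry.collection_weight(self.exit_radius_cm) > 0]


def _fresnel_reflectance(cos_i: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for internal incidence cosines."""
    cos_i = np.clip(cos_i, 0.0, 1.0)
    sin_i = np.sqrt(1.0 - cos_i**2)
    sin_t = n1 / n2 * sin_i
    tir = sin_t >= 1.0
    sin_t = np.clip(sin_t, 0.0, 1.0 - 1e-12)
    cos_t = np.sqrt(1.0 - sin_t**2)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    r = 0.5 * (rs + rp)
    return np.where(tir, 1.0, r)


def _sample_hg(g: float, u: np.ndarray) -> np.ndarray:
    """Henyey–Greenstein scattering-angle cosine from uniforms ``u``."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


def run_reference_mc(
    geometry: ProbeGeometry | None = None,
    mu_s_prime_ref: float = DEFAULT_MU_S_PRIME_REF,
    config: TransportConfig | None = None,
) -> PhotonPathRecord:
    """Run the white reference Monte Carlo and return the photon path record.

    Absorption is zero in this run by construction (it is applied afterwards
    by path-length attenuation in :func:`scaled_reflectance`); scattering is
    at ``mu_s_prime_ref`` with the configured anisotropy. Deterministic for a
    fixed seed.
    """
    geometry = geometry or ProbeGeometry()
    config = config or TransportConfig()
    g = config.anisotropy
    mus = mu_s_prime_ref / (1.0 - g)
    n1 = config.tissue_refractive_index
    n2 = n1 if config.matched_boundary else geometry.probe_index
    na_sin_max = None
    if geometry.numerical_aperture is not None and not config.matched_boundary:
        na_sin_max = geometry.numerical_aperture / n1

    rng = np.random.default_rng(config.seed)
    n = int(config.n_photons)
    x = np.zeros(n)
    y = np.zeros(n)
    z = np.zeros(n)
    ux = np.zeros(n)
    uy = np.zeros(n)
    uz = np.ones(n)
    L = np.zeros(n)

    rec_r: list[np.ndarray] = []
    rec_l: list[np.ndarray] = []

    max_iter = int(config.max_pathlength_cm * mus * 1.5) + 200
    for _ in range(max_iter):
        if x.size == 0:
            break
        s = -np.log(rng.random(x.size)) / mus
        znew = z + uz * s
        cross = znew < 0.0

        if np.any(cross):
            t = -z[cross] / uz[cross]
            xb = x[cross] + ux[cross] * t
            yb = y[cross] + uy[cross] * t
            lb = L[cross] + t
            cos_i = -uz[cross]
            if config.matched_boundary:
                refl = np.zeros(cos_i.size, dtype=bool)
            else:
                r_fres = _fresnel_reflectance(cos_i, n1, n2)
                refl = rng.random(cos_i.size) < r_fres
            # exiting photons: record those inside the radius and NA cone
            exit_mask = ~refl
            rexit = np.hypot(xb[exit_mask], yb[exit_mask])
            keep = rexit < config.record_radius_cm
            if na_sin_max is not None:
                sin_exit = np.sqrt(
                    np.clip(ux[cross][exit_mask] ** 2 + uy[cross][exit_mask] ** 2, 0, 1)
                )
                keep &= sin_exit <= na_sin_max
            rec_r.append(rexit[keep])
            rec_l.append(lb[exit_mask][keep])

            # internally reflected photons finish the remainder of the step
            idx = np.flatnonzero(cross)
            ridx = idx[refl]
            rem = s[ridx] - t[refl]
            x[ridx] = xb[refl] + ux[ridx] * rem
            y[ridx] = yb[refl] + uy[ridx] * rem
            uz[ridx] = -uz[ridx]
            z[ridx] = uz[ridx] * rem
            L[ridx] = lb[refl] + rem

        survive = ~cross
        if np.any(cross):
            survive = survive.copy()
            idx = np.flatnonzero(cross)
            survive[idx[refl]] = True

        nc = ~cross
        x[nc] += ux[nc] * s[nc]
        y[nc] += uy[nc] * s[nc]
        z[nc] = znew[nc]
        L[nc] += s[nc]

        alive = (
            survive
            & (L < config.max_pathlength_cm)
            & (z < config.kill_depth_cm)
            & (x * x + y * y < config.kill_radius_cm**2)
        )
        x, y, z = x[alive], y[alive], z[alive]
        ux, uy, uz = ux[alive], uy[alive], uz[alive]
        L = L[alive]
        if x.size == 0:
            break

        # Henyey-Greenstein scatter
        cos_t = _sample_hg(g, rng.random(x.size))
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
        phi = 2.0 * np.pi * rng.random(x.size)
        cp, sp = np.cos(phi), np.sin(phi)
        near_pole = np.abs(uz) > 0.99999
        denom = np.sqrt(np.clip(1.0 - uz**2, 1e-12, 1.0))
        ux_new = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
        uy_new = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
        uz_new = -sin_t * cp * denom + uz * cos_t
        ux_new = np.where(near_pole, sin_t * cp, ux_new)
        uy_new = np.where(near_pole, sin_t * sp, uy_new)
        uz_new = np.where(near_pole, cos_t * np.sign(uz), uz_new)
        norm = np.sqrt(ux_new**2 + uy_new**2 + uz_new**2)
        ux, uy, uz = ux_new / norm, uy_new / norm, uz_new / norm

    r = np.concatenate(rec_r) if rec_r else np.empty(0)
    lpath = np.concatenate(rec_l) if rec_l else np.empty(0)
    order = np.argsort(r, kind="stable")
    record = PhotonPathRecord(
        exit_radius_cm=r[order],
        pathlength_cm=lpath[order],
        weight=np.ones(r.size),
        n_launched=n,
        mu_s_prime_ref=float(mu_s_prime_ref),
        geometry=geometry,
        config=config,
    )
    if record.n_detected == 0:
        raise RuntimeError(
            "no photons detected in the collection window; "
            "increase TransportConfig.n_photons"
        )
    return record


def scaled_reflectance(
    record: PhotonPathRecord,
    target_props: OpticalProperties,
    mu_s_prime_ref: float | None = None,
) -> ReflectanceSpectrum:
    """Reflectance for arbitrary optical properties from the stored record.

    Per wavelength, with k = mu_s'_ref / mu_s'(lambda):

        R(lambda) = (1/N) * sum_i w_i * W(r_i * k) * exp(-mu_a * L_i * k)

    where W is the probe's radial collection window. Scaling ratios outside
    the validity band (x/ div 3 by default) are flagged in the metadata
    rather than raised, so iterative inversions can keep going.
    """
    ref = record.mu_s_prime_ref if mu_s_prime_ref is None else float(mu_s_prime_ref)
    grid = target_props.grid
    k = ref / target_props.mu_s_prime
    geometry = record.geometry
    sds, h = geometry.sds_cm, geometry.window_halfwidth_cm
    r, lpath, w = record.exit_radius_cm, record.pathlength_cm, record.weight
    n = record.n_launched

    refl = np.empty(len(grid))
    se = np.empty(len(grid))
    for i in range(len(grid)):
        ki = k[i]
        i0, i1 = np.searchsorted(r, [(sds - h) / ki, (sds + h) / ki])
        if i0 == i1:
            refl[i] = 0.0
            se[i] = 0.0
            continue
        rs = r[i0:i1] * ki
        c = w[i0:i1] * geometry.collection_weight(rs)
        c *= np.exp(-target_props.mu_a[i] * lpath[i0:i1] * ki)
        refl[i] = c.sum() / n
        se[i] = np.sqrt(np.sum(c * c)) / n

    metadata = {"mu_s_prime_ref": ref, "seed": record.config.seed}
    band = SCALING_VALIDITY_BAND
    if np.any(k > band) or np.any(k < 1.0 / band):
        metadata["validity_warning"] = (
            f"target mu_s' outside x/{band:g} of the reference {ref:g} cm^-1; "
            "similarity scaling accuracy degrades"
        )
    return ReflectanceSpectrum(grid, refl, mc_standard_error=se, metadata=metadata)


def self_calibrate(raw: ReflectanceSpectrum | Spectrum, calibration: ReflectanceSpectrum | Spectrum) -> Spectrum:
    """Point-by-point quotient of tissue spectrum by self-calibration spectrum.

    Any multiplicative instrument drift common to both channels cancels
    exactly. The calibration spectrum must be strictly positive.
    """
    raw_s = raw.as_spectrum() if isinstance(raw, ReflectanceSpectrum) else raw
    cal_s = (
        calibration.as_spectrum()
        if isinstance(calibration, ReflectanceSpectrum)
        else calibration
    )
    if raw_s.grid != cal_s.grid:
        raise ValueError("raw and calibration spectra must share the same grid")
    bad = np.flatnonzero(cal_s.values <= 0)
    if bad.size:
        wl = cal_s.grid.wavelengths[bad[0]]
        raise ValueError(f"calibration spectrum is not positive at {wl:g} nm")
    return Spectrum(raw_s.grid, raw_s.values / cal_s.values, name="calibrated")


# ---------------------------------------------------------------------------
# runtime record cache (binary .npz, never part of the source tree)

def _cache_dir() -> Path:
    env = os.environ.get("HEPOXY_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "hepoxy"


def _record_key(geometry: ProbeGeometry, mu_s_prime_ref: float, config: TransportConfig) -> str:
    payload = json.dumps(
        {"geometry": asdict(geometry), "mu_s_prime_ref": mu_s_prime_ref, "config": asdict(config)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def get_reference_record(
    geometry: ProbeGeometry | None = None,
    mu_s_prime_ref: float = DEFAULT_MU_S_PRIME_REF,
    config: TransportConfig | None = None,
    cache_dir: str | os.PathLike | None = None,
    regenerate: bool = False,
) -> PhotonPathRecord:
    """Load the reference record from the runtime cache, running MC if absent."""
    geometry = geometry or ProbeGeometry()
    config = config or TransportConfig()
    cdir = Path(cache_dir) if cache_dir is not None else _cache_dir()
    path = cdir / f"mcref_{_record_key(geometry, mu_s_prime_ref, config)}.npz"
    if path.exists() and not regenerate:
        dat = np.load(path)
        return PhotonPathRecord(
            exit_radius_cm=dat["r"],
            pathlength_cm=dat["l"],
            weight=dat["w"],
            n_launched=int(dat["n_launched"]),
            mu_s_prime_ref=float(dat["mu_s_prime_ref"]),
            geometry=geometry,
            config=config,
        )
    record = run_reference_mc(geometry, mu_s_prime_ref, config)
    cdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        r=record.exit_radius_cm,
        l=record.pathlength_cm,
        w=record.weight,
        n_launched=record.n_launched,
        mu_s_prime_ref=record.mu_s_prime_ref,
    )
    return record
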