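"""End-to-end analyses: phantom validation, saturation-curve conversion,
vascular-occlusion detection.

Each ``run_*`` function consumes a :class:`RunConfig`, funnels all
randomness through the configured seed, and returns an
:class:`AnalysisReport` bundling result tables (CSV-writable), fitted
parameters (JSON-writable) and a provenance manifest, so a report is
reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import hill, synth
from .chromophores import default_basis
from .forward import ProbeGeometry, TransportConfig, get_reference_record, run_reference_mc
from .inversion import InversionConfig, phantom_cross_validation
from .spectra import SpectralGrid


@dataclass
class RunConfig:
    """Configuration for the pipeline analyses (YAML/JSON serializable)."""

    analysis: str = "phantoms"  # phantoms | conversion | occlusion
    seed: int = 0
    out_dir: str | None = None
    n_photons: int = 300_000
    mc_seed: int = 20210521
    use_mc_cache: bool = False
    fit_wavelength_step_nm: float = 4.0
    n_phantoms: int = 16
    bypass: synth.BypassExperimentSpec = field(default_factory=synth.BypassExperimentSpec)
    phantom: synth.PhantomSeriesSpec = field(default_factory=synth.PhantomSeriesSpec)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: run config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "bypass" in data:
            data["bypass"] = synth.BypassExperimentSpec(**data["bypass"])
        if "phantom" in data:
            data["phantom"] = synth.PhantomSeriesSpec(**data["phantom"])
        return cls(**data)


@dataclass
class AnalysisReport:
    tables: dict[str, pd.DataFrame]
    params: dict
    manifest: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "params.json").write_text(json.dumps(self.params, indent=2, default=float))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=float))
        return out


def _reference_record(config: RunConfig):
    geometry = ProbeGeometry()
    tcfg = TransportConfig(n_photons=config.n_photons, seed=config.mc_seed)
    if config.use_mc_cache:
        return get_reference_record(geometry, config=tcfg)
    return run_reference_mc(geometry, config=tcfg)


def run_phantom_validation(config: RunConfig) -> AnalysisReport:
    """Rotating-reference inversion accuracy over the synthetic titration series."""
    grid = SpectralGrid.default()
    basis = default_basis(grid, include_biliverdin=False)
    record = _reference_record(config)
    pspec = config.phantom
    if config.n_phantoms != pspec.n_phantoms:
        pspec = synth.PhantomSeriesSpec(
            **{**asdict(pspec), "sphere": pspec.sphere, "n_phantoms": config.n_phantoms}
        )
    samples, manifest = synth.make_phantom_series(pspec, config.seed, record, basis, grid)
    icfg = InversionConfig(
        scatter_model="mie",
        sphere_spec=pspec.sphere,
        fit_wavelength_step_nm=config.fit_wavelength_step_nm,
    )
    cv = phantom_cross_validation(
        [(s.props, s.spectrum) for s in samples], basis, icfg, record
    )
    params = {
        "avg_mu_a_percent_error": cv.avg_mu_a_percent_error,
        "avg_mu_s_prime_percent_error": cv.avg_mu_s_prime_percent_error,
        "mu_a_range_cm1": [samples[0].mean_mu_a, samples[-1].mean_mu_a],
        "mu_s_prime_range_cm1": [samples[0].mean_mu_s_prime, samples[-1].mean_mu_s_prime],
    }
    manifest = {
        "analysis": "phantom_validation",
        "seed": config.seed,
        "mc": {"n_photons": config.n_photons, "seed": config.mc_seed},
        "reference_assignments": sorted(cv.pairs["reference"].unique().tolist()),
        "series": manifest,
    }
    return AnalysisReport(
        tables={"cross_validation_pairs": cv.pairs, "per_target": cv.per_target},
        params=params,
        manifest=manifest,
    )


def run_conversion_analysis(config: RunConfig) -> AnalysisReport:
    """Hill-model fits, nested comparison, conversion derivation and check."""
    data = synth.make_bypass_dataset(config.bypass, config.seed)
    df = data.table
    fits: dict[str, hill.HillFit] = {}
    warnings: list[str] = []
    fit3 = hill.fit_hill(df, model=3)
    fits["model3"] = fit3
    n_groups = df["ph_group"].nunique()
    if n_groups >= 2:
        fits["model1"] = hill.fit_hill(df, model=1)
        fits["model2"] = hill.fit_hill(df, model=2)
    else:
        warnings.append("fewer than 2 pH groups: models 1-2 skipped, using model 3 only")
    fit_fixed = hill.fit_hill(df, model=3, fix_n=config.bypass.reference.n)

    comparisons = {}
    if "model2" in fits:
        f, p = hill.compare_models(fits["model3"], fits["model2"], df)
        comparisons["model3_vs_model2"] = {"F": f, "p": p}
        f, p = hill.compare_models(fits["model3"], fits["model1"], df)
        comparisons["model3_vs_model1"] = {"F": f, "p": p}
    f, p = hill.compare_models(fit_fixed, fit3, df)
    comparisons["fixed_n_vs_model3"] = {"F": f, "p": p}

    pooled = fit3.pooled
    coeff = hill.derive_conversion(config.bypass.reference, pooled)
    converted = hill.apply_conversion(df["reading"].to_numpy(), coeff)
    so2_ref = df["so2_reference"].to_numpy()

    def r2(pred, obs):
        tss = np.sum((obs - obs.mean()) ** 2)
        return float(1.0 - np.sum((obs - pred) ** 2) / tss)

    r2_converted = r2(converted, so2_ref)
    r2_unconverted = r2(df["reading"].to_numpy(), so2_ref)

    cvs = [float(100.0 * np.std(s, ddof=1) / np.mean(s)) for s in data.replicate_sets]

    out = df.assign(converted_so2=converted)
    params = {
        "fits": {
            name: {
                "params": {g: asdict(p) for g, p in f.params.items()},
                "std_errors": {g: asdict(p) for g, p in f.std_errors.items()},
                "r_squared": f.r_squared,
                "rss": f.rss,
            }
            for name, f in {**fits, "model3_fixed_n": fit_fixed}.items()
        },
        "comparisons": comparisons,
        "conversion": {"c": coeff.c, "r": coeff.r, "a": coeff.a},
        "r_squared_converted_vs_reference": r2_converted,
        "r_squared_unconverted_vs_reference": r2_unconverted,
        "replicate_cv_percent": {"min": min(cvs), "max": max(cvs)},
        "warnings": warnings,
    }
    manifest = {"analysis": "conversion", "seed": config.seed, "data": data.manifest}
    return AnalysisReport(tables={"bypass_with_conversion": out}, params=params, manifest=manifest)


def run_occlusion_analysis(
    config: RunConfig,
    scenarios: dict[str, synth.OcclusionScenario] | None = None,
) -> AnalysisReport:
    """Per-phase saturation deltas with significance tests per lobe."""
    scenarios = scenarios or {
        "hepatic_artery": synth.HEPATIC_ARTERY,
        "portal_vein": synth.PORTAL_VEIN,
        "selective_right_artery": synth.SELECTIVE_RIGHT_ARTERY,
    }
    rows = []
    tables = {}
    for i, (name, scen) in enumerate(sorted(scenarios.items())):
        series, _ = synth.make_occlusion_series(scen, config.seed + i)
        tables[f"series_{name}"] = series
        for lobe, sub in series.groupby("lobe"):
            if "baseline" not in set(sub["phase"]):
                raise ValueError(f"{name}/{lobe}: missing baseline phase")
            base = sub.loc[sub["phase"] == "baseline", "reading"].to_numpy()
            for phase, vals in sub.groupby("phase"):
                if phase == "baseline":
                    continue
                v = vals["reading"].to_numpy()
                t, p = sps.ttest_ind(v, base, equal_var=False)
                rows.append(
                    {
                        "scenario": name,
                        "lobe": lobe,
                        "phase": phase,
                        "delta_pct": float(v.mean() - base.mean()),
                        "t": float(t),
                        "p": float(p),
                        "n_phase": v.size,
                        "n_baseline": base.size,
                    }
                )
    deltas = pd.DataFrame(rows)
    sel = deltas[(deltas["scenario"] == "selective_right_artery") & (deltas["phase"] == "occlusion")]
    opposite = (
        bool(np.prod(np.sign(sel["delta_pct"].to_numpy())) < 0) if len(sel) == 2 else None
    )
    params = {
        "occlusion_deltas": deltas[deltas["phase"] == "occlusion"][
            ["scenario", "lobe", "delta_pct", "p"]
        ].to_dict("records"),
        "selective_opposite_signed_lobes": opposite,
    }
    manifest = {"analysis": "occlusion", "seed": config.seed, "scenarios": sorted(scenarios)}
    return AnalysisReport(tables={**tables, "deltas": deltas}, params=params, manifest=manifest)
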