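# Methods

This note documents the models behind `hepoxy`, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
establish about real measurements.

## Spectral basis

All optics work on a strictly increasing wavelength grid restricted to
400–700 nm; the default analysis band is 435–630 nm at 1-nm steps, where
hemoglobin dominates liver absorption and the probe detects usable signal.

Absorption is Beer–Lambert over oxyhemoglobin, deoxyhemoglobin and
biliverdin, with concentrations in µM (hemoglobin per tetramer, 64,500
g/mol, so 1 g/dL ≈ 155 µM; the tetramer basis is a package convention —
heme-basis tables would differ by 4×). Extinction tables are base-10 molar
extinction; the ln(10) factor converting to natural-log transport
coefficients is applied inside `compose_mu_a`, never stored in the tables.

The bundled tables are **synthetic tabulations** (see
`scripts/generate_extinction_tables.py`): sums of Gaussian bands placed at
the landmark features of the hemoglobin visible spectrum — the Soret bands
at 414 nm (oxy) and 430 nm (deoxy), the oxy Q-band doublet at 542/577 nm,
the single deoxy band at 555 nm, and a red tail with deoxy > oxy beyond
600 nm. The overall amplitude is calibrated so a fully oxygenated 46.36 µM
solution has a band-mean µa of 3.87 cm⁻¹, the value consistent with the
liver-phantom design this package emulates. The biliverdin shape (broad
377/670-nm bands) is likewise a stand-in; no public standard tabulation is
bundled. Consequences: *relative* and structural results (linearity,
inversion self-consistency, saturation leverage, biliverdin bias patterns)
are faithful; absolute chromophore spectra should not be quoted from these
tables, and users with a preferred compilation can load it via
`load_extinction(name, path=...)` in the same CSV dialect.

## Scattering

Phantom scattering is Lorenz–Mie for homogeneous spheres (default 1-µm
polystyrene, n=1.59, in water, n=1.33) with the anisotropy g from the full
partial-wave series; µs′ = N·Csca·(1−g) is exactly linear in number
density. Index dispersion is neglected (constant-index, sub-percent over
the band). The Mie coefficients use the standard downward recurrence for
the logarithmic derivative; an independent spherical-Bessel implementation
in the test suite agrees to 1e-8 relative.

Tissue scattering uses the conventional power law a·(λ/500 nm)^(−b) with
a > 0, b ≥ 0. A power-law fit to the 1-µm-sphere Mie curve over the band
has RMSE < 2% of the mean, so either parameterization describes the
phantoms well.

## Forward model: scaled white Monte Carlo

One reference transport run is stored and reused for every forward
evaluation:

* semi-infinite homogeneous medium, zero absorption, reference
  µs′ = 15 cm⁻¹ (µs = 150 cm⁻¹ at g = 0.9, Henyey–Greenstein);
* pencil source at the origin (the 6-fiber illumination ring and the
  central detection fiber at 1.2 mm are collapsed, by reciprocity, to a
  radial collection window around the source–detector separation);
* boundary: tissue n = 1.38 against the probe face n = 1.45, unpolarized
  Fresnel decided stochastically at each surface hit; collection restricted
  to the fiber NA (0.22) acceptance cone. A matched-boundary, full-aperture
  configuration exists for physics checks;
* recorded per detected photon: exit radius and total path length; photons
  are terminated at 25 cm path, 3 cm depth or 3 cm radius (their window
  contribution is negligible at liver-like absorption).

Reflectance for arbitrary (µa(λ), µs′(λ)) is then, with
k(λ) = µs′_ref/µs′(λ):

R(λ) = (1/N) Σᵢ wᵢ · W(rᵢ·k) · exp(−µa·Lᵢ·k)

i.e. similarity rescaling of the stored geometry plus Beer attenuation of
the scaled paths. Scaling the exit radii as well as the path lengths is
essential: attenuation-only scaling would leave R a function of µa/µs′
alone and make hemoglobin and scatter amplitude jointly unidentifiable.
Ratios k outside ×/÷3 are flagged in result metadata (similarity accuracy
degrades) but never raised, so inversions can iterate through bad regions.

W is a raised-cosine window of half-width one core diameter (200 µm)
centred on the SDS. A smooth window keeps R continuously differentiable in
the scatter parameters; a hard annulus would make photon membership
discrete and defeat gradient-based fitting. Checks: the matched-boundary
configuration agrees with the dipole diffusion solution at ρ = 1.2 mm to
within ~8% for µa ≤ 0.1 cm⁻¹ (15% tolerance asserted); reflectance is
strictly decreasing in µa, and increasing in µs′ throughout the phantom
regime (µa ≈ 4–9, µs′ ≈ 6–17 cm⁻¹) — at this short SDS the
attenuation-relief effect of extra scattering dominates.

Monte Carlo noise is *shared* between synthetic measurements and model
predictions (both evaluate through the same record), so inversion accuracy
on synthetic data reflects optimizer and model-structure error, not photon
statistics. Real spectra do not share noise with the model; the validation
here therefore bounds algorithmic error only, which is the role the
phantom-titration bench experiment plays for a real instrument. The
standard error estimate per wavelength follows the usual Σc² form and
scales as n_photons^(−1/2).

## Inversion

Fits minimize the relative residual between the measured ratio
(calibrated target / reference-phantom measurement) and the model ratio
(forward(θ)/forward(reference properties)); instrument throughput and any
common drift cancel in both numerator and denominator, matching the
self-calibrating probe design. Parameters: total Hb (0–300 µM), SO2 (0–1),
scatter amplitude (1–40 cm⁻¹) and power (0–3) or Mie density, optionally
biliverdin (0–100 µM).

Optimization is bounded trust-region least squares with a fixed,
deterministic start list: three primary starts spanning low/mid/high
hemoglobin, a fallback trio tried only while the best cost remains above
1e-8, and a final restart from the incumbent (resetting the trust region
reliably escapes the shallow local minima that the piecewise-smooth scaled
MC objective exhibits). Fitting uses a 4-nm decimation of the band (49
points); reported wavelength-averaged µa and µs′ are recomputed from the
fitted parameters on the full 1-nm grid.

Identifiability limits worth knowing: at very high absorption (total Hb
well above ~130 µM with liver-like scattering) the detected signal is weak
and the five-parameter biliverdin-included fit becomes sloppy along a
(Hb, biliverdin, scatter) ridge; the phantom range and the physiologic
liver range sit comfortably below this.

Rotating-reference cross-validation (every phantom once as reference, all
as targets, self-pairs included) reports per-target spread over reference
choices and the set-wide mean percent errors of wavelength-averaged µa and
µs′ — the standard bench figure of merit for this instrument class. On the
noise-free synthetic 16-phantom series the errors are at numerical-zero
level, comfortably inside the 1.86% / 4.43% instrument-level bounds used
as acceptance thresholds.

## Hill fitting and the conversion formula

The reference pig dissociation curve is n = 3.02, P50 = 32.929 mmHg (the
scaled printed form (0.13534·PO2)^3.02/(91.2 + …) is the same curve:
91.2^(1/3.02)/0.13534 = 32.929). Reading-vs-PO2 data are fitted on the raw
percent scale by nonlinear least squares; the logit linearization
logit(v) = n·(ln PO2 − ln P50) seeds the optimizer and provides
diagnostics. R² is reported on the reading scale (1 − RSS/TSS); parameter
standard errors come from the Jacobian at the optimum. Three nested models
handle the two pH condition groups (7.1–7.25 and 7.3–7.4, treated strictly
as labels — no continuous Bohr model): pooled (3), shared-n/per-group-P50
(1), fully per-group (2), plus a fixed-n variant for comparing against the
reference cooperativity. Model comparison is the extra-sum-of-squares F
test (the choice of test where the source analysis names none); its type-I
error is verified at 5% ± 2% over 500 null replicates with homoscedastic
noise. Larger models are guaranteed no worse in RSS; a marginal optimizer
inversion clamps F at 0.

Equating reference and fitted Hill curves gives the reading-to-saturation
correction on the saturation odds q = v/(100−v):

SO2(v) = 100·X/(1+X), X = c·q^r, r = n_ref/n_fit,
c = (P50_fit/P50_ref)^n_ref

For the pooled parameters (1.67, 34.00): r = 1.81, c = 1.10 at two
decimals. Note the widely quoted closed form with the *inverted* odds
((100−v)/v) raised to r and the same c does **not** reproduce the
underlying curves (it errs by up to ~5 percentage points mid-range); the
coefficient enters that form reciprocally. The implementation keeps c on
the odds, which makes apply∘hill(fitted) ≡ hill(reference) exact (asserted
to 10 decimals), fixes the endpoints, and is strictly increasing. Both the
(c, r) and the a = c^(1/r) parameterizations are exposed.

## Agreement statistics

Lin's CCC uses population moments; its SE is Lin's asymptotic variance of
the Fisher-transformed coefficient, with an effective sample size
n_eff = N/(1 + (m̄−1)·ICC) when subjects contribute replicates (ICC from
one-way ANOVA on pair means). The exact replicate correction used in the
source studies is not public; this design-effect form is a documented
assumption with a plain-N fallback. CIs are Fisher-z. The overlapping
dependent correlation test is Meng–Rosenthal–Rubin with the f ≤ 1 cap;
its null calibration is simulation-tested. CV is the sample (n−1) form in
percent of the mean. All tests are two-sided at α = 0.05.

## Synthetic experiments: what they emulate

* **Phantom titration** — 16 steps in which hemoglobin stock is added to a
  fixed sphere population: volumes grow linearly by the factor carrying
  mean µs′ from 17.33 to 5.96 cm⁻¹ (sphere number conserved), the stock
  concentration solved so Hb spans 46.36–112.01 µM; band-mean µa then
  spans 3.87–9.35 cm⁻¹ by construction. Spectra are forward-model
  reflectances times an LED-shaped throughput, divided by a concurrent
  self-calibration channel; noise optional (default off — the bench
  acceptance case is noise-free).
* **Bypass sweeps** — 39 (PO2, reading) points with PO2 log-uniform on
  5–300 mmHg (the realized tensions behind a 2–100% delivered-O2 titration
  are not fixed, so both sigmoid shoulders are populated by design),
  readings from the generating Hill curve (pooled parameters 1.67/34) with
  1.15% multiplicative noise — chosen so 20-replicate steady-state sets
  have CVs inside the observed 0.7–1.6% band; blood-gas SO2 always from
  the reference curve. The recovery simulations use 1.5% noise, the
  steady-state CV level.
* **Occlusion time courses** — piecewise-constant saturation with additive
  2% noise; hepatic-artery, portal-vein (−44.4 / −54.3%) and selective
  right-artery scenarios (−14.7% monitored lobe, +4.8% contralateral),
  recovery returning to baseline. The stated drops are generator inputs;
  what the pipeline demonstrates is detection: significant, correctly
  signed deltas in ≥95% of seeds at these effect sizes.
* **Hemodilution** — true Hb declining 12→2.5 g/dL over 33 points across
  FiO2 ∈ {0.21, 0.3, 1.0}; the analyzer adds 0.15 g/dL noise, the optical
  estimate an 18% proportional error, putting the log-log R² in the
  0.7–0.95 band that matches in-vivo dispersion. A "3 mg/dL" dilution
  step quoted for the bench protocol is read as g/dL (mg/dL hemoglobin
  steps are physiologically meaningless).

All generators are seed-deterministic and attach a manifest (generator,
spec, seed) to their outputs.

Because readings are generated *from* Hill curves and spectra *through*
the package's own transport model, passing tests establish internal
consistency, correct algebra and statistical calibration — not instrument
performance on real livers. Features of real data deliberately absent:
probe-pressure and contact artifacts, tissue heterogeneity and vessels,
methemoglobin/carboxyhemoglobin, temperature and 2,3-DPG effects on the
dissociation curve, per-animal random effects, and drift that is not
common-mode between channels.

## Problem sizes and numerics

Default problem sizes: 3×10⁵ photons for the reference record (recorded
photons ≈ 7×10³; detected in the nominal window ≈ 10³), 16 phantoms × 16
references for cross-validation, 200 datasets for recovery simulations,
500 replicates for test calibration. These sizes put every Monte Carlo
quantity well past its asymptotic regime while keeping a full validation
run in minutes on one core; the record can be regenerated at any size and
is cached (binary, runtime-only) keyed by geometry and transport settings.
Optimizer tolerances are 1e-12 (ftol/xtol); degenerate inputs (zero
spectra, non-positive calibration, empty phantom sets, readings at 0 or
100%) raise informative errors at the boundary of each module.
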