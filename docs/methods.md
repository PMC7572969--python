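# Methods

`pibquant` quantifies regional amyloid burden from dynamic [11C]PiB PET
time–activity curves (TACs) and compares candidate reference regions against
the plasma-input gold standard. This note documents the models, the numerical
choices, what the synthetic cohorts emulate, and the known limitations.

## Data model and conventions

All times are minutes post injection; activity concentration is kBq/mL,
decay-corrected to injection time upstream (the package never handles decay).
Frame values are treated as instantaneous samples at frame mid-times; the
underlying curve is 0 at t = 0 (tracer not yet arrived), linear between
samples, and held constant from the last mid-time to the scan end. All
integrals (SUV windows, Logan running integrals) use the trapezoidal rule on
that piecewise-linear curve. These conventions are standard dynamic-PET
practice; frame-end sampling would shift Logan abscissae slightly but not
qualitatively.

The frame schedule shipped as a default (20 frames over 90 min: 4×0.25,
4×1, 2×2.5, 4×5, 6×10 min) is a plausible dynamic-PiB framing declared as a
fixture, not a reproduction of any particular scanner protocol.

## Kinetic models

**Plasma-input model (2T4k_Vb).** The reversible two-tissue compartment model
with rate constants K1 (mL·cm⁻³·min⁻¹), k2, k3, k4 (min⁻¹) and fractional
blood volume Vb. The tissue response is the analytic bi-exponential impulse
response convolved with the metabolite-corrected plasma curve on a uniform
0.05-min grid (trapezoidal discrete convolution, FFT-accelerated); the
measured signal is (1−Vb)·C_tissue + Vb·C_wholeblood, averaged over each
frame. The macro-outcome is the volume of distribution
V_T = (K1/k2)(1 + k3/k4), and DVR = V_T(target)/V_T(reference); with
cerebellar grey matter (GMCB) as reference this DVR_PI_GMCB is the gold
standard all other measures are judged against.

Fitting is bounded weighted least squares (scipy `least_squares`, trust
region reflective, tolerances 1e-12) with deterministic multi-start: a
default start, a weak-binding start (k3 ≈ 0 basin, where low-amyloid regions
live), and seeded random starts within bounds (5 total by default). Weights
default to frame durations (uniform optional). Default bounds: K1 ∈ (1e-4, 2],
k2, k3, k4 ∈ (1e-4, 1], Vb ∈ [0, 0.15].

*Nested model selection.* On regions with little specific binding the full
model is weakly identified: noise can be absorbed by a spurious ultra-slow
compartment (k4 pinned at its lower bound) that inflates V_T several-fold
while barely improving the residuals. The fitter therefore also fits the
nested one-tissue model (k3 = 0) and keeps it when the second compartment
does not earn its AICc penalty (AICc rather than AIC because 20 frames vs 6
parameters is firmly small-sample territory), or when the fitted k4 sits at
its lower bound — a time constant far beyond the scan cannot be evidence for
a second compartment. The chosen model is recorded in the fit diagnostics.
On noise-free two-tissue data the full model always wins (its RSS is at
numerical zero), so recovery of generating parameters is unaffected.

**Reference Logan.** Late-time slope of y(T) = ∫₀ᵀC_t/C_t(T) against
x(T) = ∫₀ᵀC_ref/C_t(T) over frame mid-times T strictly greater than
t* = 50 min (default), by ordinary least squares; the slope is reported as
DVR and the k2′ term is omitted. With the default 90-min schedule four
10-min frames (mid-times 55–85 min) enter the regression. The method
carries the well-known truncation bias: for slowly equilibrating two-tissue
targets (small k4) the plot is not fully linear by t* and DVR is
underestimated by a few percent; on one-tissue targets it is essentially
exact.

**SRTM.** C_t = R1·C_ref + (k2 − R1·k2a)·[C_ref ⊗ e^(−k2a·t)] with
k2a = k2/(1+BP_ND); DVR = BP_ND + 1 always and everywhere. The convolution
term is evaluated on the 0.05-min grid; the R1 term uses the exact reference
frame samples. Default bounds are R1 ∈ [0.1, 3], k2 ∈ [0.006, 0.6] min⁻¹,
BP_ND ∈ [−0.5, 10], with per-reference overrides: for the white-matter
references (WMBS, WBS, WMES) the k2 floor is raised to 0.02 min⁻¹ and BP_ND
capped at 6, because with a slow dissimilar reference the SRTM cost surface
develops a degenerate valley as k2 → 0 in which BP_ND is unidentifiable.
Per-reference boundary tuning is exactly what the original analysis did; the
numeric values here are this package's own, chosen from that identifiability
analysis.

**SUV / SUVr.** SUV = window-mean activity divided by injected dose per gram
of body weight (g/mL); SUVr is the ratio of window means and needs no dose.
Window means are time-integrals over the window divided by its length
(robust to unequal frame durations), for the two canonical windows 40–60
and 60–90 min.

## Statistics layer

* Test–retest variability: |T − R| / (0.5·|T + R|) · 100 (%), on the
  volume-weighted composite cortical value.
* Outliers: MAD criterion with multiplier 3 and normal-consistency constant
  1.4826, applied across subjects within each region × method × reference
  group before any downstream analysis; when MAD = 0 only values strictly
  different from the median are flagged. Every exclusion is logged with its
  group median and MAD.
* Agreement: the method value is regressed on the gold standard (slope < 1
  therefore reads as underestimation), plus Pearson r; Bland–Altman bias,
  1.96·SD limits (sample SD), and an OLS trend of difference on pairwise
  mean to expose burden-dependent bias. Regional values of test scans are
  pooled by default.
* Longitudinal stability: paired t tests on reference-region SUVs per
  window, with follow-up standardised linearly in time to 2.6 years and
  Bonferroni correction over the five reference regions.
* Annual change: ((FU − BL)/years)·(100/BL) per subject on the composite,
  plotted against baseline; linear and quadratic OLS fits compared by
  AIC = n·ln(RSS/n) + 2k with k counting coefficients plus the error
  variance. AICc is reported alongside; selection uses plain AIC here.
  Note AIC's inherent ~16% false preference for the quadratic on truly
  linear data (the χ²₁ > 2 event) — a property of the criterion, not a bug.
* Discrimination: Mann–Whitney U (exact enumeration p for m+n ≤ 12 without
  ties, normal approximation with tie correction otherwise; delegated to
  scipy behind this surface) with Bonferroni over 20 tests (5 references ×
  4 reference-tissue methods), and the Hodges–Lehmann median of pairwise
  differences as effect size, computed amyloid-negative minus
  amyloid-positive so effects come out negative.

The `ParameterTable` method vocabulary includes `SUV_40_60` / `SUV_60_90`
rows (region = the reference region itself) so the longitudinal stability
analysis can travel through the same CSV interchange format as the ratio
outcomes.

## Synthetic cohorts

The generator emulates the study design, not any patient's data: 90-min
dynamic scans, one arterial input, ~19 cortical targets and the five
candidate references. Defaults (declared simulation conditions, not
measurements):

* **Input function**: Feng-type plasma curve (sharp peak ~1 min, bi-exponential
  tail; A1 = 200, A2 = 5, A3 = 4 kBq/mL, λ = −4, −0.12, −0.01 min⁻¹, 0.5-min
  delay), scaled per scan by injected dose per unit body mass. The whole-blood
  curve is derived through the inverse corrections (parent fraction falling
  exponentially from 1 to a 0.15 plateau, τ = 20 min; plasma/whole-blood ratio
  rising slowly above 1.05), so the blood-table round trip is exact.
* **Reference kinetics**: GMCB fast one-tissue (K1 = 0.30, k2 = 0.15,
  V_T = 2.0); white matter slower and higher-V_T (WMBS 0.10/0.037, V_T ≈ 2.7;
  WMES 0.09/0.030, V_T = 3.0); WCB and WBS as explicit 70/30 volume-weighted
  grey/white mixtures. These choices reproduce the qualitative orderings —
  cerebellar TACs decline fastest, white matter slowest, and reference-method
  agreement slopes fall below 1 for white-matter references with WMES worst —
  without claiming any numeric fidelity to real PiB white matter.
* **Targets**: two-tissue profiles with K1/k2 matched to GMCB and
  k3 = k4·(DVR−1), k4 = 0.03; amyloid-negative range DVR 0.95–1.2,
  positive 1.8–2.5; Vb = 0.05 everywhere. A one-tissue (SRTM-consistent)
  target mode exists for method-validity checks, used with Vb = 0 because
  reference-tissue theory ignores the blood term.
* **Noise**: Gaussian per frame with SD = level·max(value, floor)/√duration
  (floor = 5% of the TAC maximum), level 0.05 by default — a standard
  TAC-level surrogate for reconstruction noise, not Poisson counts.
* **Test–retest**: two scans per subject from identical kinetics with
  independent noise; arterial data attached to both.
* **Longitudinal**: baseline burden spread evenly over DVR 1.0–2.5;
  follow-up interval truncated-normal 2.6 ± 0.45 y within [1.9, 4.0];
  annual DVR accumulation is an inverted-U in baseline burden
  (max 5%/y at DVR 1.75, Gaussian width 0.4), implemented through k3;
  optional white-matter drift scales brainstem K1 by (1+d/100)^years
  (d = −2%/y in the demo), dragging V_T and late-window SUV down together —
  scaling k2 in compensation would leave the 60–90 min SUV almost unchanged
  because slow white matter is near equilibrium there. No arterial data are
  attached (mirroring the design), but dose and weight are, so SUVs are
  computable.

What passing tests on these cohorts do **not** show: robustness to real-data
features the generator omits — partial-volume and spill-over effects, motion,
scatter, plasma metabolite model error, delay/dispersion in the blood curve,
atlas missegmentation, and population kinetic variability beyond the
uniform DVR draws.

## Problem sizes

The validation battery runs at desk scale on one CPU: full-scan parameter
recovery uses one 24-region scan plus 50 noise replicates of a single target;
the method-validity grid is six DVR levels; test–retest ordering uses 20
subjects at two noise levels with the fast methods; drift stability 18
subjects; accumulation model selection 50 seeds × 30 subjects with reference
Logan only; the demo cohorts are 6 test–retest and 12 longitudinal subjects
with 4 targets. These sizes are the package's choices for a tractable demo
battery and are stated in each experiment's docstring.

## Known limitations

* Reference Logan inherits t* truncation bias for slow k4; no k2′ term.
* SRTM on two-tissue targets (all realistic cohorts) is a deliberately
  mis-specified fit, as in practice; its bias against gold is part of what
  the comparison measures.
* The composite cortical value is the volume-weighted mean of regional
  outcome values, not a fitted composite TAC.
* No image-space processing of any kind; the pipeline begins at extracted
  TACs.
* Exclusion decisions (MAD3) are made at the regional-analysis level and do
  not cascade into the composite values.
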