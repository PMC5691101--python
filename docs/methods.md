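# Methods

This note documents the physical model behind the simulator, the inverse
analysis chain, the defaults and why they were chosen, and what the tests
do and do not demonstrate.

## Forward model of the acquisition

**Lineshape.** Each LiPc deposit contributes a single exchange-narrowed
Lorentzian absorption line; Voigt/Gaussian components are out of scope. The
line is parametrised directly by its first-derivative peak-to-peak width
ΔB_pp (the oximetric observable); the Lorentzian half-width at half-maximum
is Γ = (√3/2)·ΔB_pp, and the derivative extrema sit at centre ± ΔB_pp/2.
The truth model is affine in oxygen, ΔB_pp = ΔB₀ + k·pO₂, optionally scaled
by a microwave-saturation factor √(1+s) (off by default: the emulated
low-Q L-band resonator keeps B₁ small even at 36 mW).

**Gradient multiplexing and probe footprint.** A static gradient G (G/cm)
along the sweep axis shifts each probe's resonance by G·x. The probe is not
a point: it is modelled as a uniform 1-D segment of length 1.4 mm (the
physical probe length) along the gradient axis, so its line is the average
of Lorentzians spread over `G × footprint_length` — 0.14 G at 1 G/cm, a
substantial extra broadening at typical linewidths. Full 3-D averaging and
probe orientation are not modelled. With the gradient off the footprint has
no effect.

**Detection.** Field modulation with lock-in detection is computed by
numerical first-harmonic projection (pseudo-modulation): at each field
point the absorption is sampled along one modulation cycle (48 midpoint
nodes; midpoint quadrature is spectrally accurate for this periodic
integrand) and projected onto the fundamental. The output is scaled by
2/B_m so the small-modulation limit is exactly the analytic first
derivative; no closed-form overmodulation approximation is used anywhere.
The detected signal then passes a causal single-pole RC filter with the
acquisition time constant (per-sample coefficient α = exp(−Δt/τ),
Δt = sweep_time/(n−1); for the standard 20.48 ms / 10 s / 512-point
protocol, α ≈ 0.3846), which drags peaks along the sweep direction.

**Noise and drift.** White Gaussian noise of sd `noise_sd/√n_averages` is
added, plus a polynomial baseline (degree 1 by default) standing in for
slow drift. 1/f structure beyond the linear baseline is not modelled. A
zero-probe, zero-noise simulation is exactly zero (the empty-resonator
case).

## Inverse chain

`analyze_spectrum` runs, deterministically for a fixed input and config:

1. **Baseline removal.** A first pass (smooth + detect) locates candidate
   lines; a polynomial (degree 1) is then fitted only on wing samples —
   the outer 15% of the sweep at each end — that no detected line reaches
   (1.5 line widths of clearance). If the lines fill the window, detrending
   is skipped and flagged: fitting a baseline through a line distorts it.
2. **Smoothing.** Zero-phase single-pole exponential smoothing (forward +
   backward pass), default τ = 40.96 ms = 2× the acquisition time
   constant. Chosen to suppress sample-scale noise ripple while inflating
   noise-free widths by at most ~2.3% over the 0.2–1.0 G grid, well inside
   the ≤10% digital-filtration broadening budget the protocol tolerates —
   and the inflation is removed exactly by the correction anyway. The
   causal variant exists for acquisition emulation only.
3. **Detection.** Local extrema with both amplitude and prominence above
   the threshold. The default threshold is reproducible rather than
   interactive: 5× the robust noise scale (1.4826·MAD of successive
   differences / √2, estimated on the *unsmoothed* trace and propagated
   through the smoother's analytic noise gain — the difference-based
   estimator is biased low on correlated smoothed noise). The prominence
   requirement keeps noise ripple riding on a broad line crest from
   spawning spurious extrema. An explicit numeric threshold remains
   settable. Zero detections return an empty, flagged result.
4. **Refinement.** Each extremum is localised below the grid by a
   least-squares parabola. The bare `refine_peak` operation defaults to a
   5-point window (w = 2), which localises noise-free Lorentzian-derivative
   extrema to better than a tenth of the 5.87 mG grid spacing. For width
   *measurement* the pipeline runs a second pass whose window scales with
   the detected line width (0.7× the raw width, capped at 25 samples and at
   the trace edge): at realistic SNR the vertex of a 5-point parabola on a
   ~30-sample-wide line is noise-dominated, while the wide window averages
   over many samples. The wide window's systematic (model-mismatch) bias is
   not a problem because the correction model measures its own forward
   signal with the identical window — the bias cancels by construction.
5. **Assignment.** Consecutive (+,−) extremum pairs become lines. When the
   probe count is known, the subset of pairings minimising the mismatch
   between consecutive line spacings and the expected gradient separation
   is selected by exhaustive search; unpaired extrema, missing lines and
   overlapping lines (centre distance below the sum of half-widths) are
   flagged, never silently dropped.
6. **Width correction.** The true ΔB_pp is found by inverting the package's
   own forward chain — Lorentzian → footprint smear (when a gradient was
   on) → field modulation → causal acquisition RC → the same baseline
   projection the data received (it is linear, so applying the identical
   fit mask to the model mirrors its effect, including the slow Lorentzian
   tails it inevitably shaves) → zero-phase smoothing → the same
   wide-window measurement. The root of `apparent(x) = raw` is bracketed by
   sign change and solved with Brent's method (xtol 10⁻⁷ G). The map is
   increasing in the ordinary regime but can *decrease* with true width
   under heavy overmodulation (B_m/ΔB_pp ≈ 2), hence sign-change
   bracketing rather than assumed monotonicity. A raw width below the
   modulation/smear floor is flagged `uncorrectable` and left unset. The
   model also yields the apparent-centre shift of the causal RC filter,
   which is subtracted from the reported line centre.
7. **Neighbour deflation.** With several resolved lines, one iteration of
   peak deflation re-measures each line on the trace minus the modelled
   signals of the others (scaled to the measured extremum amplitudes) and
   re-corrects: the single-line correction model cannot see neighbour
   tails, which otherwise bias wide-window refinement by ~0.1 mmHg
   equivalent at 1 G line separation.

Because stage 6 inverts the exact discrete forward model on the same grid,
noise-free round trips are limited only by solver tolerance: over the
factorial ΔB_pp ∈ {0.2…1.0 G} × B_m/ΔB_pp ∈ {0, 0.2, 1, 2} × acquisition
τ ∈ {0, Δt, 2Δt}, corrected widths agree with truth to ≲0.2% and centres
to ≪1 grid spacing. The pipeline is invariant under intensity rescaling
(auto threshold and all geometry scale together).

**Uncertainty.** A line's width standard error is the heuristic
√2·Δx/SNR (grid spacing over the measured peak SNR, one factor per
extremum); pO₂ errors divide by the calibration slope. This tracks the
noise-dominated regime the heuristic was designed for and is not a full
covariance treatment.

## Calibration

pO₂ = (ΔB_pp,corrected − ΔB₀)/k. The package default (ΔB₀ = 0.050 G,
k = 0.006 G/mmHg, valid 0–100 mmHg) is of literature magnitude for LiPc
but deliberately marked non-authoritative: calibration is probe-batch
chemistry and must come from a bench fit (`fit_calibration`, ordinary
least squares with slope/intercept standard errors and residual sd,
requiring ≥3 distinct pO₂ levels). Temperature dependence is out of scope
(single body-temperature curve). Negative pO₂ estimates are reported as
computed with a `below-anoxic` flag, never clamped.

## Synthetic cohorts

`CohortDesign` emulates a two-group (control vs cetuximab-style treated)
bilateral-xenograft study: per-animal random effects plus per-tumour noise
on pO₂ (truncated at 0), exponential tumour growth with lognormal
measurement noise recorded every 2–3 days, and one spectrum per animal
containing both tumours' probes at ±0.5 cm along the 1 G/cm gradient.
Defaults and rationale:

| parameter | default | why |
|---|---|---|
| control / treated mean pO₂ | 10 / 15 mmHg | hypoxic tumour baseline; treated 1.5× control, the effect size the study design targets |
| between-/within-animal sd | 0.75 / 0.75 mmHg | chosen a priori by power analysis: with 6 animals × 2 tumours per group, the group-mean ratio then has sd ≈ 0.08, so a ±0.15 recovery band holds in ≳90% of cohorts including measurement noise; larger spreads would make the stated design underpowered for ratio recovery |
| tumours per animal | 2 | one probe per flank tumour |
| animals per group | 6 | 12 tumours/group |
| growth | 40 mm³ at day 7, rate 0.18/day, treated ×0.5, lognormal sd 0.15 | ~3.9-day doubling for controls; treatment halves the rate |
| measurement days | 7, 9, 12, 14, 16, 19, 21 | 2–3 day cadence, pO₂ read at day 21 |
| target SNR | 10 | effective (post-averaging) peak SNR of each spectrum; the per-spectrum noise sd is derived from the clean signal so the stated SNR is realised exactly |

All randomness flows from a single explicit seed; identical seeds give
bit-identical cohorts and spectra.

What the generator does **not** emulate: spatial/temporal oxygen
heterogeneity within a tumour beyond the probe's own averaging, probe drift
between implantation and measurement, anaesthesia physiology, non-Gaussian
or 1/f noise beyond a linear baseline, and animal-level clustering of
*measurement* error. Passing tests therefore show the chain is correct and
well-calibrated under its stated assumptions, not that real in vivo spectra
meet those assumptions.

## Statistics

One-way fixed-effects ANOVA (F, p) with Tukey HSD adjusted pairwise
p-values via the studentized-range distribution (scipy); all-equal input
returns F = 0, p = 1. Per-tumour observations are treated as independent,
matching the tumour-level n the emulated study reports; with two tumours
per animal and a nonzero animal effect this is anticonservative, which is
why the type-I calibration check uses one tumour per animal. A
mixed-effects extension is a deliberate non-goal. Ordinal 0–3
immunohistochemistry scores reuse the same ANOVA/Tukey operation. The
per-day volume comparison defaults to Welch's t (pooled-variance
selectable); Pearson correlation uses the exact t-transform p-value, which
is exactly uniform under a bivariate-normal null. Identical group vectors
short-circuit to p = 1 (the Welch statistic is 0/0 there).

## Numerical choices and degenerate inputs

- Forward-model quadrature: 48 modulation nodes, 7 footprint nodes; the
  analysis inverts the same discretisation, so these are model definitions,
  not accuracy knobs.
- Brent root-finding tolerance 10⁻⁷ G; forward evaluations are cached per
  model instance.
- Parabolic refinement falls back to the grid point (with a flag) at trace
  edges, on curvature/polarity mismatch, or when the vertex leaves the fit
  window. Equal-amplitude tie-breaks keep the leftmost grid extremum (the
  first `find_peaks` candidate).
- τ = 0 smoothing, zero modulation and zero footprint are exact identities;
  the correction then returns the raw width unchanged.
- Readers reject non-monotonic field axes, fewer than 8 points, and NaN/Inf
  intensities at write time; missing non-essential metadata is defaulted
  and recorded in provenance.

## Problem sizes used by the test suite

Noise-free factorial grids run all 60 width × modulation × time-constant
cells. Monte-Carlo checks use 200 full-pipeline cohort replicates
(12 spectra each), 2000 table-level null cohorts for type-I calibration,
2000 replicates for null p-value uniformity, and 200 seeds for the
single-trace width-recovery check; these sizes give binomial/KS resolution
comfortably finer than the asserted bounds.

## Known limitations

- The width-uncertainty heuristic ignores correlations between the two
  extremum estimates and the correction's error amplification (the inverse
  map's slope exceeds 1 when footprint smear flattens the apparent-width
  map), so reported standard errors are indicative, not calibrated.
- Overmodulation beyond B_m/ΔB_pp ≈ 2 combined with wide lines makes the
  apparent-width map nearly flat or non-injective; the corrector flags
  what it cannot bracket but cannot restore sensitivity that the physics
  has destroyed.
- The correction model assumes an isolated (deflated) single line per
  probe; strongly overlapping lines (gradient off, coincident probes) are
  flagged `overlap` and their widths are not trustworthy.
- No full-spectrum least-squares lineshape fitting and no spectral-spatial
  imaging: the chain deliberately mirrors extremum-refinement practice.
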