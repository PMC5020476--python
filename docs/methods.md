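# Methods

This note documents the models, estimators and numerical choices behind
`vesselpulse`, and what its synthetic phantoms do and do not establish about
performance on real data.

## Transit time and pulse wave velocity

The arterial pulse reaches a distal measurement plane Δt later than a proximal
one; over a centerline path length Δx the propagation speed is
`PWV = Δx / Δt` (Δx in m, Δt converted from ms to s). Δt is estimated from
velocity-encoded flow-versus-time curves by normalized cross-correlation of
the systolic upstrokes:

1. **Upstroke window.** The window ends at the global flow maximum and starts
   at the latest pre-peak crossing of `baseline + foot_fraction·(peak −
   baseline)`, with the baseline taken as the pre-peak minimum and the
   crossing linearly interpolated. `foot_fraction` defaults to 0.1; the method
   is insensitive to it because the correlation support is anchored at the
   foot (below).
2. **Low-pass filtering.** Both curves are smoothed with a cyclic Hann kernel
   (`smooth_ms`, default 130 ms ≈ 15 samples at 9 ms). The pulse occupies a
   few Hz while the additive noise is white, so the kernel suppresses noise at
   negligible cost to the waveform; applied identically to both curves and
   symmetric, it cannot shift the estimated delay. Cyclic (wrap-around)
   padding exploits the periodicity of the gated acquisition and avoids edge
   artifacts when the upstroke sits near the start of the cycle.
3. **Correlation support.** The correlation is evaluated over the proximal
   upstroke window extended downward by a baseline lead-in
   (`baseline_lead_ms`, default 60 ms). This matters: two bare monotone ramps
   are highly correlated at *any* relative shift, so the correlation-versus-lag
   curve of upstroke-only windows is nearly flat on top and the argmax is
   fragile under noise. Including the flat-baseline-to-rise corner makes the
   peak sharp. With the lead-in and the smoothing, the pooled median PWV error
   at waveform SNR 20 drops from ~26 % to ~8 % with no measurable cost in the
   noise-free case (max error 0.4 % across delays of 5–45 ms).
4. **Lag search.** Both signals are linearly interpolated onto a grid refined
   by `interp_factor` (default 16, i.e. 0.5625 ms at 9 ms sampling). The
   normalized (Pearson) correlation between the mean-subtracted windows is
   scanned over positive lags up to `max_lag` (default 100 ms; the pipeline
   uses 120 ms to cover slow waves over long descending-aorta paths).
   Mean subtraction and amplitude normalization make the estimate invariant
   to distal attenuation. Negative lags are excluded — the distal wave
   physically trails the proximal one; if the correlation is already falling
   at the first positive lag the case is rejected as non-physiologic.
5. **Sub-sample refinement.** The discrete argmax (ties break toward the
   smallest lag) is refined by quadratic interpolation through the three
   correlation values around the peak, with the vertex clamped to ±half a
   grid step. Refinement is skipped when the discrete peak correlation is 1
   to machine precision, so noise-free integer-sample shifts are recovered
   exactly.

Warnings (not errors): best lag at the search boundary; peak correlation
below 0.5 (poor waveform similarity).

## Distensibility

`D = (A_max − A_min) / (A_min · (P_sys − P_dia))`, reported in 10⁻³ mmHg⁻¹.
The implementation is positive-definite — the pulse pressure enters as
systolic minus diastolic — matching the sign convention of all published
values. Area extremes are the global per-phase minimum and maximum of the
cross-sectional-area curve; no temporal smoothing is applied by default (an
optional cyclic moving average exists for noisy contour series, and raw
versus smoothed extremes differ on noisy data — the raw extremes are biased
outward). Areas come from the shoelace formula on the traced polygons;
self-intersecting polygons are rejected via a linear-ring simplicity check.
One cuff blood pressure per subject is assumed for all locations.

BSA uses Mosteller (`√(height·weight/3600)`, configurable to Du Bois), chosen
for simplicity and validity across the pediatric-to-adult range of such
cohorts.

## Chamber volumetrics

"Simpson's rule" is implemented in its cardiac-MR sense: chamber volume is the
sum of planimetered slice areas times the slice spacing (thickness plus an
optional `gap_mm`, default 0). This is a midpoint-rule slab summation whose
error vanishes quadratically in the slice thickness; on a 20×20×30 mm
ellipsoid it is 0.5 % at 6 mm slices and 0.014 % at 1 mm. A phase with no
contours raises an error rather than contributing a silent zero.

LA landmark detection on the volume–phase curve: the maximal volume is the
global maximum; the minimal volume is the global minimum, required to occur
after the maximum within the acquired (R-wave-gated) cycle — curves whose
minimum precedes the maximum (e.g. time-reversed or monotone curves) are
rejected as showing no atrial cycle. The pre-contraction volume is the last
strict local maximum between the two (the pre-kick shoulder). When no interior
local maximum exists — fused phases at high heart rate, or a conduit-only
atrium — a fallback takes the phase of minimal downslope magnitude between
mid-diastole and the minimum, and flags the record (`la_ac_fallback`).

The six LA parameters follow the standard definitions (emptying volumes as
differences of the landmark volumes; fractions as percentages of their
respective reference volumes). The derived quantities satisfy two algebraic
identities exactly as computed: total emptying = passive + contractile volume
(the sum is formed after BSA indexing), and
`LAEF_reservoir = 1 − (1 − LAEF_passive)(1 − LAEF_contractile)` (all three
fractions share the same landmark volumes). LV mass uses the epicardial minus
endocardial end-diastolic volume at the standard myocardial density of
1.05 g/ml. Papillary muscles and trabeculation are whatever the contours
encode; there is no automatic exclusion.

## Carotid wall morphometry

Wall area is the outer-contour polygon area minus the lumen polygon area; the
outer contour must strictly enclose the inner one. Wall thickness is measured
along rays cast from the lumen centroid at evenly spaced angles — a
reproducible analogue of manual caliper placement. The thickness at one
position is the distance from the last inner-boundary crossing to the first
outer-boundary crossing along the ray; positions whose ray misses a boundary
are skipped. The default of two positions mirrors common manual practice and
is configurable upward; the per-artery value averages positions and sites.

## Statistics

* **Mann-Whitney U**, two-sided, with midrank tie handling. For pooled sizes
  n+m ≤ 12 without ties the p-value is exact (permutation distribution);
  otherwise the normal approximation with tie and continuity correction is
  used. Two completely identical samples return p = 1 with a degenerate flag.
  The exact branch is verified against full enumeration over all label
  assignments in the tests.
* **Spearman rank correlation** with the t-approximation p-value; undefined
  (and rejected) when either variable has zero rank variance.
* **Adult hypertension staging**: stage 1 at systolic 140–159 and/or
  diastolic 90–99 mmHg, stage 2 at 160–179 and/or 100–109 mmHg; the higher of
  the two component stages wins; above both stage-2 ranges is labelled
  separately. Pediatric percentile staging is out of scope (it requires
  external reference tables), so the pipeline stages adults only.
* **Distensibility mixed model**: response = intercept + age at repair + age
  at MRI + location contrasts + subject random intercept + residual, fit by
  REML (configurable to ML), with treatment contrasts against the descending
  aorta at the diaphragm — the site least affected by coarctation. Fixed-effect
  p-values are Wald tests on a t distribution with residual degrees of freedom
  (n_observations − n_fixed_effects); the degrees-of-freedom method is a
  documented choice, and p-values near 0.05 can flip under other conventions.
  The optimizer tries BFGS, then Powell, then Nelder-Mead, accepting the first
  converged fit; boundary variance estimates (random-intercept variance → 0)
  are legitimate outcomes, and in that balanced-design limit the fixed effects
  coincide with OLS. The model is fit on the patient group only; group
  contrasts use Mann-Whitney throughout.

## Synthetic phantoms and cohorts

The generators define the study conditions; every downstream estimator is
validated as a round trip against their recorded ground truth.

* **Waveforms**: a half-sine systolic pulse on a constant baseline — the
  simplest shape with a closed form and a monotone upstroke, which is all the
  cross-correlation method requires. The distal curve is the continuous
  proximal pulse evaluated at `t − true_delay` with its pulsatile component
  scaled by an attenuation factor (default 0.85), both sampled at 9 ms —
  the temporal resolution of a retrospectively gated phase-contrast
  acquisition — with optional i.i.d. Gaussian noise. Propagation is
  shape-preserving; upstroke dispersion is not modelled, consistent with the
  assumption underlying the cross-correlation method.
* **Lumen-area curves**: a raised-cosine single-peak profile rescaled to hit
  `a_min` and `a_min·(1 + D·ΔP)` exactly, so the noise-free distensibility
  round trip is exact to floating point.
* **Chamber stacks**: ellipsoids sliced at slab centres spaced by the slice
  thickness; each slice polygon is placed on a slightly inflated ellipse so
  its shoelace area equals the analytic section area exactly, leaving the
  midpoint-rule discretization as the only volume error. A degenerate
  ellipsoid shorter than half a slice still emits its centre slice. LA volume
  curves through the three landmark volumes are piecewise raised-cosine
  interpolations with a shallow conduit dip and a pre-kick shoulder, attaining
  the landmarks exactly at their phases; LV uses a prolate (2.5:1) ellipsoid
  at end-diastole and end-systole with the epicardial shell sized to the
  target mass.
* **Wall rings**: concentric circles solving the wall-area/thickness pair,
  with area-exact polygons.
* **Cohorts**: per-subject latent parameters drawn from the published group
  means/SDs (Tables of clinical characteristics, CMR measurements and the
  carotid substudy) as truncated normals at physiologic floors, with rank
  correlations induced through a Gaussian copula (Spearman targets converted
  by ρ_P = 2·sin(πρ_S/6); an indefinite target matrix is rejected). Defaults:
  51 patients / 54 controls with an 11/13 carotid subgroup; reported
  associations (age at repair with descending-aorta PWV and isthmus
  distensibility, arch PWV with the LA volumes) enter as copula targets; a
  few hard constraints (LA volume ordering, ESV < EDV, pulse pressure ≥ 5
  mmHg) clip a small tail of draws. The latent table is then materialized to
  raw waveforms and contours so the full pipeline runs end to end; path
  lengths default to 0.12 m (arch), 0.14 m (descending aorta) and 0.10 m
  (carotid).

Deliberate deviations from naive parameter choices, made once:

* PWV draws are floored at 1.3 m/s rather than a nominal 0.5 m/s so the
  implied transit delay over the longest path stays inside the lag search
  window; with the published means/SDs this clips well under 1 % of draws.
* Age at repair is floored at 0.01 y; because the published SD (6.1 y) is
  larger than the mean (4.2 y), truncation raises the sample mean to ~6.6 y.
  This is the documented non-normal tail behavior of a truncated-normal
  marginal for a strongly right-skewed quantity (half of such cohorts are
  repaired in infancy); rank correlations are unaffected.
* Within-subject correlation of distensibility across the four aortic sites
  is not published; it is exposed as a copula knob and left at 0 by default.

**What the phantoms do not show.** Contours are ideal geometric shapes:
there is no tracing jitter, no partial-volume or through-plane motion, no
pulmonary-vein/appendage ambiguity in the LA, and waveform noise is white
rather than structured (ghosting, trigger jitter). Passing round trips
demonstrate the correctness of the estimators and the statistical machinery
under the stated noise models, not observer-level accuracy on clinical images.
The published cohort statistics are used only as simulation parameters; the
real per-patient data are not reproducible from them.

## Problem sizes

The test suite and the acceptance script use: 9 delays × 500 seeds for noisy
PWV recovery; 10 000 random triples for the LA-fraction identity; all
two-group splits with n+m ≤ 10 for the Mann-Whitney oracle; 200 simulated
cohorts of 50 subjects × 4 locations for mixed-model interval coverage; 200
replicates of 51 + 54 subjects for the arch-PWV power check; and a
materialized 14 + 14 cohort (6 + 6 carotid) for the end-to-end pipeline run.
These sizes give Monte-Carlo standard errors comfortably below the margins
being checked while keeping a full run around a minute.
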