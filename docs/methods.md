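# Methods

This note documents the models and procedures implemented in `phenoswap`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## OD conditioning (`plate_io`)

Raw plate-reader turbidity readings are conditioned in three steps:

1. **Blank subtraction.** Default policy `per-timepoint-mean` averages all
   blank wells at each time point, which tracks drift of the medium signal;
   `scalar-mean` subtracts one grand mean. Post-blank values below a floor
   (default 1e-4 OD) are clipped to it rather than dropped, keeping the
   time grid aligned; the clip count is logged.
2. **Nonlinearity / path-length correction.** Turbidity readers saturate at
   high density; over the working range this is modeled by an odd
   polynomial with a linear and a cubic term. `CalibrationModel` supports
   two conventions: `correct` applies the polynomial directly to the
   blanked measurement (the familiar calibration-curve form), while
   `invert` treats the polynomial as the detector response (true →
   measured) and inverts it by Newton iteration. The distinction matters:
   if the detector response is `od − c·od³`, applying `od + c·od³` to the
   measurement recovers the true OD only to first order in `c`, whereas
   numerical inversion is exact to machine precision. Monotonicity of the
   polynomial over the observed OD range is checked and non-monotone
   calibrations are rejected. `path_factor` rescales the well geometry to
   1-cm-equivalent OD. The identity model is a strict no-op.
3. **ln transform.** All rates downstream are natural-log per hour. This is
   self-consistent with the endpoint definition: a rate floor of
   0.025 h⁻¹ corresponds to a doubling time of ln 2 / 0.025 = 27.7 h.

Times are normalized to hours at ingest; the time column header must
declare its unit (`time_min`, `time_h`, ...). Wells are validated for
strictly increasing times, and a sampling interval that varies by more
than 1% triggers a warning, since the window search assumes a uniform grid.

## Growth features (`growth_features`)

**µmax** is deliberately nonparametric — no growth law is fitted. Candidate
windows are every contiguous stretch of samples spanning at least 4 h
(`min_window_h`); a window qualifies when a single OLS fit of ln OD vs time
reaches r² > 0.995 (`r2_min`); the reported µmax is the maximum slope among
qualifying windows. "Stable for at least 4 hours" is thus read as: the
window itself is ≥ 4 h long and log-linear to the r² gate. By default
window lengths are capped at 8 h (`max_window_h`), giving O(n·w) cost per
well; `full_enumeration` removes the cap. Window statistics come from
prefix sums (O(1) per window); ties break to the earliest window. A
zero-variance window is an exact fit, so its r² is defined as 1 with slope
0; wells with no qualifying positive-slope window report every rate-derived
feature as undefined rather than failing.

**Lag** is the time where the tangent of the steepest-slope window — the
OLS line fitted over that window — crosses the baseline density level,
clipped below at 0. The baseline defaults to the mean of the first 3
samples of ln OD (`baseline_points`), which is the standard phenomics
convention for the inoculation level; a `time-axis` alternative
(intersection with ln OD = 0) is available behind a config flag. Two
known error sources, quantified on synthetic data: (i) the baseline is
estimated from 3 noisy points at the lowest OD of the run, so lag noise
scales as σ_baseline/µ and is largest for slow growers; (ii) because µmax
is a maximum over many noisy windows, it carries a small positive selection
bias (≲2–3% at µ = 0.1 h⁻¹ and σ_od = 0.005) which tilts the tangent and
shifts the lag late in proportion to the window-center-to-lag distance. At
µ ≥ 0.2 h⁻¹ both effects are well inside one 10-min sampling interval.

**Endpoint and diauxic shift** use a local rate: a centered rolling OLS
slope with the same 4-h window as the µmax search, for consistency. The
endpoint is the first time after the µmax window at which the local rate
drops below 0.025 h⁻¹ (crossing located by linear interpolation between
adjacent window centers; OD interpolated at the crossing); cultures that
never slow down that far are reported as `n.d.`. The diauxic shift is the
first downward crossing of 0.07 h⁻¹ after the µmax window, defined only
when the culture grew faster than that threshold to begin with; no
second-derivative "suddenness" test is applied. On rich/complex media,
where batch cultures do not reach stationary phase within the observation
window, the endpoint fields are replaced by the diauxic-shift values
(config: `rich_medium_conditions`). Because the local rate is a 4-h window
average, detected crossings lag the instantaneous rate crossing by up to
about half a window for sharply decelerating cultures; the package's
self-consistency guarantee is on the rolling rate itself (below threshold
at the endpoint, at or above it at the previous evaluable center).

**Generations** is log₂ of the corrected-OD fold expansion between the
first and last retained points.

## Replicate statistics (`phenotype_stats`)

Clonal replicates are summarized as mean and sample SD (n−1). Groups are
compared by one-way ANOVA (scipy's F test, with explicit degenerate
branches: all-equal groups give F = 0, zero within-group variance with
unequal means gives F = ∞, p = 0). Pairwise comparisons for ≥ 3 groups use
Tukey's HSD, generalized to Tukey–Kramer for unbalanced designs:
q = |mi − mj| / sqrt(MSW/2 · (1/ni + 1/nj)), with the adjusted p from the
studentized-range distribution (k groups, N−k df; scipy's implementation,
which integrates the tail numerically to ~1e-8). For exactly two groups the
pooled-variance (Student's, not Welch's) unpaired t test is used — with two
groups ANOVA's F equals t² exactly. Star codes use strict inequalities:
*** p<0.001, ** p<0.01, * p<0.05.

## Competition (`competition`)

The model is a constant per-generation selection coefficient s: the
log-odds of the focal strain's fraction is linear in cumulative
generations. Serial-transfer bookkeeping: the initial 1:1 logarithmic mix
is sampled at T = 0; the first stationary sample follows the initial
outgrowth (`pre_cycle_generations`, default 8 doublings); each subsequent
1:1000 cycle adds log₂ 1000 ≈ 9.97 generations, so the default
seven-cycle design spans 8 + 7·9.97 ≈ 78 generations. Observed fractions
are binomial draws of `events_per_sample` flow-cytometry events (default
10⁴), or exact when counting noise is disabled.

The estimator is the OLS slope of logit(observed fraction) vs generations.
Samples at exactly 0 or 1 are continuity-corrected (half an event per
class) and flagged rather than dropped. The confidence interval uses the
Student-t quantile on the regression standard error (df = points − 2): with
only ~9 sampling points a normal quantile would noticeably under-cover,
and Monte-Carlo calibration at the default design shows ~95% empirical
coverage for the t interval. Within-cycle lag/rate structure is not
modeled; when the generator produces it, the logit-linear estimator treats
it as tolerable misspecification. The mutual-labeling design is supported
end to end: both orientations are fitted on the GFP fraction, and the
half-difference of the two slopes cancels an additive label-cost term
exactly.

`generations_to_threshold` inverts the model in closed form:
T = (logit(threshold) − logit(p0)) / s, infinite under neutrality. At
s = 0.0282 from a 50:50 start, a 90% takeover needs ln 9 / s ≈ 78
generations — the scale of the default experiment.

## Relative quantification (`rna_quant`)

Northern: rq = (band / loading) ÷ mean(band / loading over the calibrator
group). qPCR: ΔCt = Ct(target) − mean(reference Cts); per-sample linear
quantities efficiency^(−ΔCt) are scaled by the arithmetic mean of the
calibrator group's quantities, making the calibrator mean exactly 1.
Combining reference genes by arithmetic mean of Cts equals the geometric
mean of their abundances, the standard multi-reference convention; the
amplification efficiency defaults to 2 (perfect doubling) and is
per-assay configurable in (1, 2]. Invariances that hold exactly by
construction: blot-wide intensity scaling, per-sample Ct shifts (RNA input
amount), and composition of relative quantities across calibrators.

## Synthetic data (`synthetic_data`)

Growth curves are generated from a smooth specific-growth-rate schedule
rather than a parametric growth law: the rate rises sigmoidally (ramp
width 0.1 h) from 0 to µ1 at the end of the lag, holds µ1 exactly, and
falls sigmoidally to 0 when the integral of the schedule reaches
ln(capacity/od0); an optional shoulder and second phase (µ2, capacity2)
produce a diauxic pattern. Integrating the sigmoid schedule gives a closed
softplus form for ln OD. This family was chosen because every feature the
estimators must detect is exactly defined: the true µmax is µ1 (a
logistic-capped exponential, by contrast, never contains a strictly
log-linear window, so "truth" would depend on the estimator), the
tangent-intercept lag is exactly the lag parameter, and threshold
crossings of the true rate are available in closed form for oracle tests.

The measurement model is measured = blank + (od − c·od³) + N(0, σ), with
defaults chosen once as the study conditions: inoculum od0 = 0.45
(10⁶ cells in 150 µl ≈ 6.7·10⁶ cells/ml ≈ OD600 0.45 for diploid cells at
~1.5·10⁷ cells/ml per OD unit), capacity 6.0 corrected-OD units, detector
cubic c = 0.005 (monotone to OD ≈ 8), blank level 0.08, σ_od = 0.005,
10-min sampling over 48 h. The default plate layout is 2 strains × 3
replicates × 15 conditions plus 6 blanks = 96 wells, with per-group true
µ ~ U(0.1, 0.5) h⁻¹ and lag ~ U(0, 5) h. Plate wells draw from per-well
RNG substreams keyed by (seed, plate position), so extending a layout
never perturbs existing wells, and all generators are byte-deterministic
under a fixed seed.

What the generator does *not* emulate — and what passing recovery tests
therefore do not show about real data: evaporation and condensation
artifacts, shaking/settling transients, temperature equilibration, well
edge effects and spatial gradients, biological replicate variation beyond
the modeled noise, non-Gaussian detector error, and drift of the blank.
Competition fixtures assume constant s (no frequency dependence, mutation,
or adaptation) and perfect GFP classification; quantification fixtures
assume log-normal intensity noise and Gaussian Ct noise with a shared
per-sample input offset.

## Numerical notes

- Window OLS statistics use prefix sums; slopes agree with independent
  per-window `np.polyfit` to better than 1e-10 absolute on 12-h series.
- Exactly piecewise-linear (noise-free) series contain many
  identically-sloped qualifying windows, between which "the" steepest
  window is genuinely undefined; equivalence tests against brute-force
  enumeration therefore use a 1e-5 noise floor to keep slopes generic.
- Plate files are written with 17 significant digits and parsed with
  round-trip float precision, so write → read is bit-exact.
- Newton inversion of the detector polynomial converges to ~1e-13 relative
  within the monotone range; the monotonicity precondition keeps the
  derivative bounded away from zero.
- The studentized-range tail is evaluated by scipy's quadrature
  (~1e-8); Tukey p values agree with statsmodels' implementation to 1e-6.

## Known limitations

- The lag estimate inherits noise from only 3 baseline points and a small
  positive bias from µmax selection; for µ < 0.15 h⁻¹ at σ_od = 0.005 its
  error can approach one 10-min sampling interval.
- Endpoint/diauxic crossing times are window-smoothed and systematically
  late relative to the instantaneous rate for sharply decelerating
  cultures (up to ~half a window).
- The ANOVA/Tukey machinery assumes exchangeable, roughly normal replicate
  values; with n = 3 clonal replicates the tests are valid but weak, as in
  any three-replicate design.
- The competition estimator's OLS is unweighted although logit noise grows
  toward extreme fractions; at 10⁴ events per sample the effect on bias is
  negligible (<0.1% of s) and coverage stays near nominal.
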