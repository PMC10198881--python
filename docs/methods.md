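# Methods

## Scope and model

The package analyzes 2D single-particle trajectories of membrane proteins
imaged at a fixed frame time Δt (default 20 ms, 1000 frames per cell). Motion
is modeled as one of three stationary modes per segment: immobile (no motion
beyond localization noise), confined (Brownian motion restricted to a
region), and free (unrestricted Brownian motion). Receptor activation is read
out as a redistribution of these mode populations and a slowdown of the
mobile modes over minutes, resolved by imaging many cells sequentially and
time-stamping each cell relative to ligand addition.

## Synthetic data generator

The generator emulates the acquisition design so that every downstream stage
can be tested against known truth.

- Each cell carries a timestamp on a uniform grid spanning `span_min`
  (default 30 min, 25 cells); the ligand is added after the fifth cell, and
  timestamps are reported relative to that moment.
- Each emitter draws a mode from the response profile evaluated at the
  cell's timestamp, a start frame uniform over the movie (emulating ongoing
  probe binding and photoactivation, which keeps the instantaneous spot
  density low and roughly constant), and a geometric lifetime with per-frame
  bleaching probability `p_bleach` (default 0.064), truncated by the movie
  end.
- Free emitters take Gaussian steps with per-axis variance 2·D·Δt
  (D_free default 0.15 µm²/s). Confined emitters do the same inside a
  reflecting circular corral (radius default 0.125 µm, D_conf 0.10 µm²/s —
  a ~250 nm membrane domain with intra-domain mobility comparable to free
  diffusion). Immobile emitters are static. Every recorded point is the true
  position plus isotropic Gaussian noise with sd `sigma_loc` (default 20 nm)
  per axis; the uncertainty column carries `sigma_loc`.
- Default resting mode fractions are (0.105, 0.281, 0.614) for
  (immobile, confined, free).

**Response kinetics.** The immobile fraction follows a piecewise kernel:
baseline for t < 0, linear ramp to the peak at `t_peak`, then exponential
relaxation toward a plateau with time constant `decay_tau`. The confined
fraction stays fixed; the free fraction absorbs the complement. The free
diffusion coefficient is multiplied by `1 − dip·k(t − t_D_lag)` with the same
kernel, so the mobility dip trails the immobilization. This closed form was
chosen for testability; the shipped ligand-like profiles
(`benchmarks.LIGAND_PROFILES`) encode a strong sustained response (peak
+180%, plateau +60%), two intermediate transient responses (~+120%/+100%,
full return), and a weak late response (peak at 10 min).

**What the generator does not emulate:** motion blur within the integration
time, pixelation, camera noise, false localizations, mid-trajectory mode
switching, cell-shape boundaries, and cell-to-cell biological heterogeneity
beyond an optional log-normal jitter on the mode weights (off by default; no
published magnitude exists). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated motion model, not robustness
to every artifact of real recordings.

## Tracking

Per-dataset parameters are estimated from the localization tables:
precision as the per-cell mean of the uncertainty column; the expected
frame-to-frame displacement as the mean distance of mutual-nearest-neighbour
links between consecutive frames (one-sided matches are discarded, making
the estimate robust to moderate density — on mixed-mode data it
underestimates the free population's step length, which only tightens the
search radius); the bleaching probability as the geometric maximum-likelihood
estimate p = deaths / Σ durations, where trajectories reaching the last
movie frame count as right-censored exposure, not deaths.

Linking is greedy nearest-neighbour: per frame, candidate pairs between
active track ends and new localizations within `radius_factor ×
exp_displacement` (default 3×) are accepted in order of increasing distance;
unmatched localizations open new tracks; a track survives up to
`max_gap_frames` (default 1) missing frames. Input rows are canonically
sorted, so the result is independent of row order. The published per-frame
mode-switching probability (0.01) is carried in `TrackingParams` for
compatibility with probabilistic motion-model linkers but is not used by the
greedy assignment; segments produced here never switch modes internally,
matching the generator. At the study's densities (≲0.05 spots/µm² per frame)
measured track purity exceeds 99.9%.

## MSD analysis

The time-averaged MSD uses all displacement pairs whose both endpoints
exist (segments with closed gaps contribute only existing pairs), with lags
up to `max_lag_fraction` (default 0.6) of the segment length. The
diffusion-coefficient fit is an unweighted OLS line through the first
`n_fit` = 4 MSD points; D = slope/4 may be negative for noise-dominated
segments and is never clipped (negative D falls below any positive threshold
and is classified immobile; it is excluded from mobile-mode mean-D
reporting). σ_dyn = √(intercept/4) is defined only for positive intercepts.

**Immobile threshold.** D_min = Q3(σ_dyn)²/(4·Δt) — the apparent D that pure
localization noise of magnitude Q3 produces over one frame interval — with
Q3 the linear-interpolation (type-7) quartile of the pooled per-segment
σ_dyn values. The convention is fixed because Q3 feeds a threshold. σ_dyn is
pooled per dataset, not per cell. Published per-target thresholds
(HER2 0.0084, TMD 0.0037, GPI 0.0086 µm²/s) are available as overrides, and
the override mode is the default for reproduction-style runs: on strongly
confined data the 4-point intercept absorbs confinement curvature, which
inflates the Q3-based formula value well above the pure-noise floor.

**Confined vs free.** For mobile segments the full MSD curve is fit with
MSD(t) = 4·Γ·t^α + c (nonlinear least squares; α bounded to [0.01, 2];
points weighted by the relative sd of a time-averaged Brownian MSD,
√((2n²+1)/(3n(N−n+1))) at lag n for N points). The segment is confined when
α̂ falls below a critical value, free otherwise.

The critical values are calibrated, not derived from the fit covariance: the
MSD points of a single trajectory are strongly correlated, and the null
distribution of α̂ on genuinely free segments is left-skewed with a heavy
lower tail, so Wald intervals α̂ ± z·SE(α̂) are badly miscalibrated in both
directions (measured on simulation: an unweighted fit calls 42% of typical
free segments confined, while a weighted fit with covariance-based SEs
detects only 22% of strongly confined ones). Instead
`scripts/calibrate_classifier.py` simulates free Brownian segments with
localization noise across the relevant D range (0.05–0.3 µm²/s, σ = 20 nm,
Δt = 20 ms) and tabulates the size-q quantile of α̂ per segment length; the
classifier interpolates this table (`diffusion.ALPHA_CRIT`). This makes the
confined call an honest hypothesis test of "not free" with known size.

The default test size is 0.075. The operating point was chosen to balance
the two misclassification masses at the study's resting composition (61.4%
free × false-confined rate against 28.1% confined × miss rate), which
minimizes the bias of cohort-level mode fractions; smaller sizes under-call
confined (size 0.05 leaves a −0.04 bias on the confined fraction), larger
ones inflate it at the expense of the free fraction. The calibration assumes
the noise-to-motion regime of the study (σ²/(D·Δt) ≈ 0.1–0.4); datasets far
outside it should be recalibrated with the shipped script.

## Cell and cohort aggregation

Cells are summarized by the mean over their surviving segments (≥ 20
localizations): D_global is the per-cell mean of segment D, then averaged
over cells with SEM — per-cell first, pooled second, matching a design in
which the cell is the statistical unit. Cells with no surviving segments are
excluded from cohort means rather than imputed.

Time bins are half-open intervals [k·w, (k+1)·w) minutes relative to ligand
addition (w = 5 by default, 1 optionally), starting at [−5, 0); empty bins
are reported as missing, never interpolated. Baseline alignment shifts each
condition's mode fractions additively so its [−5, 0) interval equals the
grand-mean baseline across conditions, then renormalizes the fraction triple;
the additive rule preserves between-bin differences, which is what
relative-change profiles display (a multiplicative variant is available, and
raw series are always kept). Relative change and its error are

rc = (m_bin − m_base)/m_base × 100 %,  SED = 100·√(SEM_bin² + SEM_base²)/|m_base|,

treating the two intervals as independent samples of cells.

## Statistics

Normality is screened per group with Shapiro–Wilk at α = 0.05 and recorded;
following the study's practice the comparisons are nonparametric regardless:
two-sided Mann–Whitney U between treatment groups (exact for groups ≤ 20
without ties, tie-corrected normal approximation otherwise) and Wilcoxon
signed-rank for paired designs (pairing must be explicit; it is never
inferred). Significance labels: p < 0.05 (*), < 0.01 (**), < 0.001 (***);
p = 0.05 itself is not significant. No multiple-testing correction is applied
by default (a Bonferroni option exists) since the star scheme reports raw
per-comparison p values.

## Problem sizes and numerical choices

The standard validation runs use 40 cells × 250 emitters (1000 frames,
20 ms) for the resting-state recovery — about 10⁴ trajectories, 3·10³ of
them ≥ 20 localizations — and 8 pooled replicates of 25 cells × 150 emitters
per time-course scenario, giving ~32–40 cells per 5-min interval. Recovery
tolerances in the tests are ±0.03 absolute per mode fraction, 10% relative
on mean free D, and 3 SE on p_bleach. Degenerate inputs are handled by
convention: all-zero MSD ⇒ immobile; D exactly equal to D_min ⇒ mobile
(strict inequality); constant samples fail the normality gate; identical
paired samples give p = 1. Ties in the greedy linker are broken by distance,
then by canonical row order, so reruns are bit-identical for a fixed seed;
all randomness flows from numpy `default_rng` seeds derived via
`SeedSequence` and kept below 2³¹.

## Known limitations

- The greedy linker does not model detection gaps probabilistically or
  resolve merge/split events; at densities far above the study's it will
  fragment tracks sooner than a motion-model linker.
- The anomalous-exponent test calibration is specific to the acquisition
  regime above; σ_dyn-based thresholds and the α table should be regenerated
  for very different frame times or noise levels.
- Mode fractions are per-segment proportions; no hidden-Markov segmentation
  of within-trajectory mode switches is attempted.
- The D_min "formula" mode inherits confinement bias through the MSD
  intercept on data with strong, fast-saturating confinement; prefer the
  published overrides (or noise-only calibration) there.
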