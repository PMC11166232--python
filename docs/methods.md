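# Methods

This note documents the statistical procedures implemented in
`patternshift`, the parameter defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical
conventions that fix otherwise ambiguous behavior.

## Data model

A case is a channels × days matrix of daily self-ratings on a bounded
visual-analog scale (default 0–100), on a strictly contiguous daily grid;
absent days are explicit missing cells. Missing values are imputed by
last-observation-carried-forward (LOCF); a leading gap takes the first
observed value, so every channel is total afterwards without inventing a
trend. Factor scores are unweighted means of their items, which preserves
the scale bounds. Day indices are 1-based ("a transition at day 65" means
the 65th monitored day is the first day of the new regime).

Diary codings live on the same day grid as sets drawn from eight
subcategory codes (three stability codes, two improvement codes,
broadening of perspective, critical instability, Kairos) plus an explicit
`no_entry` marker that never co-occurs with a code. Parent groupings are
derived, never stored.

## Dynamic complexity

DC = F·D on a sliding window of `window_m = 7` days, right-aligned (the
value is attributed to the window's last day, matching a real-time
monitoring perspective; the first 6 days are undefined and rendered
blank). Both factors are normalized to [0, 1] and are zero exactly for a
constant window; both are invariant under joint affine rescaling of values
and scale bounds.

- **F (fluctuation)** partitions the window into maximal monotone
  segments and sums `|x_end − x_start|/(end − start)`, normalized by the
  largest attainable value, `(scale range)·(m − 1)` (achieved by
  full-range alternation every step). Tie rule: equal consecutive values
  extend the running segment — a plateau is not a turning point — and a
  leading plateau joins the first directed segment. This avoids
  zero-length segments and makes F order-sensitive (it is *not*
  permutation invariant; D is).
- **D (distribution)** compares the sorted window against an ideally
  even spread over the whole scale range: it accumulates, over all value
  pairs, the shortfall of the empirical gap below the ideal gap, and
  subtracts the normalized deficit from 1.

### Surrogate significance

The null model is exchangeability: each channel's observed values in
random order (independent permutations per channel, default 1000). This
preserves the marginal distribution exactly and destroys temporal
structure. Per-channel empirical null quantiles at 1 − 0.05 and 1 − 0.01
give the gray/black masks of the complexity resonance diagram; z-values
(DC standardized by the null mean/sd) are reported for display parity but
the masks are quantile-based, avoiding any normality assumption on DC.
Per-day counts of flagged cells form the column histogram drawn on top of
the diagram.

Critical-instability periods: days whose channel-mean DC exceeds the
(1 − α) null quantile are flagged; runs with gaps ≤ 1 day are merged. Each
period's p-value is the share of surrogate cases whose best same-length
sliding-window mean DC reaches the period's observed mean, with add-one
correction ((r + 1)/(n + 1)), so p is never exactly 0 and `p < 0.001`
requires at least 1000 surrogates.

Calibration caveat: on exchangeable noise the mask exceedance rates match
their nominal levels and scan p-values are uniform (verified in the
acceptance suite). On *autocorrelated* but regime-free series the shuffle
null is anticonservative by construction — autocorrelation itself is
temporal structure. This applies equally to the permutation confidence of
the change-point detectors below; it is a property of the surrogate
scheme, not a defect of the implementation.

## Second-level representations

- **Recurrence plot**: delay embedding with dimension m = 3, delay τ = 1
  day (coarse defaults for daily data), Euclidean distances, and a
  threshold ε set to the 10% quantile of all pairwise embedded distances
  (fixed recurrence rate). Fixing the rate rather than ε makes the plot
  comparable across channels with different variances. The binary rows
  (not distance rows) feed the line-wise change-point vote. A fully
  degenerate distance distribution (constant channel) yields an all-ones
  matrix with a warning flag.
- **Time–frequency distribution**: plain windowed periodogram, window 7
  to match the DC window, right-aligned, mean-removed, no taper; rows are
  squared DFT magnitudes at frequencies k/7 cycles/day, k = 1…3. Mean
  removal drops the DC bin and annihilates constant windows.

## Change-point detectors

All detectors scan every admissible two-segment split exhaustively and
report the split minimizing the model cost; ties break to the earliest
day; the reported day is the first day of the new regime. Scores are
cost reductions against the one-segment fit; a relatively zero score flags
a degenerate (no-change) detection.

- mean: two constant segments, least squares, splits with ≥ 1 point per
  segment;
- variance: two-segment Gaussian cost Σ len·log(var + 1e−9), ≥ 2 points
  per segment (shorter segments make the log-variance cost meaningless);
- trend: two independent least-squares lines, ≥ 3 points per segment (two
  points fit any line exactly).

Confidence is a permutation bootstrap: the share of value-shuffled
surrogates whose best score stays strictly below the observed one,
denominator n + 1. For matrices (recurrence plot, TFD), the mean-change
scan runs per line, degenerate lines abstain, the bin-width-1 histogram's
earliest mode is the matrix change point, and confidence is the share of
voting lines within ±3 days of it.

Leading undefined columns (DC profile, TFD) are stripped before the scan
and the found day is shifted back onto the original grid. A change
detected in these windowed profiles can land on either edge of the
transient bump a level shift produces, i.e. up to one window width after
the raw change day; the pooled estimate absorbs this jitter.

## PTDA

Per channel the six points (mean, variance, trend, dc_mean, rp_lines,
tfd_lines) are computed; with case-level pooling (default) all channels'
points enter one histogram, each voting for its day with weight
min(confidence, 1). The transition day is the weighted mode after
smoothing with a triangular kernel of half-width `mode_window_w = 3`
(ties → earliest). Smoothing is deliberate: individual detectors jitter
by a few days around a real transition, and adjacent votes should
reinforce rather than split; the kernel choice keeps the exact arithmetic
of the unsmoothed example {65, 65, 64, 66, 63, 20} → day 65.

The probability is Σ confidence of points within ±`mode_window_w` days of
the transition day, divided by the number of **all** points — degenerate
detections count in the denominator as evidence of absence. It is 1
exactly when every point is non-degenerate, fully confident and agrees
within the window, and it shrinks under scattered or absent evidence.
The analysis level defaults to the 7 factor scores; item level is
available.

The whole-algorithm surrogate test permutes every channel independently,
recomputes the full pooled probability per surrogate case (default 200),
and reports p = (#{probability ≥ observed} + 1)/(n + 1). For large
simulation studies of the *day* estimate, the surrogate stage can be
skipped (`compute_surrogate_p=False`).

## Synthetic generator

The generator plants the minimal structure the analysis assumes: per
factor a latent AR(1) path (φ = 0.6) around a baseline mean drawn from
35–65 scale units; item = factor latent + independent N(0, noise_sd)
noise, clipped to the scale; a level shift of `level_shift_sd`·noise_sd
(default 1.5·6 = 9 scale units, random sign) on a random 70% of factors
from the transition day (default 60 of 90); completely-at-random missing
values at 1.6%.

Two parameterization choices matter:

- The latent AR(1) is parameterized by its **stationary** sd = noise_sd
  (innovations have sd `noise_sd·√(1 − φ²)`), so "noise sd" is the actual
  day-to-day dispersion of a factor around its regime mean and planted
  effect sizes in noise-sd units keep their face meaning.
- `instability_window="auto"` plants a burst of critical instability on
  the 3 days immediately preceding the transition (none when no
  transition is planted), encoding the canonical sequence *stable regime →
  critical instability → pattern shift* that motivates the whole method;
  reported instability phases immediately before qualitative changes are
  of about this length. Inside the window, innovations are inflated by
  `instability_gain = 3` and an alternating ±gain·noise_sd component is
  added, so both the order-sensitive F and the scatter-sensitive D
  respond. An optional transient relapse pushes the shifted factors
  *away* from the upcoming regime for a few days before the shift.

The coupled diary timeline draws one code per day (plus a second with
probability 0.25) from phase-specific emission weights: stability codes in
the stable regime, critical-instability/broadening codes inside the
window, elevated Kairos probability within ±3 days of the transition,
improvement codes afterwards; days are independently replaced by
`no_entry` at 15.2%.

What the generator does *not* emulate: cross-factor correlation,
item-specific loadings and variances, weekly rhythms, retrospective
entry effects, non-random (state-dependent) missingness, and multi-case
heterogeneity. Passing recovery tests therefore show that the pipeline
detects the planted transition complex (instability burst + level shift)
under realistic noise and missingness — not that it would perform
identically on clinical data. In particular, an isolated level shift with
*no* adjacent instability is intrinsically harder to localize: in that
configuration the day-recovery rate within ±3 days drops below the
coupled-case rate (the change-point jitter of a ~1.5σ step under
autocorrelated noise is several days).

## Alignment of diaries and indicators

For each category group, the days are cross-classified by group presence
and by membership in the quantitative indicator set (significant-DC
periods ∪ transition day ± 3); association is an odds ratio with Haldane
correction. The permutation null circularly shifts the whole timeline
(preserving its run structure — diary phases are runs, not independent
days), 1000 shifts, add-one corrected. This is one explicit
operationalization of qualitative/quantitative correspondence among
several defensible ones.

## Problem sizes and numerics

Simulation studies in the test and acceptance suites use 90-day,
43-item cases; 100 seeds for transition recovery and monotonicity, 50 for
instability detection, 1000 surrogates for mask calibration, 100–500
elsewhere. Degeneracy is decided at relative tolerance 1e−9 on the
cost-reduction score; quantile comparisons use a 1e−12 guard; the
variance cost carries a 1e−9 additive guard. All randomness flows through
`numpy.random.default_rng` seeds; every public stochastic entry point is
reproducible given its seed.
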