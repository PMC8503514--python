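# Methods

## Problem and model

Basketball alternates short bouts of live play (ball in play, game clock
running) with frequent stoppages. Quantifying demands *per live-play
period* requires knowing when those periods start and end; doing that by
annotating video is slow and observer-dependent. `liveplay` detects
live-play periods automatically from body-worn accelerometry, on the
premise that a player's relative exercise intensity is above a "light"
level while play is live and below it during stoppages and bench time,
*provided* the signal is smoothed over a window comparable to the shortest
meaningful bout. A single second of low intensity (a shooter waiting in
the corner) or high intensity (a bench player jumping up) must not flip
the classification; a moving average over several seconds makes the
decision depend on a sustained level.

### Signal chain

1. **Band-pass filter.** Raw triaxial acceleration (g units) is filtered
   with a Butterworth band-pass, cut-offs 0.1 and 15 Hz. The 0.1 Hz edge
   removes the gravity/DC component (no separate gravity-vector
   subtraction), the 15 Hz edge removes sensor noise above the frequency
   band of human movement. The filter is applied zero-phase
   (forward-backward): a causal filter's group delay would shift every
   detected boundary late by a window-dependent lag, which would bias
   period start/end times systematically; the cost is that the effective
   magnitude response is the square of the one-pass response. The `order`
   parameter (default 4) is the overall transfer-function order of the
   band-pass — an order-4 band-pass has two poles at each edge.
2. **Average net force.** Per 1-s epoch, AvF_NET = body mass × the mean
   Euclidean norm of the filtered acceleration vector (converted with
   g = 9.80665 m s⁻²), in newtons. Computing force from an *unfiltered*
   trace is refused: gravity would contribute ~1 g to every sample.
3. **Relative intensity.** Per player, %V̇O2R = max(0, slope·AvF_NET +
   intercept). The slope/intercept come from a laboratory calibration and
   are configuration inputs; the calibration protocol itself is out of
   scope. Values are clamped below at 0 but not above 100 — supramaximal
   readings are physiologically meaningful.

### Detection rules

Per player, on the 1-s epoch series over the match clock (second 0 =
tip-off, half-open intervals `[start, end)` throughout):

1. **Moving average** of `window_s` (W, default 9 s), centred, shrinking
   at the series edges; for even W the centre is biased one epoch earlier.
   A centred window is unbiased for both onsets and offsets, whereas a
   trailing window would shift every boundary late by ~W/2 s.
2. **Threshold** at `threshold_pct` (T, default 31 %V̇O2R); a second is
   active iff smoothed ≥ T (ties count as active, so exactly one side of
   the comparison is closed).
3. **Gap-filling**: inactive runs strictly shorter than `min_gap_s`
   (default 10 s) flanked by activity on both sides become active.
   Stoppages essentially always outlast 10 s, so a shorter lull is
   on-court low-intensity play. Leading/trailing inactive runs (warm-up,
   post-match) are never filled.
4. **Team rule**: at any second with at most `min_players_active − 1`
   active players (default: ≤ 2), *all* players are set inactive. Isolated
   "active" players at such seconds are substitution traffic, not play.
5. **Exclusions**: configured intervals (half time) forced inactive.
6. **Segmentation** into maximal active runs per player; the team timeline
   is active where the count of active players ≥ `min_players_active`.

Rule order is per-player smoothing/threshold/gap-fill, then the team rule,
then exclusions. Gap-fill is *not* re-applied after the team rule — that
would resurrect exactly the substitution gaps the team rule exists to
create. Whether the team rule should instead see pre-gap-fill activity is
not decidable from first principles; `DetectorParams.team_rule_first`
exposes the alternative order for sensitivity analysis. No minimum period
duration is imposed; a known consequence of the smoothing is that periods
much shorter than W are rarely detected.

### Parameter optimisation

The detector is run for every combination of W ∈ {5, 10, 15, 20, 25} s and
T ∈ {20, 25, 30, 35, 40} %V̇O2R; each cell is scored by the proportion of
player-seconds classified identically to the manual criterion (raw counts
are kept alongside; multiple matches are pooled by summing correct and
total seconds — the proportion is scale-free across matches of different
length, the two representations differ by one multiplication). A full
bivariate quadratic f(W,T) = b0 + b1W + b2T + b3W² + b4T² + b5WT is fitted
by ordinary least squares, its quality summarised as the Pearson
correlation between fitted and observed scores, and maximised by solving
∇f = 0. The stationary point is accepted only when the Hessian
[[2b3, b5], [b5, 2b4]] is negative definite and the point lies inside the
grid's bounding box; otherwise the best of the box corners, per-edge 1-D
vertices and grid cells is returned, with the branch recorded
(`analytic` / `clamped` / `grid-fallback`). The continuous optimum is
reported at full precision and rounded to integers for use as detector
defaults. A sensitivity table (score spread over W ∈ [5,15], T ∈ [25,35])
quantifies how blunt the surface is near its maximum.

### Criterion validity

* **Per second:** 2×2 confusion matrix over player-seconds (manual
  on-court = positive). Accuracy = (TP+TN)/total, misclassification =
  (FN+FP)/total, precision = TP/(TP+FP), sensitivity = TP/(TP+FN), in
  percent. Accuracy and misclassification are computed with rational
  arithmetic, so they sum to exactly 100 before any rounding; display
  rounding is half-away-from-zero to one decimal.
* **Period pairing:** manual and automated periods are paired per player
  by maximal temporal overlap, greedily in manual order, each automated
  period used at most once, ties to the earliest automated period.
  Unmatched periods on either side are counted and reported — the two
  methods generally find unequal numbers of periods, so some periods
  necessarily go unpaired. Greedy matching is not guaranteed to maximise
  *total* overlap when one method merges periods the other splits; it is
  the fixed, documented choice because it is deterministic, order-stable
  and matches the intended one-to-one reading of period comparison.
* **Relative agreement:** Spearman's ρ on paired durations (Hopkins
  labels: ≥0.90 nearly perfect, 0.70–0.89 very large, 0.50–0.69 large),
  and ICC(A,1) — single-rating, absolute-agreement, two-way model — on
  natural-log durations (right-skewed; integer seconds ≥ 1, so the log is
  safe). ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) with
  k = 2 from the two-way ANOVA decomposition; 95% CI by the F-based method
  of McGraw & Wong (1996). The point estimate is identical under the
  mixed- and random-effects readings; the model label records which is
  intended. Cicchetti bands (≥0.75 excellent) are attached.
* **Absolute agreement:** median and 5th/95th percentiles
  (linear-interpolation quantiles) of the automated − manual duration
  differences. The sign convention is automated − manual, stated in the
  report. Durations are not normally distributed, so percentile bands are
  used instead of normal-theory limits of agreement; the report flags
  whether the 5th–95th band lies within twice the sample window.

## Synthetic match generator

`simulate` provides the test bed: no public accelerometry-with-annotation
dataset exists for this task, so correctness is demonstrated on matches
with known ground truth.

* **Schedule.** Four quarters (1350 s of playable span each) separated by
  120 s quarter breaks and a 900 s half time (match clock 6540 s).
  Within a quarter, live and stoppage durations alternate, drawn from
  lognormals. Lognormal because bout durations are positive and
  right-skewed; parameters are solved from the target median and
  quartiles (μ = ln median, σ = ln(UQ/LQ)/(2z₀.₇₅)) since published match
  descriptions report median (LQ–UQ), not mean/sd. Defaults: live median
  39 s, IQR 22–60 s; stoppages median 25 s, quartiles 18–35 s, floored at
  10 s (breaks shorter than that are part of live play by definition).
* **Rotations.** Exactly 5 of the roster (default 10) are on court per
  live period; 0–3 players are swapped at each stoppage. Ground truth per
  player-second is on-court ∩ live.
* **Intensity.** Active seconds draw from N(55, 12) %V̇O2R, all other
  seconds from N(12, 6), floored at 0. The midpoint of the two means
  (33.5 %V̇O2R) is the generator's planted threshold: the smoothed signal
  ramps between the levels across a boundary, so thresholding at the
  midpoint crosses the ramp with zero boundary offset, making it the
  score-maximising threshold by construction. Contamination defaults:
  per-second lull probability 0.05 (on-court player below threshold),
  burst probability 0.02 (bench player spiking), and throw-in
  micro-stoppages (probability 0.2 per period, 3–12 s) inserted *inside*
  live periods as shared low-intensity stretches — the ground truth stays
  live, mirroring the convention that short out-of-bounds breaks belong to
  live play.
* **Raw accelerometry.** Band-limited Gaussian noise per axis, rescaled
  second-by-second so that the filtered per-epoch mean magnitude maps
  (through mass and the calibration line) to the intensity series drawn
  for the same seed; 1 g gravity is added on z. The consumer-side second
  filter pass is compensated with a spectral gain factor computed from the
  filter's frequency response, leaving a residual relative RMS error of
  ~3% (tested < 10%).
* **Reproducibility.** One seed per command; per-player and per-purpose
  sub-streams are spawned deterministically from it.

What the generator does *not* emulate: biomechanically realistic impacts
and jumps, orientation changes, clock-run-down tactics (a real failure
mode of the method, deliberately unmodelled), time-out traffic, and
inter-observer annotation noise. Passing tests therefore show the
detection and statistics machinery is correct under the stated
distributional assumptions, not that the field performance on real matches
equals the synthetic numbers — synthetic matches are cleaner, and the
per-second accuracy on them (~99%) is accordingly higher than is realistic.

## Numerical choices and degenerate inputs

* Threshold ties count as active; all intervals half-open; match clock
  0-based integer seconds.
* Moving-average edges shrink (no padding); even windows centre one epoch
  early.
* Constant score grids: the surface fit warns and reports r as NaN.
* Precision with no positive calls (and sensitivity with no positive
  criterion seconds) is NaN, flagged rather than zero-filled.
* Spearman/ICC on constant inputs warn and return NaN; ICC needs ≥ 5
  pairs, Spearman ≥ 3.
* A singular Hessian in surface maximisation falls back to dense
  evaluation of edges and grid cells, flagged `grid-fallback`.
* The detector refuses rosters smaller than `min_players_active` (the
  team rule would blank the whole match) and series shorter than the
  match clock.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
full-length matches (6540 s, 10 players) for end-to-end checks — a single
detection pass is a few milliseconds — and shorter structurally complete
matches (a few hundred seconds) where only the mechanics are under test,
such as the 100 Hz raw-accelerometry chain.
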