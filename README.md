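# liveplay

Automated detection of **live-play periods** in basketball from
accelerometry-derived relative exercise intensity.

Basketball is intermittent: bouts of live play (ball in play, game clock
running; median duration around 39 s) are separated by frequent stoppages.
Describing match demands *per live-play period* normally requires
annotating video by hand. `liveplay` replaces that with an automated
method for body-worn accelerometers, aimed at sport scientists and
performance staff who instrument players with trunk-mounted 100 Hz
triaxial devices.

## Method

Per player, raw acceleration is band-pass filtered (Butterworth, 0.1–15 Hz,
zero-phase), reduced to per-second average net force
AvF_NET = m·mean‖a‖ (N), and mapped to a percentage of oxygen-uptake
reserve (%V̇O2R) by a per-player linear calibration. Each match-clock
second is then classified:

1. smooth the 1-s %V̇O2R epochs with a centred moving average of **W** s;
2. mark second *t* active iff the smoothed value ≥ threshold **T** %V̇O2R;
3. fill inactive gaps shorter than 10 s that are flanked by activity
   (stoppages outlast 10 s; shorter lulls are on-court low-intensity play);
4. if ≤ 2 players are active at a second, set **all** players inactive
   (substitution traffic control);
5. force half time inactive and segment maximal active runs into periods.

Defaults W = 9 s, T = 31 %V̇O2R. The package also implements the procedure
that selects them — scoring every (W, T) on a 5×5 grid against manual
annotation by the proportion of identically classified player-seconds,
fitting the full quadratic f(W,T) = b0 + b1W + b2T + b3W² + b4T² + b5WT
and maximising it analytically — and the criterion-validity battery used
to judge the result: per-second confusion matrix (accuracy,
misclassification, precision, sensitivity), Spearman's ρ and
absolute-agreement ICC(A,1) with 95% CI on log period durations, and the
median with 5th/95th percentiles of the automated − manual duration
differences. A built-in simulator generates whole matches (schedules,
5-player rotations, intensity, optional raw 100 Hz traces) with known
ground truth.

## Worked example

```python
import liveplay as lp

schedule, series, truth = lp.simulate_match(lp.SimulationParams(), seed=7)
print(f"simulated match: {schedule.match_end_s} s, "
      f"{len(schedule.live_periods)} live periods")

result = lp.detect_live_play(
    series, lp.DetectorParams(window_s=9, threshold_pct=31.0),
    match_end_s=schedule.match_end_s, exclusions=[schedule.half_time],
)
print(f"detected team periods: {len(result.team_periods)}")

report = lp.evaluate(result.player_masks, truth, window_s=9)
m = report.metrics.rounded()
print(f"accuracy {m['accuracy_pct']}%  precision {m['precision_pct']}%  "
      f"sensitivity {m['sensitivity_pct']}%")
print(f"rho {report.rho.rho:.3f} ({report.rho.label}), "
      f"ICC {report.icc.icc:.3f} ({report.icc.label})")
print(f"bias {report.bias.median:g} s ({report.bias.p5:g} to {report.bias.p95:g} s)")

match = lp.MatchInputs(series, truth, schedule.match_end_s, [schedule.half_time])
grid, model = lp.optimize_parameters(match)
w, t = model.optimum
print(f"optimum: W = {w:.1f} s, T = {t:.1f} %VO2R (surface r = {model.fit_r:.3f})")
```

prints

```
simulated match: 6540 s, 82 live periods
detected team periods: 84
accuracy 98.8%  precision 98.5%  sensitivity 96.6%
rho 0.946 (nearly perfect), ICC 0.943 (excellent)
bias 0 s (-13.85 to 2 s)
optimum: W = 5.0 s, T = 30.9 %VO2R (surface r = 0.969)
```

Reading it: the detector classified 98.8% of player-seconds the same as
the ground truth; matched period durations correlate at ρ = 0.95 with an
excellent absolute-agreement ICC; the median duration difference is 0 s
with the 5th–95th percentile band well inside twice the sample window. The
grid search on this match prefers the smallest window and a threshold
within one grid step of the generator's planted separation midpoint; the
quadratic surface fits the 25 scores at r ≈ 0.97. (Synthetic matches are
cleaner than real ones — see `docs/methods.md` for what the simulator does
and does not emulate.)

The same steps are available from the shell:

```sh
liveplay simulate --seed 7 --out match/
liveplay detect   --intensity match/intensity.csv --config match/config.yaml --out det/
liveplay optimize --intensity match/intensity.csv --annotations match/annotations.csv \
                  --config match/config.yaml --rotations match/rotations.csv --out opt.json
liveplay evaluate --auto-masks det/player_masks.csv --manual match/annotations.csv \
                  --config match/config.yaml --rotations match/rotations.csv --out report.json
```

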