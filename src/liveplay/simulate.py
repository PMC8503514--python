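"""Synthetic basketball match generator.

Produces the three artefacts the rest of the package consumes, with known
ground truth:

* a **schedule** — alternating live-play and stoppage periods over four
  quarters with a half-time break, plus 5-player on-court rotations that
  change only at stoppages;
* **intensity traces** — per-player per-second %V̇O2R drawn from an
  "active" distribution on on-court live seconds and an "inactive"
  distribution elsewhere, with configurable contamination (lulls on court,
  bursts on the bench, throw-in micro-stoppages inside live periods);
* optionally **raw 100 Hz triaxial accelerometry** whose filtered
  per-second envelope lands at the intensity targets, to exercise the full
  signal chain.

Durations are lognormal because live-play bouts are positive and
right-skewed (reported medians sit well below means, with asymmetric
interquartile ranges); the lognormal parameters are solved from the target
median and quartiles rather than mean/sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sps
from scipy import stats as _stats

from .signal import (
    G_TO_MS2,
    AccelTrace,
    RelativeIntensitySeries,
    design_bandpass,
)

#: z-score of the 75th percentile of the standard normal.
_Z75 = float(_stats.norm.ppf(0.75))


@dataclass
class SimulationParams:
    """Generator defaults: the study conditions the detector assumes.

    Live-play durations follow the published match description (median
    39 s, IQR 22-60 s); stoppages are right-skewed with a 10 s floor
    (shorter breaks are treated as part of live play).  Intensity levels
    put active play at moderate intensity (55 %V̇O2R) and bench/stoppage
    time well below the "light" band (12 %V̇O2R), with the detection
    threshold of ~31 %V̇O2R between them.
    """

    # live-play durations (s)
    live_median_s: float = 39.0
    live_lq_s: float = 22.0
    live_uq_s: float = 60.0
    # stoppage durations (s)
    stoppage_median_s: float = 25.0
    stoppage_lq_s: float = 18.0
    stoppage_uq_s: float = 35.0
    stoppage_min_s: float = 10.0
    # intensity levels (%V̇O2R)
    active_mean: float = 55.0
    active_sd: float = 12.0
    inactive_mean: float = 12.0
    inactive_sd: float = 6.0
    # contamination (probability per second / per period)
    lull_rate: float = 0.05
    burst_rate: float = 0.02
    microstoppage_prob: float = 0.2
    microstoppage_max_s: int = 12
    # roster and clock structure (s)
    roster_size: int = 10
    quarter_span_s: int = 1350
    quarter_break_s: int = 120
    half_time_s: int = 900
    # raw-accelerometry synthesis
    sample_rate_hz: float = 100.0
    body_mass_kg: float = 90.0
    cal_slope: float = 0.08  # %V̇O2R per newton
    cal_intercept: float = 4.0

    def __post_init__(self) -> None:
        for name in ("live_median_s", "live_lq_s", "live_uq_s",
                     "stoppage_median_s", "stoppage_lq_s", "stoppage_uq_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.live_lq_s <= self.live_median_s <= self.live_uq_s:
            raise ValueError("live quartiles must bracket the median")
        if not self.stoppage_lq_s <= self.stoppage_median_s <= self.stoppage_uq_s:
            raise ValueError("stoppage quartiles must bracket the median")
        for name in ("lull_rate", "burst_rate", "microstoppage_prob"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if min(self.active_sd, self.inactive_sd) < 0:
            raise ValueError("intensity sds must be non-negative")
        if self.roster_size < 1:
            raise ValueError("roster_size must be >= 1")

    @property
    def match_end_s(self) -> int:
        return 4 * self.quarter_span_s + 2 * self.quarter_break_s + self.half_time_s

    @property
    def half_time(self) -> tuple[int, int]:
        start = 2 * self.quarter_span_s + self.quarter_break_s
        return (start, start + self.half_time_s)

    @property
    def separability_midpoint(self) -> float:
        """Midpoint of the active/inactive means: the planted threshold.

        The smoothed intensity ramps between the two levels across a
        period boundary; thresholding at the midpoint crosses the ramp
        with zero boundary offset, so it is the score-maximising threshold
        by construction.
        """
        return (self.active_mean + self.inactive_mean) / 2.0


@dataclass
class MatchSchedule:
    """Ground-truth match structure: live periods, half time, rotations."""

    live_periods: list[tuple[int, int]]
    half_time: tuple[int, int]
    lineups: list[frozenset[str]]  # on-court set per live period
    player_ids: list[str]
    match_end_s: int
    seed: int

    def rotations(self) -> dict[str, list[tuple[int, int]]]:
        """Per-player on-court intervals.

        A player who plays two consecutive live periods stays on court
        through the stoppage between them, so those spans are merged.
        """
        out: dict[str, list[tuple[int, int]]] = {pid: [] for pid in self.player_ids}
        for i, ((start, end), lineup) in enumerate(
            zip(self.live_periods, self.lineups)
        ):
            for pid in lineup:
                spans = out[pid]
                if spans and i > 0 and pid in self.lineups[i - 1] and (
                    spans[-1][1] == self.live_periods[i - 1][1]
                ):
                    spans[-1] = (spans[-1][0], end)
                else:
                    spans.append((start, end))
        return out

    def truth_masks(self) -> dict[str, np.ndarray]:
        """Per-player ground truth: on court AND clock running."""
        masks = {
            pid: np.zeros(self.match_end_s, dtype=bool) for pid in self.player_ids
        }
        for (start, end), lineup in zip(self.live_periods, self.lineups):
            for pid in lineup:
                masks[pid][start:end] = True
        return masks

    def team_mask(self) -> np.ndarray:
        mask = np.zeros(self.match_end_s, dtype=bool)
        for start, end in self.live_periods:
            mask[start:end] = True
        return mask


def lognormal_from_quartiles(median: float, lq: float, uq: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and quartiles.

    mu = ln(median); sigma solves the interquartile ratio,
    sigma = ln(uq/lq) / (2 z_{0.75}).  Degenerate quartiles (lq == uq)
    give sigma = 0, i.e. all draws equal the median.
    """
    if not 0 < lq <= median <= uq:
        raise ValueError("need 0 < lq <= median <= uq")
    mu = np.log(median)
    sigma = np.log(uq / lq) / (2 * _Z75)
    return float(mu), float(sigma)


def _draw_duration(rng: np.random.Generator, mu: float, sigma: float,
                   minimum: float = 1.0) -> int:
    d = float(rng.lognormal(mu, sigma)) if sigma > 0 else float(np.exp(mu))
    return int(max(minimum, round(d)))


def generate_schedule(params: SimulationParams | None = None, seed: int = 0) -> MatchSchedule:
    """Draw a full match schedule with rotations; reproducible from seed."""
    params = params or SimulationParams()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    mu_l, sg_l = lognormal_from_quartiles(
        params.live_median_s, params.live_lq_s, params.live_uq_s
    )
    mu_s, sg_s = lognormal_from_quartiles(
        params.stoppage_median_s, params.stoppage_lq_s, params.stoppage_uq_s
    )

    q = params.quarter_span_s
    b = params.quarter_break_s
    h = params.half_time_s
    quarter_spans = [
        (0, q),
        (q + b, 2 * q + b),
        (2 * q + b + h, 3 * q + b + h),
        (3 * q + 2 * b + h, 4 * q + 2 * b + h),
    ]
    live_periods: list[tuple[int, int]] = []
    for qi, (q_start, q_end) in enumerate(quarter_spans):
        t = q_start
        first = True
        while t < q_end:
            if not first or qi not in (0, 2):
                # stoppage before the next live period (tip-off and the
                # restart after half time begin with live play immediately)
                t += max(
                    _draw_duration(rng, mu_s, sg_s, params.stoppage_min_s),
                    int(params.stoppage_min_s),
                )
            first = False
            if t >= q_end:
                break
            dur = _draw_duration(rng, mu_l, sg_l, 1.0)
            end = min(t + dur, q_end)
            if end > t:
                live_periods.append((t, end))
            t = end

    player_ids = [f"p{i:02d}" for i in range(params.roster_size)]
    lineups: list[frozenset[str]] = []
    if params.roster_size < 5:
        warnings.warn(
            "roster smaller than 5: all players on court for every live period"
        )
        lineups = [frozenset(player_ids) for _ in live_periods]
    else:
        on_court = list(rng.choice(player_ids, size=5, replace=False))
        for _ in live_periods:
            lineups.append(frozenset(on_court))
            bench = [p for p in player_ids if p not in on_court]
            n_swap = int(rng.integers(0, min(3, len(bench)) + 1))
            if n_swap:
                out_ids = rng.choice(on_court, size=n_swap, replace=False)
                in_ids = rng.choice(bench, size=n_swap, replace=False)
                on_court = [p for p in on_court if p not in out_ids] + list(in_ids)

    return MatchSchedule(
        live_periods=live_periods,
        half_time=params.half_time,
        lineups=lineups,
        player_ids=player_ids,
        match_end_s=params.match_end_s,
        seed=int(seed),
    )


def generate_intensity(
    schedule: MatchSchedule,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, RelativeIntensitySeries], dict[str, np.ndarray]]:
    """Per-player %V̇O2R series plus ground-truth activity masks.

    Active draws on on-court live seconds, inactive draws elsewhere;
    contamination (lulls, bursts, shared throw-in micro-stoppages) moves
    individual seconds across the two distributions without changing the
    ground truth.
    """
    params = params or SimulationParams()
    truth = schedule.truth_masks()
    n = schedule.match_end_s
    root = np.random.SeedSequence([int(seed), 1])
    period_rng = np.random.default_rng(root.spawn(1)[0])

    # throw-in micro-stoppages: shared low-intensity stretches inside live
    # periods, affecting every on-court player; ground truth stays live
    micro = np.zeros(n, dtype=bool)
    for start, end in schedule.live_periods:
        if period_rng.random() < params.microstoppage_prob:
            dur = int(period_rng.integers(3, params.microstoppage_max_s + 1))
            if end - start > dur + 2:
                s0 = int(period_rng.integers(start + 1, end - dur))
                micro[s0 : s0 + dur] = True

    series: dict[str, RelativeIntensitySeries] = {}
    child_seqs = root.spawn(len(schedule.player_ids) + 1)[1:]
    for pid, seq in zip(schedule.player_ids, child_seqs):
        rng = np.random.default_rng(seq)
        active = truth[pid].copy()
        # intensity-level state: active minus lulls/micro-stoppages,
        # inactive plus bursts
        lulls = rng.random(n) < params.lull_rate
        bursts = rng.random(n) < params.burst_rate
        hot = active & ~lulls & ~micro
        hot |= ~active & bursts
        values = np.where(
            hot,
            rng.normal(params.active_mean, params.active_sd, size=n),
            rng.normal(params.inactive_mean, params.inactive_sd, size=n),
        )
        series[pid] = RelativeIntensitySeries(
            values=np.clip(values, 0.0, None), player_id=pid
        )
    return series, truth


# ---------------------------------------------------------------------------
# raw accelerometry synthesis


def _filter_power_gains(params: SimulationParams) -> tuple[float, float]:
    """(first-pass, second-pass) std gains of the zero-phase band-pass on
    white noise, from the filter's frequency response."""
    sos = design_bandpass(sample_rate_hz=params.sample_rate_hz)
    freqs = np.linspace(0, params.sample_rate_hz / 2, 4096)
    _, h = _sps.sosfreqz(sos, worN=freqs, fs=params.sample_rate_hz)
    p = np.abs(h) ** 4  # zero-phase single pass: power gain |H|^4
    g1 = float(np.sqrt(p.mean()))
    g2 = float(np.sqrt((p * p).mean() / p.mean()))
    return g1, g2


def generate_raw_accel(
    schedule: MatchSchedule,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> dict[str, AccelTrace]:
    """100 Hz triaxial traces whose processed envelope matches the intensity.

    Each trace is 1 g gravity on the z axis plus band-limited Gaussian
    noise rescaled second-by-second so that, after the band-pass /
    AvF_NET / calibration chain with the generator's mass and calibration
    coefficients, the per-second %V̇O2R lands at the values
    :func:`generate_intensity` draws for the same seed.  The consumer-side
    second filter pass is compensated with an analytic spectral gain.
    """
    params = params or SimulationParams()
    intensity, _ = generate_intensity(schedule, params, seed)
    sos = design_bandpass(sample_rate_hz=params.sample_rate_hz)
    _, g2 = _filter_power_gains(params)
    sps = int(round(params.sample_rate_hz))
    n_seconds = schedule.match_end_s
    n_samples = n_seconds * sps
    root = np.random.SeedSequence([int(seed), 2])
    traces: dict[str, AccelTrace] = {}
    for pid, seq in zip(schedule.player_ids, root.spawn(len(schedule.player_ids))):
        rng = np.random.default_rng(seq)
        target_v = intensity[pid].values
        force = np.clip((target_v - params.cal_intercept) / params.cal_slope, 0.0, None)
        target_mag_g = force / (params.body_mass_kg * G_TO_MS2)  # mean |a| in g

        noise = rng.standard_normal((n_samples, 3))
        noise = _sps.sosfiltfilt(sos, noise, axis=0)
        mag = np.linalg.norm(noise, axis=1)
        per_sec = mag.reshape(n_seconds, sps).mean(axis=1)
        scale = np.zeros(n_seconds)
        nonzero = per_sec > 0
        scale[nonzero] = target_mag_g[nonzero] / (per_sec[nonzero] * g2)
        noise *= np.repeat(scale, sps)[:, None]
        noise[:, 2] += 1.0  # gravity
        traces[pid] = AccelTrace(
            data=noise, sample_rate_hz=params.sample_rate_hz, player_id=pid,
            filtered=False,
        )
    return traces


def simulate_match(
    params: SimulationParams | None = None, seed: int = 0
) -> tuple[MatchSchedule, dict[str, RelativeIntensitySeries], dict[str, np.ndarray]]:
    """Schedule + intensity + ground truth in one call."""
    params = params or SimulationParams()
    schedule = generate_schedule(params, seed)
    series, truth = generate_intensity(schedule, params, seed)
    return schedule, series, truth
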