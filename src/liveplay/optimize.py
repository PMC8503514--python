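"""Detector parameter optimisation: grid search + quadratic response surface.

The automated method is run for every combination of sample window W and
intensity threshold T on a grid (default {5,10,15,20,25} s x
{20,25,30,35,40} %V̇O2R); each cell is scored by the proportion of
player-seconds classified identically to the manual criterion.  A full
bivariate quadratic

    f(W, T) = b0 + b1 W + b2 T + b3 W^2 + b4 T^2 + b5 W T

is fitted to the scores by ordinary least squares and maximised
analytically; the stationary point is accepted only when the Hessian is
negative definite and the point lies inside the grid's bounding box,
otherwise the best point on the box edges / grid is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detector import DetectorParams, detect_live_play
from .signal import RelativeIntensitySeries

DEFAULT_WINDOWS_S = (5, 10, 15, 20, 25)
DEFAULT_THRESHOLDS_PCT = (20.0, 25.0, 30.0, 35.0, 40.0)


@dataclass
class MatchInputs:
    """One match's inputs to the grid search: intensity + manual criterion."""

    intensity: Mapping[str, RelativeIntensitySeries]
    manual_masks: Mapping[str, np.ndarray]
    match_end_s: int
    exclusions: Sequence[tuple[int, int]] = ()


@dataclass
class ScoreResult:
    correct_seconds: int
    total_seconds: int

    @property
    def proportion(self) -> float:
        return self.correct_seconds / self.total_seconds


@dataclass
class ParameterGrid:
    """Scored (W, T) grid: proportion and raw count of correct player-seconds."""

    windows_s: np.ndarray
    thresholds_pct: np.ndarray
    proportion: np.ndarray  # (n_windows, n_thresholds)
    correct: np.ndarray
    total: int

    def best_cell(self) -> tuple[float, float]:
        """(W, T) of the arg-max cell (first by row-major order on ties)."""
        i, j = np.unravel_index(int(np.argmax(self.proportion)), self.proportion.shape)
        return float(self.windows_s[i]), float(self.thresholds_pct[j])


@dataclass
class SurfaceModel:
    """Fitted quadratic surface over (W, T) and its maximiser."""

    coefficients: np.ndarray  # b0..b5
    fit_r: float
    response: str = "proportion"
    optimum: tuple[float, float] | None = None
    optimum_source: str | None = None

    def __call__(self, w, t):
        b0, b1, b2, b3, b4, b5 = self.coefficients
        w = np.asarray(w, dtype=float)
        t = np.asarray(t, dtype=float)
        return b0 + b1 * w + b2 * t + b3 * w**2 + b4 * t**2 + b5 * w * t


def score_parameters(
    auto_masks: Mapping[str, np.ndarray],
    manual_masks: Mapping[str, np.ndarray],
) -> ScoreResult:
    """Count player-seconds where automated and manual states agree."""
    if set(auto_masks) != set(manual_masks):
        raise ValueError(
            f"rosters differ: {sorted(auto_masks)} vs {sorted(manual_masks)}"
        )
    correct = 0
    total = 0
    for pid, auto in auto_masks.items():
        auto = np.asarray(auto, dtype=bool)
        manual = np.asarray(manual_masks[pid], dtype=bool)
        if auto.shape != manual.shape:
            raise ValueError(f"player {pid}: mask lengths differ")
        correct += int(np.sum(auto == manual))
        total += auto.size
    if total == 0:
        raise ValueError("no player-seconds to score")
    return ScoreResult(correct_seconds=correct, total_seconds=total)


def grid_search(
    matches: MatchInputs | Sequence[MatchInputs],
    windows_s: Sequence[int] = DEFAULT_WINDOWS_S,
    thresholds_pct: Sequence[float] = DEFAULT_THRESHOLDS_PCT,
    base_params: DetectorParams | None = None,
) -> ParameterGrid:
    """Score every (W, T) combination against the manual criterion.

    Multiple matches are pooled by summing correct and total player-seconds
    before any surface fitting, so matches of different length contribute
    by duration.
    """
    if isinstance(matches, MatchInputs):
        matches = [matches]
    windows = np.asarray(sorted(windows_s), dtype=float)
    thresholds = np.asarray(sorted(thresholds_pct), dtype=float)
    if windows.size < 2 or thresholds.size < 2:
        raise ValueError("grid must be at least 2x2")
    base = base_params or DetectorParams()
    correct = np.zeros((windows.size, thresholds.size), dtype=int)
    total = 0
    for i, w in enumerate(windows):
        for j, t in enumerate(thresholds):
            params = DetectorParams(
                window_s=int(w),
                threshold_pct=float(t),
                min_gap_s=base.min_gap_s,
                min_players_active=base.min_players_active,
                team_rule_first=base.team_rule_first,
            )
            cell_total = 0
            for k, match in enumerate(matches):
                try:
                    result = detect_live_play(
                        match.intensity,
                        params,
                        match_end_s=match.match_end_s,
                        exclusions=match.exclusions,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"grid cell (W={w:g}, T={t:g}), match {k}: {exc}"
                    ) from exc
                score = score_parameters(result.player_masks, match.manual_masks)
                correct[i, j] += score.correct_seconds
                cell_total += score.total_seconds
            if total and cell_total != total:
                raise RuntimeError("inconsistent total seconds across grid cells")
            total = cell_total
    return ParameterGrid(
        windows_s=windows,
        thresholds_pct=thresholds,
        proportion=correct / total,
        correct=correct,
        total=total,
    )


def _design_matrix(w: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(w), w, t, w**2, t**2, w * t])


def fit_quadratic_surface(grid: ParameterGrid, response: str = "proportion") -> SurfaceModel:
    """Ordinary least squares of the score on [1, W, T, W², T², W·T]."""
    ww, tt = np.meshgrid(grid.windows_s, grid.thresholds_pct, indexing="ij")
    w = ww.ravel()
    t = tt.ravel()
    if response == "proportion":
        y = grid.proportion.ravel()
    elif response == "count":
        y = grid.correct.ravel().astype(float)
    else:
        raise ValueError(f"unknown response {response!r}")
    if w.size < 6:
        raise ValueError("need at least 6 grid cells to fit 6 coefficients")
    design = _design_matrix(w, t)
    rank = np.linalg.matrix_rank(design)
    if rank < 6:
        raise ValueError(
            "rank-deficient design (e.g. a single distinct window value); "
            "cannot identify the quadratic surface"
        )
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coeffs
    if np.ptp(y) == 0 or np.ptp(fitted) < 1e-14 * max(1.0, float(np.abs(y).max())):
        warnings.warn(
            "constant scores: surface fit correlation is undefined", RuntimeWarning
        )
        fit_r = float("nan")
    else:
        fit_r = float(np.corrcoef(fitted, y)[0, 1])
    return SurfaceModel(coefficients=coeffs, fit_r=fit_r, response=response)


def optimize_surface(
    model: SurfaceModel,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    grid: ParameterGrid | None = None,
) -> tuple[float, float]:
    """Maximise the fitted quadratic over the bounding box.

    Solves the stationary system ∇f = 0; the interior solution is kept only
    when the Hessian [[2 b3, b5], [b5, 2 b4]] is negative definite and the
    point lies inside ``bounds``.  Otherwise the maximum over the box edges
    (per-edge 1-D quadratic vertices plus corners) and, if supplied, the
    grid cells is returned.  ``model.optimum_source`` records which branch
    produced the result.
    """
    (wmin, wmax), (tmin, tmax) = bounds
    _, b1, b2, b3, b4, b5 = model.coefficients
    hessian = np.array([[2 * b3, b5], [b5, 2 * b4]])
    source = None
    optimum = None
    det = np.linalg.det(hessian)
    if abs(det) > 1e-12 * max(1.0, float(np.abs(hessian).max()) ** 2):
        w_star, t_star = np.linalg.solve(hessian, [-b1, -b2])
        neg_definite = hessian[0, 0] < 0 and det > 0
        inside = wmin <= w_star <= wmax and tmin <= t_star <= tmax
        if neg_definite and inside:
            optimum = (float(w_star), float(t_star))
            source = "analytic"
    else:
        source = "grid-fallback"

    if optimum is None:
        candidates: list[tuple[float, float]] = [
            (wmin, tmin), (wmin, tmax), (wmax, tmin), (wmax, tmax)
        ]
        # per-edge 1-D quadratic vertices
        for w_fixed in (wmin, wmax):
            # f(t) at fixed w: (b4) t^2 + (b2 + b5 w) t + ...
            if b4 < 0:
                t_v = -(b2 + b5 * w_fixed) / (2 * b4)
                if tmin <= t_v <= tmax:
                    candidates.append((w_fixed, float(t_v)))
        for t_fixed in (tmin, tmax):
            if b3 < 0:
                w_v = -(b1 + b5 * t_fixed) / (2 * b3)
                if wmin <= w_v <= wmax:
                    candidates.append((float(w_v), t_fixed))
        if grid is not None:
            for w in grid.windows_s:
                for t in grid.thresholds_pct:
                    candidates.append((float(w), float(t)))
        values = [model(w, t) for w, t in candidates]
        optimum = candidates[int(np.argmax(values))]
        source = source or "clamped"

    model.optimum = optimum
    model.optimum_source = source
    return optimum


def sensitivity_table(
    grid: ParameterGrid,
    w_range: tuple[float, float] = (5, 15),
    t_range: tuple[float, float] = (25, 35),
) -> dict:
    """Score spread over a sub-range of the grid.

    Quantifies how blunt the response surface is near its maximum: the
    spread (max - min, percentage points of correctly classified match
    time) across grid cells inside ``w_range`` x ``t_range``, and the drop
    from the global best cell to the worst cell in the range.
    """
    wi = (grid.windows_s >= w_range[0]) & (grid.windows_s <= w_range[1])
    tj = (grid.thresholds_pct >= t_range[0]) & (grid.thresholds_pct <= t_range[1])
    sub = grid.proportion[np.ix_(wi, tj)]
    if sub.size == 0:
        raise ValueError("no grid cells inside the requested ranges")
    return {
        "w_range": list(w_range),
        "t_range": list(t_range),
        "n_cells": int(sub.size),
        "spread_pct": float((sub.max() - sub.min()) * 100),
        "drop_from_best_pct": float((grid.proportion.max() - sub.min()) * 100),
    }


def optimize_parameters(
    matches: MatchInputs | Sequence[MatchInputs],
    windows_s: Sequence[int] = DEFAULT_WINDOWS_S,
    thresholds_pct: Sequence[float] = DEFAULT_THRESHOLDS_PCT,
    base_params: DetectorParams | None = None,
) -> tuple[ParameterGrid, SurfaceModel]:
    """Grid search, surface fit and maximisation in one call.

    The continuous optimum is stored at full precision in
    ``model.optimum``; round to the nearest integer second / percent for
    use as detector defaults.
    """
    grid = grid_search(matches, windows_s, thresholds_pct, base_params)
    model = fit_quadratic_surface(grid)
    bounds = (
        (float(grid.windows_s.min()), float(grid.windows_s.max())),
        (float(grid.thresholds_pct.min()), float(grid.thresholds_pct.max())),
    )
    optimize_surface(model, bounds, grid)
    return grid, model
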