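"""Criterion-validity statistics: automated vs manual live-play detection.

Two complementary views of agreement:

* **per second** — a 2x2 confusion matrix over player-seconds (manual
  on-court as the positive class) with accuracy, misclassification,
  precision and sensitivity;
* **per period** — manual and automated periods are paired by maximal
  temporal overlap, then the paired durations are compared with
  Spearman's ρ (relative agreement), a single-rating absolute-agreement
  intraclass correlation on log durations (relative agreement penalising
  systematic offsets), and the median with 5th/95th percentiles of the
  automated-minus-manual differences (distribution-free absolute
  agreement; the durations are right-skewed, so normal-theory limits of
  agreement are avoided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .detector import LivePlayPeriod


@dataclass(frozen=True)
class ConfusionCounts:
    """Player-second counts; rows manual, columns automated; positive = on court."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


@dataclass
class ClassificationMetrics:
    """Percentages derived from a confusion matrix (full precision).

    ``accuracy + misclassification == 100`` exactly: both are computed with
    rational arithmetic before conversion to float.  Precision with no
    positive calls, or sensitivity with no positive criterion seconds, is
    NaN.  Use :meth:`rounded` for one-decimal display values.
    """

    accuracy_pct: float
    misclassification_pct: float
    precision_pct: float
    sensitivity_pct: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "accuracy_pct": round_half_away(self.accuracy_pct, ndigits),
            "misclassification_pct": round_half_away(self.misclassification_pct, ndigits),
            "precision_pct": round_half_away(self.precision_pct, ndigits),
            "sensitivity_pct": round_half_away(self.sensitivity_pct, ndigits),
        }


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    label: str
    n: int


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str  # "two-way mixed" | "two-way random"
    log_transformed: bool
    label: str
    n: int


@dataclass
class BiasResult:
    """automated - manual duration differences, distribution-free summary."""

    median: float
    p5: float
    p95: float
    n: int
    within_two_windows: bool | None = None


@dataclass
class AgreementReport:
    counts: ConfusionCounts
    metrics: ClassificationMetrics
    rho: SpearmanResult | None
    icc: ICCResult | None
    bias: BiasResult | None
    n_periods_manual: int
    n_periods_auto: int
    n_matched: int
    agreement_proportion: float

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    if not math.isfinite(value):
        return value
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def confusion_counts(
    auto_masks: Mapping[str, np.ndarray] | np.ndarray,
    manual_masks: Mapping[str, np.ndarray] | np.ndarray,
) -> ConfusionCounts:
    """Per player-second cross-tabulation of manual vs automated state."""
    if not isinstance(auto_masks, Mapping):
        auto_masks = {"team": auto_masks}
    if not isinstance(manual_masks, Mapping):
        manual_masks = {"team": manual_masks}
    if set(auto_masks) != set(manual_masks):
        raise ValueError(
            f"rosters differ: {sorted(auto_masks)} vs {sorted(manual_masks)}"
        )
    tp = fn = fp = tn = 0
    for pid in auto_masks:
        auto = np.asarray(auto_masks[pid], dtype=bool)
        manual = np.asarray(manual_masks[pid], dtype=bool)
        if auto.shape != manual.shape:
            raise ValueError(f"player {pid}: mask lengths differ")
        tp += int(np.sum(manual & auto))
        fn += int(np.sum(manual & ~auto))
        fp += int(np.sum(~manual & auto))
        tn += int(np.sum(~manual & ~auto))
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, misclassification, precision and sensitivity, in percent."""
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = Fraction(counts.tp + counts.tn, total) * 100
    misclassification = Fraction(counts.fn + counts.fp, total) * 100
    if counts.tp + counts.fp:
        precision = float(Fraction(counts.tp, counts.tp + counts.fp) * 100)
    else:
        precision = float("nan")
    if counts.tp + counts.fn:
        sensitivity = float(Fraction(counts.tp, counts.tp + counts.fn) * 100)
    else:
        sensitivity = float("nan")
    return ClassificationMetrics(
        accuracy_pct=float(accuracy),
        misclassification_pct=float(misclassification),
        precision_pct=precision,
        sensitivity_pct=sensitivity,
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _as_interval(p) -> tuple[int, int]:
    if isinstance(p, LivePlayPeriod):
        return (p.start_s, p.end_s)
    return (int(p[0]), int(p[1]))


def match_periods(
    manual_periods: Sequence,
    auto_periods: Sequence,
) -> tuple[list[tuple[tuple[int, int], tuple[int, int]]], list[tuple[int, int]], list[tuple[int, int]]]:
    """Pair manual periods with automated periods by maximal overlap.

    Greedy in manual order: each manual period takes the not-yet-used
    automated period of maximal temporal overlap (ties broken by the
    earliest automated period).  Manual periods with zero overlap to every
    unused automated period, and unused automated periods, are returned as
    unmatched.
    """
    manual = [_as_interval(p) for p in manual_periods]
    auto = [_as_interval(p) for p in auto_periods]
    used = [False] * len(auto)
    pairs = []
    unmatched_manual = []
    for m in manual:
        best_j = -1
        best_ov = 0
        for j, a in enumerate(auto):
            if used[j]:
                continue
            ov = _overlap(m, a)
            if ov > best_ov:
                best_ov, best_j = ov, j
        if best_j >= 0:
            used[best_j] = True
            pairs.append((m, auto[best_j]))
        else:
            unmatched_manual.append(m)
    unmatched_auto = [a for j, a in enumerate(auto) if not used[j]]
    return pairs, unmatched_manual, unmatched_auto


_HOPKINS_BANDS = [
    (0.90, "nearly perfect"),
    (0.70, "very large"),
    (0.50, "large"),
    (0.30, "moderate"),
    (0.10, "small"),
    (0.0, "trivial"),
]

_CICCHETTI_BANDS = [
    (0.75, "excellent"),
    (0.60, "good"),
    (0.40, "fair"),
    (-1.0, "poor"),
]


def _band(value: float, bands) -> str:
    if not math.isfinite(value):
        return "undefined"
    for cut, label in bands:
        if abs(value) >= cut if bands is _HOPKINS_BANDS else value >= cut:
            return label
    return bands[-1][1]


def spearman_rho(
    manual_durations: Sequence[float], auto_durations: Sequence[float]
) -> SpearmanResult:
    """Spearman rank correlation of paired durations, with Hopkins label."""
    manual = np.asarray(manual_durations, dtype=float)
    auto = np.asarray(auto_durations, dtype=float)
    if manual.size != auto.size:
        raise ValueError("paired durations must have equal length")
    if manual.size < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(manual) == 0 or np.ptp(auto) == 0:
        warnings.warn("constant durations: Spearman's rho is undefined", RuntimeWarning)
        return SpearmanResult(float("nan"), float("nan"), "undefined", manual.size)
    rho, p = _stats.spearmanr(manual, auto)
    return SpearmanResult(float(rho), float(p), _band(float(rho), _HOPKINS_BANDS), manual.size)


def _two_way_anova(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, error) of a two-way crossed layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(
    manual_durations: Sequence[float],
    auto_durations: Sequence[float],
    model: str = "mixed",
    log_transform: bool = True,
    confidence: float = 0.95,
) -> ICCResult:
    """Single-rating absolute-agreement intraclass correlation, ICC(A,1).

    From the two-way ANOVA decomposition with k = 2 raters (methods) and n
    subjects (periods)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the F-based confidence interval of McGraw & Wong (1996).  The
    point estimate and interval are identical for the two-way mixed and
    two-way random formulations; ``model`` only sets the report label.
    Durations are natural-log transformed by default (they are
    right-skewed and >= 1 s by construction).
    """
    if model not in ("mixed", "random"):
        raise ValueError("model must be 'mixed' or 'random'")
    manual = np.asarray(manual_durations, dtype=float)
    auto = np.asarray(auto_durations, dtype=float)
    if manual.size != auto.size:
        raise ValueError("paired durations must have equal length")
    n = manual.size
    if n < 5:
        raise ValueError("need at least 5 pairs for a stable ICC")
    if log_transform:
        if (manual < 1).any() or (auto < 1).any():
            raise ValueError("log transform requires durations >= 1 s")
        manual = np.log(manual)
        auto = np.log(auto)
    x = np.column_stack([manual, auto])
    k = 2
    msr, msc, mse = _two_way_anova(x)
    label_model = f"two-way {model}"
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.ptp(x[:, 0] + x[:, 1]) == 0:
        warnings.warn("no between-subject variance: ICC is undefined", RuntimeWarning)
        return ICCResult(float("nan"), float("nan"), float("nan"),
                         label_model, log_transform, "undefined", n)
    icc = (msr - mse) / denom

    alpha = 1 - confidence
    if mse == 0 and msc == 0:
        # perfect agreement: degenerate interval
        ci_low = ci_high = icc
    else:
        r = icc
        one_minus = max(1 - r, 1e-15)
        a = k * r / (n * one_minus)
        b = 1 + k * r * (n - 1) / (n * one_minus)
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else float("inf")
        f_u = _stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = _stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
    return ICCResult(
        icc=float(icc),
        ci_low=float(min(ci_low, icc)),
        ci_high=float(max(ci_high, icc)),
        model=label_model,
        log_transformed=log_transform,
        label=_band(float(icc), _CICCHETTI_BANDS),
        n=n,
    )


def icc_consistency(
    manual_durations: Sequence[float],
    auto_durations: Sequence[float],
    log_transform: bool = True,
) -> float:
    """Consistency ICC(C,1); ignores systematic offsets between methods."""
    manual = np.asarray(manual_durations, dtype=float)
    auto = np.asarray(auto_durations, dtype=float)
    if log_transform:
        manual, auto = np.log(manual), np.log(auto)
    x = np.column_stack([manual, auto])
    msr, _, mse = _two_way_anova(x)
    return float((msr - mse) / (msr + (2 - 1) * mse))


def bias_percentiles(
    manual_durations: Sequence[float],
    auto_durations: Sequence[float],
    window_s: int | None = None,
) -> BiasResult:
    """Median and 5th/95th percentiles of automated - manual differences.

    Percentiles use the linear-interpolation quantile definition.  When
    ``window_s`` is given, the result flags whether the 5th-95th percentile
    band lies within twice the sample window (the absolute-agreement
    criterion used for this method).
    """
    manual = np.asarray(manual_durations, dtype=float)
    auto = np.asarray(auto_durations, dtype=float)
    if manual.size != auto.size or manual.size == 0:
        raise ValueError("need equally many (>=1) manual and automated durations")
    diffs = auto - manual
    median = float(np.median(diffs))
    p5, p95 = (float(v) for v in np.percentile(diffs, [5, 95]))
    flag = None
    if window_s is not None:
        flag = bool(max(abs(p5), abs(p95)) < 2 * window_s)
    return BiasResult(median=median, p5=p5, p95=p95, n=manual.size,
                      within_two_windows=flag)


def evaluate(
    auto_masks: Mapping[str, np.ndarray],
    manual_masks: Mapping[str, np.ndarray],
    auto_periods: Mapping[str, Sequence] | None = None,
    manual_periods: Mapping[str, Sequence] | None = None,
    window_s: int = 9,
    icc_model: str = "mixed",
) -> AgreementReport:
    """Full criterion-validity report for one (or one pooled) match.

    Periods default to run-length segmentations of the masks.  Period
    matching is done within player and the matched pairs are pooled across
    players for ρ, ICC and the bias percentiles.
    """
    from .detector import segment_periods

    counts = confusion_counts(auto_masks, manual_masks)
    metrics = classification_metrics(counts)
    if auto_periods is None:
        auto_periods = {pid: segment_periods(np.asarray(m, bool), pid)
                        for pid, m in auto_masks.items()}
    if manual_periods is None:
        manual_periods = {pid: segment_periods(np.asarray(m, bool), pid)
                          for pid, m in manual_masks.items()}

    manual_d: list[float] = []
    auto_d: list[float] = []
    n_manual = n_auto = n_matched = 0
    for pid in manual_periods:
        m_list = list(manual_periods[pid])
        a_list = list(auto_periods.get(pid, []))
        n_manual += len(m_list)
        n_auto += len(a_list)
        pairs, _, _ = match_periods(m_list, a_list)
        n_matched += len(pairs)
        for (ms, me), (as_, ae) in pairs:
            manual_d.append(me - ms)
            auto_d.append(ae - as_)

    rho = icc = bias = None
    if n_matched >= 3:
        rho = spearman_rho(manual_d, auto_d)
    if n_matched >= 5:
        icc = icc_absolute_agreement(manual_d, auto_d, model=icc_model)
    if n_matched >= 1:
        bias = bias_percentiles(manual_d, auto_d, window_s=window_s)
    return AgreementReport(
        counts=counts,
        metrics=metrics,
        rho=rho,
        icc=icc,
        bias=bias,
        n_periods_manual=n_manual,
        n_periods_auto=n_auto,
        n_matched=n_matched,
        agreement_proportion=(counts.tp + counts.tn) / counts.total,
    )
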