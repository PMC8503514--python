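"""Criterion-validity statistics: confusion metrics, matching, rho, ICC, bias."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from liveplay.agreement import (
    BiasResult,
    ConfusionCounts,
    bias_percentiles,
    classification_metrics,
    confusion_counts,
    evaluate,
    icc_absolute_agreement,
    icc_consistency,
    match_periods,
    round_half_away,
    spearman_rho,
)


class TestConfusion:
    def test_identical_masks(self, rng):
        mask = rng.random(100) < 0.4
        c = confusion_counts({"a": mask}, {"a": mask})
        assert (c.tp, c.fn, c.fp, c.tn) == (mask.sum(), 0, 0, (~mask).sum())

    def test_manual_all_active_auto_all_inactive(self):
        c = confusion_counts(np.zeros(50, bool), np.ones(50, bool))
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 50, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_tally(self, seed):
        rng = np.random.default_rng(600 + seed)
        auto = {f"p{i}": rng.random(60) < 0.5 for i in range(4)}
        manual = {f"p{i}": rng.random(60) < 0.5 for i in range(4)}
        c = confusion_counts(auto, manual)
        tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for p in auto:
            for a, m in zip(auto[p], manual[p]):
                key = ("tp" if a else "fn") if m else ("fp" if a else "tn")
                tally[key] += 1
        assert (c.tp, c.fn, c.fp, c.tn) == tuple(tally[k] for k in ("tp", "fn", "fp", "tn"))
        assert c.total == 240

    def test_player_permutation_invariance(self, rng):
        auto = {f"p{i}": rng.random(40) < 0.5 for i in range(3)}
        manual = {f"p{i}": rng.random(40) < 0.5 for i in range(3)}
        swapped_auto = {"p1": auto["p0"], "p0": auto["p1"], "p2": auto["p2"]}
        swapped_manual = {"p1": manual["p0"], "p0": manual["p1"], "p2": manual["p2"]}
        assert confusion_counts(auto, manual) == confusion_counts(swapped_auto, swapped_manual)


class TestClassificationMetrics:
    def test_published_counts_reproduce_reported_percentages(self):
        m = classification_metrics(ConfusionCounts(23275, 3047, 2306, 75367)).rounded()
        assert m == {
            "accuracy_pct": 94.9,
            "misclassification_pct": 5.1,
            "precision_pct": 91.0,
            "sensitivity_pct": 88.4,
        }

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(10, 0, 0, 20))
        assert (m.accuracy_pct, m.misclassification_pct) == (100.0, 0.0)
        assert (m.precision_pct, m.sensitivity_pct) == (100.0, 100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_rational_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(700 + seed)
        tp, fn, fp, tn = (int(v) for v in rng.integers(1, 10000, 4))
        m = classification_metrics(ConfusionCounts(tp, fn, fp, tn))
        total = tp + fn + fp + tn
        assert m.accuracy_pct == pytest.approx(float(Fraction(tp + tn, total) * 100), abs=1e-12)
        assert m.precision_pct == pytest.approx(100 * tp / (tp + fp), abs=1e-12)
        assert m.sensitivity_pct == pytest.approx(100 * tp / (tp + fn), abs=1e-12)
        # exact complement, before rounding
        assert m.accuracy_pct + m.misclassification_pct == 100.0

    def test_undefined_precision_and_sensitivity(self):
        m = classification_metrics(ConfusionCounts(0, 0, 0, 10))
        assert math.isnan(m.precision_pct) and math.isnan(m.sensitivity_pct)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(90.95) == 91.0
        assert round_half_away(90.94) == 90.9
        assert round_half_away(-0.05) == -0.1


def brute_force_matching(manual, auto):
    """Exhaustive max-total-overlap injective assignment (small instances)."""

    def overlap(a, b):
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    best = 0
    n = len(manual)
    for k in range(min(n, len(auto)) + 1):
        for m_idx in itertools.combinations(range(n), k):
            for a_idx in itertools.permutations(range(len(auto)), k):
                tot = sum(overlap(manual[i], auto[j]) for i, j in zip(m_idx, a_idx)
                          if overlap(manual[i], auto[j]) > 0)
                best = max(best, tot)
    return best


def random_period_list(rng, n_max=8, horizon=200):
    cuts = np.sort(rng.choice(horizon, size=2 * int(rng.integers(1, n_max + 1)),
                              replace=False))
    return [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(len(cuts) // 2)]


class TestMatchPeriods:
    def test_identical_lists_match_one_to_one(self):
        periods = [(0, 30), (50, 90), (120, 200)]
        pairs, um, ua = match_periods(periods, periods)
        assert pairs == [(p, p) for p in periods]
        assert um == [] and ua == []

    def test_constructed_example(self):
        pairs, um, ua = match_periods([(10, 30)], [(12, 28), (40, 50)])
        assert pairs == [((10, 30), (12, 28))]
        assert um == [] and ua == [(40, 50)]

    def test_tie_broken_by_earliest(self):
        pairs, _, _ = match_periods([(10, 20)], [(5, 15), (15, 25)])
        assert pairs == [((10, 20), (5, 15))]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_assignment_on_jittered_instances(self, seed):
        """On detector-like instances (boundary jitter, no splits/merges)
        the greedy pairing attains the exhaustive max-overlap optimum."""
        rng = np.random.default_rng(800 + seed)
        manual = []
        t = int(rng.integers(0, 20))
        for _ in range(int(rng.integers(1, 8))):
            d = int(rng.integers(15, 60))
            manual.append((t, t + d))
            t += d + int(rng.integers(12, 40))
        auto = []
        for s, e in manual:
            if rng.random() < 0.15:
                continue  # missed period
            s2 = max(0, s + int(rng.integers(-5, 6)))
            e2 = max(s2 + 1, e + int(rng.integers(-5, 6)))
            auto.append((s2, e2))

        def overlap(a, b):
            return max(0, min(a[1], b[1]) - max(a[0], b[0]))

        pairs, _, _ = match_periods(manual, auto)
        greedy_total = sum(overlap(m, a) for m, a in pairs)
        assert greedy_total == brute_force_matching(manual, auto)

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_bounded_by_optimal_on_arbitrary_instances(self, seed):
        rng = np.random.default_rng(850 + seed)
        manual = random_period_list(rng, n_max=6)
        auto = random_period_list(rng, n_max=6)

        def overlap(a, b):
            return max(0, min(a[1], b[1]) - max(a[0], b[0]))

        pairs, _, _ = match_periods(manual, auto)
        greedy_total = sum(overlap(m, a) for m, a in pairs)
        assert all(overlap(m, a) > 0 for m, a in pairs)
        assert greedy_total <= brute_force_matching(manual, auto)


class TestSpearman:
    def test_monotone_is_one(self):
        r = spearman_rho([1, 5, 9, 20], [2, 6, 30, 31])
        assert r.rho == pytest.approx(1.0)
        assert r.label == "nearly perfect"

    def test_reversed_is_minus_one(self):
        assert spearman_rho([1, 2, 3], [9, 5, 1]).rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(900 + seed)
        x = rng.integers(1, 50, 20).astype(float)  # integer durations -> ties
        y = x + rng.normal(0, 5, 20)

        def average_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
                i = j
            return ranks

        rx, ry = average_ranks(x), average_ranks(y)
        expected = float(
            np.sum((rx - rx.mean()) * (ry - ry.mean()))
            / np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
        )
        assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            r = spearman_rho([5, 5, 5], [1, 2, 3])
        assert math.isnan(r.rho)


def anova_icc_oracle(x, y):
    """ICC(A,1) from explicitly accumulated sums of squares."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.sum() / (n * k)
    ss_rows = sum(k * (np.mean(data[i]) - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (np.mean(data[:, j]) - grand) ** 2 for j in range(k))
    ss_total = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_give_one(self):
        d = [10.0, 20, 30, 40, 50, 60]
        r = icc_absolute_agreement(d, d)
        assert r.icc == pytest.approx(1.0)
        assert r.label == "excellent"

    def test_offset_penalised_by_absolute_agreement(self, rng):
        d = rng.uniform(10, 100, 20)
        shifted = d * 5  # constant shift after log transform
        r = icc_absolute_agreement(d, shifted, log_transform=True)
        c = icc_consistency(d, shifted, log_transform=True)
        assert c == pytest.approx(1.0)
        assert r.icc < 0.9  # offsets penalised

    def test_absolute_leq_consistency_under_systematic_offset(self, rng):
        """With a systematic between-method offset (rater variance above the
        residual), absolute agreement can only be the stricter criterion."""
        for _ in range(10):
            x = rng.uniform(5, 120, 15)
            y = x * 1.6 * np.exp(rng.normal(0.0, 0.1, 15))
            r = icc_absolute_agreement(x, y)
            assert r.icc <= icc_consistency(x, y) + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_anova_from_scratch_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        x = rng.uniform(5, 120, 20)
        y = x * np.exp(rng.normal(0, 0.2, 20))
        r = icc_absolute_agreement(x, y, log_transform=True)
        assert r.icc == pytest.approx(
            anova_icc_oracle(np.log(x), np.log(y)), abs=1e-10
        )
        assert r.ci_low <= r.icc <= r.ci_high

    @pytest.mark.parametrize("seed", range(5))
    def test_reference_implementation_cross_check(self, seed):
        """Point estimate and 95% CI agree with pingouin's ICC2."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1100 + seed)
        x = np.log(rng.uniform(5, 120, 25))
        y = x + rng.normal(0, 0.3, 25)
        frame = pd.DataFrame({
            "targets": np.repeat(np.arange(25), 2),
            "raters": np.tile(["m", "a"], 25),
            "score": np.column_stack([x, y]).ravel(),
        })
        ref = pingouin.intraclass_corr(frame, targets="targets", raters="raters",
                                       ratings="score")
        ref = ref.set_index("Type")
        row = ref.loc[[t for t in ref.index if "A,1" in t][0]]
        ci_col = [c for c in ref.columns if c.startswith("CI95")][0]
        r = icc_absolute_agreement(x, y, log_transform=False)
        assert r.icc == pytest.approx(row["ICC"], abs=1e-8)
        # pingouin reports the CI rounded to two decimals
        assert r.ci_low == pytest.approx(row[ci_col][0], abs=0.006)
        assert r.ci_high == pytest.approx(row[ci_col][1], abs=0.006)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            r = icc_absolute_agreement([5.0] * 6, [5.0] * 6)
        assert math.isnan(r.icc)

    def test_log_transform_requires_durations_geq_one(self):
        with pytest.raises(ValueError, match="log"):
            icc_absolute_agreement([0.5, 2, 3, 4, 5], [1, 2, 3, 4, 5])


class TestBiasPercentiles:
    def test_identical_durations(self):
        r = bias_percentiles([10, 20, 30], [10, 20, 30], window_s=9)
        assert (r.median, r.p5, r.p95) == (0.0, 0.0, 0.0)
        assert r.within_two_windows is True

    def test_median_of_small_example(self):
        manual = np.zeros(5)
        auto = np.array([-5.0, -1, 0, 2, 4])
        assert bias_percentiles(manual, auto).median == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_sorted_interpolation_oracle(self, seed):
        rng = np.random.default_rng(1200 + seed)
        diffs = rng.normal(0, 10, 200)
        r = bias_percentiles(np.zeros(200), diffs)

        def quantile(v, q):
            v = np.sort(v)
            pos = q * (len(v) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        assert r.p5 == pytest.approx(quantile(diffs, 0.05), abs=1e-10)
        assert r.p95 == pytest.approx(quantile(diffs, 0.95), abs=1e-10)
        assert r.median == pytest.approx(quantile(diffs, 0.5), abs=1e-10)

    def test_two_window_flag(self):
        r = bias_percentiles(np.zeros(100), np.full(100, 19.0), window_s=9)
        assert r.within_two_windows is False  # 19 s >= 2 * 9 s


class TestEvaluate:
    def test_perfect_agreement_fixed_point(self, rng):
        masks = {f"p{i}": rng.random(500) < 0.4 for i in range(5)}
        # guarantee enough periods for the period-level statistics
        masks["p0"][:] = False
        masks["p0"][10:40] = masks["p0"][60:90] = masks["p0"][120:180] = True
        report = evaluate(masks, masks, window_s=9)
        assert report.metrics.accuracy_pct == 100.0
        assert report.rho.rho == pytest.approx(1.0)
        assert report.icc.icc == pytest.approx(1.0)
        assert (report.bias.median, report.bias.p5, report.bias.p95) == (0, 0, 0)
        assert report.n_matched == report.n_periods_manual == report.n_periods_auto

    def test_simulator_run_is_excellent(self, simulated_match):
        from liveplay.detector import DetectorParams, detect_live_play

        schedule, series, truth = simulated_match
        res = detect_live_play(series, DetectorParams(),
                               match_end_s=schedule.match_end_s,
                               exclusions=[schedule.half_time])
        report = evaluate(res.player_masks, truth)
        assert report.metrics.accuracy_pct >= 90.0
        assert report.icc.label == "excellent"
        assert report.bias.within_two_windows

    def test_order_invariance_of_period_statistics(self, rng):
        manual = rng.uniform(5, 100, 30)
        auto = manual * np.exp(rng.normal(0, 0.1, 30))
        perm = rng.permutation(30)
        a = icc_absolute_agreement(manual, auto)
        b = icc_absolute_agreement(manual[perm], auto[perm])
        assert a.icc == pytest.approx(b.icc, abs=1e-12)
        assert spearman_rho(manual, auto).rho == pytest.approx(
            spearman_rho(manual[perm], auto[perm]).rho, abs=1e-12
        )
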