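"""Validation battery: CVs, accuracy, LOQ, recovery, ME, carryover,
hematocrit robustness, stability, and the aggregate report."""

import numpy as np
import pytest

from vamsquant.compartment import vams_from_serum
from vamsquant.panel import ThresholdConfig
from vamsquant.validation import (
    LOQ_NOT_REACHED,
    LoqLevel,
    ValidationError,
    accuracy,
    accuracy_passes,
    carryover,
    estimate_loq,
    hct_robustness,
    imprecision,
    matrix_effect,
    recovery,
    stability_assess,
    validation_report,
)


class TestImprecision:
    def test_degenerate_identical(self, thresholds):
        runs = {f"r{i}": [5.0] * 6 for i in range(3)}
        res = imprecision(runs, thresholds)
        assert all(cv == 0 for cv in res.intraday_cv_pct)
        assert res.interday_cv_pct == 0 and res.passed

    def test_hand_computed_cv(self, thresholds):
        res = imprecision({"r1": [9.0, 10.0, 11.0]}, thresholds)
        assert res.intraday_cv_pct[0] == pytest.approx(10.0)

    def test_zero_mean_errors(self, thresholds):
        with pytest.raises(ValidationError, match="zero mean"):
            imprecision({"r1": [1.0, -1.0]}, thresholds)

    def test_interday_sampling_distribution(self, thresholds):
        # Monte-Carlo oracle: intra 5% within-run noise plus a lognormal
        # 7% between-run effect pools to about sqrt(5^2+7^2) = 8.60%; the
        # target must sit inside the central 95% of the estimator's own
        # sampling distribution (3 runs x 6 replicates, 1000 batches)
        rng = np.random.default_rng(7)
        ests = []
        for _ in range(1000):
            runs = {}
            for r in range(3):
                shift = np.exp(rng.normal(0, 0.07))
                runs[f"r{r}"] = 10.0 * shift * (1 + rng.normal(0, 0.05, 6))
            ests.append(imprecision(runs, thresholds).interday_cv_pct)
        lo, hi = np.percentile(ests, [2.5, 97.5])
        assert lo <= np.sqrt(5**2 + 7**2) <= hi

    def test_anova_component_reported(self, thresholds):
        rng = np.random.default_rng(3)
        runs = {f"r{i}": 10 + rng.normal(0, 0.5, 6) for i in range(3)}
        res = imprecision(runs, thresholds, anova=True)
        assert res.interday_cv_anova_pct is not None
        assert res.interday_cv_anova_pct >= 0


class TestAccuracy:
    def test_examples(self, thresholds):
        assert accuracy([10, 10, 10], 10) == pytest.approx(100.0)
        assert accuracy([8.7, 8.7], 10) == pytest.approx(87.0)
        assert accuracy_passes(87.0, thresholds)
        assert accuracy([11.9], 10) == pytest.approx(119.0)
        assert not accuracy_passes(119.0, thresholds)

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            accuracy([1.0], 0.0)
        with pytest.raises(ValidationError):
            accuracy([], 10.0)


class TestEstimateLoq:
    LEVELS = [0.01, 0.02, 0.05, 0.1, 0.5]

    def _levels(self, cvs, snrs):
        return [
            LoqLevel(c, cv, s) for c, cv, s in zip(self.LEVELS, cvs, snrs)
        ]

    def test_all_pass_gives_lowest(self, thresholds):
        lv = self._levels([5] * 5, [20] * 5)
        assert estimate_loq(lv, thresholds) == 0.01

    def test_noisy_bottom_level_excluded(self, thresholds):
        lv = self._levels([35, 5, 5, 5, 5], [20] * 5)
        assert estimate_loq(lv, thresholds) == 0.02

    def test_monotone_closure(self, thresholds):
        # a passing low level below a failing mid level must not win
        lv = self._levels([5, 5, 35, 5, 5], [20] * 5)
        assert estimate_loq(lv, thresholds) == 0.1

    def test_sentinel_when_nothing_passes(self, thresholds):
        lv = self._levels([35] * 5, [20] * 5)
        assert estimate_loq(lv, thresholds) == LOQ_NOT_REACHED

    def test_monotone_in_snr(self, thresholds):
        base = self._levels([5] * 5, [2, 4, 8, 12, 20])
        better = self._levels([5] * 5, [20, 40, 80, 120, 200])
        assert estimate_loq(better, thresholds) <= estimate_loq(base, thresholds)

    def test_unsorted_levels_error(self, thresholds):
        lv = [LoqLevel(0.1, 5, 20), LoqLevel(0.01, 5, 20)]
        with pytest.raises(ValidationError, match="ascending"):
            estimate_loq(lv, thresholds)


class TestAreaRatios:
    def test_recovery(self):
        assert recovery([1.0, 1.0], [1.0, 1.0]) == pytest.approx(100.0)
        assert recovery([300, 320], [990, 1010]) == pytest.approx(31.0)
        assert recovery([840], [1000]) == pytest.approx(84.0)
        with pytest.raises(ValidationError):
            recovery([], [1.0])

    def test_matrix_effect(self):
        assert matrix_effect([2, 2], [2, 2]) == pytest.approx(100.0)
        assert matrix_effect([850], [1000]) == pytest.approx(85.0)
        assert matrix_effect([0.0], [1000]) == 0.0
        with pytest.raises(ValidationError):
            matrix_effect([1.0], [0.0])

    def test_carryover(self, thresholds):
        assert carryover(0.0, 100.0) == 0.0
        assert carryover(0.5, 10000.0) == pytest.approx(0.005)
        assert carryover(0.5, 10000.0) <= thresholds.carryover_max_pct
        assert carryover(2.0, 10000.0) == pytest.approx(0.02)
        assert carryover(2.0, 10000.0) > thresholds.carryover_max_pct
        with pytest.raises(ValidationError):
            carryover(1.0, 0.0)

    def test_common_rescaling_invariance(self):
        pre, post = [300.0, 320.0], [990.0, 1010.0]
        for s in (0.5, 40.0):
            assert recovery([x * s for x in pre], [x * s for x in post]) == (
                pytest.approx(recovery(pre, post))
            )
            assert carryover(2.0 * s, 1e4 * s) == pytest.approx(
                carryover(2.0, 1e4)
            )


class TestHctRobustness:
    def test_flat_series_full_range(self, thresholds):
        measured = [(h, 5.0) for h in (0.3, 0.4, 0.5, 0.6, 0.7)]
        res = hct_robustness(measured, 0.4, thresholds)
        assert all(d == 0 for _, d in res.deviations)
        assert res.pass_range == (0.3, 0.7)

    def test_compartment_model_series(self, panel, thresholds):
        # measured concentrations following the 4:1 mixture model must
        # pass at least over [0.30, 0.50] relative to the 0.40 reference
        grid = np.round(np.arange(0.30, 0.71, 0.05), 2)
        measured = [
            (h, vams_from_serum(2.0, h, panel["T"])) for h in grid
        ]
        res = hct_robustness(measured, 0.40, thresholds)
        lo, hi = res.pass_range
        assert lo <= 0.30 and hi >= 0.50

    def test_single_reference_point(self, thresholds):
        res = hct_robustness([(0.4, 5.0)], 0.4, thresholds)
        assert res.pass_range == (0.4, 0.4)

    def test_missing_reference_errors(self, thresholds):
        with pytest.raises(ValidationError, match="reference"):
            hct_robustness([(0.5, 5.0), (0.6, 5.0)], 0.4, thresholds)


class TestStability:
    SCHEDULE = (0, 1, 3, 5, 7, 14, 28)

    def test_flat_series_beyond_28(self, thresholds):
        series = [(d, 10.0) for d in self.SCHEDULE]
        res = stability_assess(series, thresholds, temp_c=-18.0)
        assert res.pass_28d and res.stable_days_label == ">28"

    def test_degrading_series_stops_at_14(self, thresholds):
        series = [(0, 10.0), (1, 9.9), (3, 9.8), (5, 9.6), (7, 9.3),
                  (14, 8.6), (28, 8.2)]  # −14% at d14, −18% at d28
        res = stability_assess(series, thresholds, temp_c=20.0)
        assert res.stable_days == 14 and not res.pass_28d

    def test_immediate_failure(self, thresholds):
        res = stability_assess([(0, 10.0), (1, 8.0)], thresholds)
        assert res.stable_days == 0

    def test_missing_day0_errors(self, thresholds):
        with pytest.raises(ValidationError, match="day 0"):
            stability_assess([(1, 10.0)], thresholds)

    def test_monotone_in_tolerance(self):
        series = [(0, 10.0), (7, 9.0), (14, 8.4), (28, 7.0)]
        days = [
            stability_assess(
                series, ThresholdConfig(stability_tol_pct=tol)
            ).stable_days
            for tol in (5.0, 10.0, 20.0, 40.0)
        ]
        assert days == sorted(days)


class TestValidationReportAggregation:
    def test_all_passing(self, thresholds):
        prec = imprecision({"r1": [10, 10.1], "r2": [9.9, 10]}, thresholds)
        rep = validation_report(
            "T", thresholds, precision=prec, accuracy_pct=98.0,
            loq_est=0.02, loq_claimed=0.02, carryover_pct=0.001,
            stability=[stability_assess([(0, 1.0), (28, 0.99)], thresholds,
                                        temp_c=-18.0)],
            linearity_ok=True,
        )
        assert rep.overall_pass
        assert "selectivity" in rep.not_assessed

    def test_single_failing_cv_flags_report(self, thresholds):
        prec = imprecision({"r1": [10, 13.0], "r2": [9.9, 10]}, thresholds)
        assert max(prec.intraday_cv_pct) > thresholds.cv_max_pct
        rep = validation_report("T", thresholds, precision=prec,
                                accuracy_pct=100.0, linearity_ok=True)
        assert not rep.overall_pass and not rep.precision.passed

    def test_missing_components_excluded_with_warning(self, thresholds):
        rep = validation_report("T", thresholds, accuracy_pct=100.0)
        assert rep.overall_pass  # only accuracy assessed, and it passes
        assert set(rep.not_assessed) >= {"precision", "loq", "carryover"}
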