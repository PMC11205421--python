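"""Forward measurement model and study generators."""

import math

import numpy as np
import pandas as pd
import pytest

from vamsquant.calibration import area_ratio
from vamsquant.io import paired_table_from_study, quantify_peak_table, compare_paired
from vamsquant.synthdata import (
    ISTD_AREA,
    CohortModel,
    DegradationModel,
    NoiseModel,
    ValidationDesign,
    simulate_cohort,
    simulate_measurement,
    simulate_paired_study,
    simulate_validation_batch,
)
from vamsquant.validation import stability_assess, validate_batch


class TestNoiseModel:
    def test_defaults_cover_panel(self, panel):
        noise = NoiseModel.default()
        for code in panel:
            assert noise.intraday_cv_pct[code] > 0
            assert 0 < noise.recovery_frac[code] <= 1
        # testosterone figures of merit
        assert noise.intraday_cv_pct["T"] == 2.0
        assert noise.interday_cv_pct["T"] == 3.0
        assert noise.recovery_frac["T"] == pytest.approx(0.84)
        assert noise.matrix_effect_frac["T"] == pytest.approx(0.92)

    def test_between_run_component(self):
        noise = NoiseModel.default()
        # pooled interday CV decomposes as sqrt(intra^2 + between^2)
        assert noise.between_run_sd("T") == pytest.approx(
            math.sqrt(3**2 - 2**2) / 100
        )
        assert noise.between_run_sd("A4") == pytest.approx(
            math.sqrt(7**2 - 5**2) / 100
        )

    def test_validation(self):
        with pytest.raises(ValueError, match="recovery"):
            NoiseModel({"T": 1}, {"T": 1}, {"T": 1.5}, {"T": 0.9})


class TestDegradation:
    def test_default_rates_match_stated_endpoints(self, thresholds):
        deg = DegradationModel.default()
        # frozen: no loss for anyone
        assert all(deg.rate(c, -18.0) == 0 for c in ("T", "F", "A4"))
        # cortisol at room temperature: ~86% at day 14, < 85% at day 28
        assert deg.retention("F", 20.0, 14) == pytest.approx(0.86)
        assert deg.retention("F", 20.0, 28) < 0.85
        # everyone else retains at least 85% through day 28
        for c in ("T", "A4", "T4"):
            assert deg.retention(c, 20.0, 28) >= 0.85

    def test_model_curve_classification(self, thresholds):
        # the scheduled-day concentration-time curve of the degradation
        # model itself classifies cortisol as 14-day stable warm and
        # beyond-28-day stable frozen
        deg = DegradationModel.default()
        days = (0, 1, 3, 5, 7, 14, 28)
        warm = [(d, 10.0 * deg.retention("F", 20.0, d)) for d in days]
        cold = [(d, 10.0 * deg.retention("F", -18.0, d)) for d in days]
        assert stability_assess(warm, thresholds).stable_days == 14
        assert stability_assess(cold, thresholds).pass_28d

    def test_explicit_endpoint_rate(self):
        # retention constructed from e^{-28k} = 0.80
        k = -math.log(0.80) / 28
        deg = DegradationModel({("T", 20.0): k})
        assert deg.retention("T", 20.0, 28) == pytest.approx(0.80)


class TestForwardModel:
    def test_noiseless_composition(self, panel):
        # serum 1 ng/mL at Hct 0.40 with a 4:1 ratio mixes to 0.7 on the
        # tip; the area ratio is slope x (0.7 + residual) x recovery x ME
        noise = NoiseModel.noiseless()
        rng = np.random.default_rng(0)
        m = simulate_measurement(1.0, 0.4, panel["T"], noise, rng)
        expected = (
            noise.response_slope * (0.7 + panel["T"].blank_residual)
            * noise.recovery_frac["T"] * noise.matrix_effect_frac["T"]
        )
        assert area_ratio(m) == pytest.approx(expected, rel=1e-12)
        assert m.istd_area == ISTD_AREA

    def test_determinism(self, panel):
        a = simulate_validation_batch(panel, seed=5)
        b = simulate_validation_batch(panel, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_validation_batch(panel, seed=6)
        assert not a["analyte_area"].equals(c["analyte_area"])

    def test_design_completeness(self, panel):
        df = simulate_validation_batch(panel, seed=0)
        purposes = set(df["purpose"])
        assert purposes >= {
            "calibration", "precision", "loq", "recovery_pre",
            "recovery_post", "me_matrix", "me_solvent", "carryover_high",
            "carryover_blank", "hct", "stability",
        }
        prec_t = df[(df.analyte == "T") & (df.purpose == "precision")]
        assert prec_t.groupby("run_id").size().tolist() == [6, 6, 6]

    def test_incomplete_design_rejected(self):
        with pytest.raises(ValueError, match="precision design"):
            ValidationDesign(precision_runs=1)
        with pytest.raises(ValueError, match="0.40 reference"):
            ValidationDesign(hct_grid=(0.3, 0.5))


class TestNoiseFreePipeline:
    def test_full_chain_returns_truth(self, panel, thresholds):
        # simulate -> calibrate -> quantify -> compartment-correct must be
        # the identity without noise, for every analyte
        noise = NoiseModel.noiseless()
        serum, vams, truth = simulate_paired_study(
            8, noise=noise, panel=panel, seed=3, n_male=1
        )
        paired = paired_table_from_study(serum, vams, panel, thresholds)
        merged = paired.merge(truth, on=["subject_id", "analyte"])
        rel = np.abs(merged["c_vams"] - merged["true_serum"]) / merged["true_serum"]
        assert float(rel.max()) <= 1e-6
        # and the serum arm equals truth exactly under zero noise
        rel_s = np.abs(merged["c_serum"] - merged["true_serum"]) / merged["true_serum"]
        assert float(rel_s.max()) <= 1e-12

    def test_zero_noise_agreement_bias_is_zero(self, panel, thresholds):
        noise = NoiseModel.noiseless()
        serum, vams, _ = simulate_paired_study(
            6, noise=noise, panel=panel, seed=9, n_male=0
        )
        paired = paired_table_from_study(serum, vams, panel, thresholds)
        results, _ = compare_paired(paired)
        for res in results.values():
            assert abs(res.bias) <= 1e-9


class TestValidationBatchEndToEnd:
    def test_default_batch_meets_all_criteria(self, panel, thresholds):
        reports = validate_batch(
            simulate_validation_batch(panel, seed=0), panel, thresholds
        )
        assert set(reports) == set(panel)
        for code, rep in reports.items():
            assert rep.overall_pass, (code, rep.not_assessed)
        # storage pattern: cortisol limited warm, everyone fine frozen
        f_stab = {s.temp_c: s for s in reports["F"].stability}
        assert f_stab[-18.0].pass_28d
        assert f_stab[20.0].stable_days in (7, 14)
        for code in set(panel) - {"F"}:
            for s in reports[code].stability:
                assert s.pass_28d

    def test_built_to_fail_precision(self, panel, thresholds):
        noise = NoiseModel.default()
        noisy = NoiseModel(
            intraday_cv_pct={c: 30.0 for c in panel},
            interday_cv_pct={c: 30.0 for c in panel},
            recovery_frac=noise.recovery_frac,
            matrix_effect_frac=noise.matrix_effect_frac,
        )
        design = ValidationDesign()
        reports = validate_batch(
            simulate_validation_batch(panel, noisy, design=design, seed=0),
            panel, thresholds,
        )
        assert not reports["T"].precision.passed


class TestPairedStudy:
    def test_null_rejection_rate_in_precomputed_bounds(self, panel, thresholds):
        # all-female null study, exact calibration: the paired t-test is
        # mildly conservative because the differences scale with each
        # subject's concentration (true rate ~0.038 from a 1000-seed
        # oracle; bounds are that estimate +- 3 binomial Ses at 200 seeds)
        rej = 0
        n_seeds = 200
        for s in range(n_seeds):
            serum, vams, _ = simulate_paired_study(
                11, panel=panel, seed=s, n_male=0, exact_calibration=True
            )
            paired = paired_table_from_study(serum, vams, panel, thresholds)
            res, _ = compare_paired(paired[paired["analyte"] == "T"])
            rej += res["T"].paired_t_p < 0.05
        assert 0.0 <= rej / n_seeds <= 0.079

    def test_counts_and_sex_composition(self, panel):
        serum, vams, truth = simulate_paired_study(11, panel=panel, seed=1)
        assert truth["subject_id"].nunique() == 11
        assert (truth["sex"] == "male").groupby(truth["subject_id"]).any().sum() == 1
        # male subjects contribute no female-only hormones
        male_ids = truth.loc[truth.sex == "male", "subject_id"].unique()
        male_rows = truth[truth.subject_id.isin(male_ids)]
        assert not set(male_rows["analyte"]) & {"E2", "P4"}


class TestCohort:
    def test_cohort_composition_and_sensitivity(self, panel, thresholds):
        df = simulate_cohort(32, 18, panel=panel, seed=0)
        truth = df.attrs["truth"]
        assert truth["subject_id"].nunique() == 50
        male = truth[truth.sex == "male"]
        assert not set(male["analyte"]) & {"E2", "P4"}
        # testosterone must be quantifiable above its LOQ in every subject
        q = quantify_peak_table(df, panel, thresholds)
        t = q[q["analyte"] == "T"]
        assert len(t) == 50
        assert (t["conc_vams"] > panel["T"].loq).all()

    def test_empty_cohort(self, panel):
        df = simulate_cohort(0, 0, panel=panel, seed=0)
        assert df.empty


class TestCohortModel:
    def test_lognormal_moments(self):
        cohort = CohortModel.default()
        rng = np.random.default_rng(0)
        draws = cohort.draw_serum("T", "male", rng, 40000)
        assert np.mean(draws) == pytest.approx(5.2, rel=0.03)
        assert np.std(draws) == pytest.approx(1.4, rel=0.05)

    def test_hct_bounds_and_sex_shift(self):
        cohort = CohortModel.default()
        rng = np.random.default_rng(0)
        f = cohort.draw_hct("female", rng, 2000)
        m = cohort.draw_hct("male", rng, 2000)
        assert f.min() >= 0.30 and m.max() <= 0.55
        assert np.mean(m) > np.mean(f)
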