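"""Seeded simulator of every input the pipeline consumes.

The forward measurement model composes, in the order a real VAMS sample
would experience them:

1. biology — lognormal between-subject serum concentrations and a
   sex-specific truncated-normal hematocrit;
2. the blood-compartment mixture — total tip concentration from serum
   level, hematocrit and the analyte's serum/RBC partition, plus the trace
   endogenous residual of the surrogate blank matrix;
3. storage — first-order degradation at the storage temperature;
4. sample preparation and detection — extraction recovery and matrix-effect
   attenuation of the analyte signal (the ISTD area is held at its nominal
   value, so both appear in the analyte/ISTD ratio), a shared lognormal
   between-run effect, and multiplicative within-run noise.

Noise magnitudes default to the validated assay's figures of merit: the
``interday_cv_pct`` entries are the *pooled* interday CVs the generator
should reproduce, so the between-run component is drawn with
sd = sqrt(interday² − intraday²). SNR is simulated deterministically as
conc/LOQ × snr_at_loq (it is an input column downstream, never derived
from areas).

All generators are deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import compartment
from .panel import AnalyteSpec, Panel, default_panel
from .calibration import PeakMeasurement, Role

__all__ = [
    "ISTD_AREA",
    "NoiseModel",
    "DegradationModel",
    "CohortModel",
    "ValidationDesign",
    "PEAK_COLUMNS",
    "simulate_measurement",
    "simulate_validation_batch",
    "simulate_paired_study",
    "simulate_cohort",
]

#: Nominal ISTD peak area (arbitrary units); constant by construction.
ISTD_AREA = 1.0e5

#: Column order of the long-format peak table (CSV schema).
PEAK_COLUMNS = [
    "sample_id", "analyte", "role", "run_id", "day_index",
    "analyte_area", "istd_area", "snr", "nominal_conc", "hct",
    "storage_days", "storage_temp_c",
]

# Assay figures of merit per analyte:
# (intraday CV %, interday CV % (pooled), recovery %, matrix effect %)
_ASSAY_CV_TABLE: Dict[str, Tuple[float, float, float, float]] = {
    "A4":     (5.0, 7.0, 81.0, 91.0),
    "F":      (4.0, 7.0, 66.0, 85.0),
    "DHEA-S": (4.0, 10.0, 63.0, 95.0),
    "P4":     (8.0, 12.0, 77.0, 88.0),
    "T":      (2.0, 3.0, 84.0, 92.0),
    "T3":     (3.0, 10.0, 31.0, 87.0),
    "T4":     (5.0, 9.0, 27.0, 89.0),
    "E2":     (3.0, 4.0, 87.0, 90.0),
}

# Between-subject serum concentration (arithmetic mean, SD) ng/mL by sex.
_COHORT_TABLE: Dict[str, Dict[str, Optional[Tuple[float, float]]]] = {
    "A4":     {"male": (1.2, 0.5), "female": (1.7, 0.7)},
    "F":      {"male": (136.3, 23.5), "female": (136.5, 39.5)},
    "DHEA-S": {"male": (1826.7, 843.8), "female": (1535.8, 728.4)},
    "P4":     {"male": None, "female": (4.0, 4.7)},
    "T":      {"male": (5.2, 1.4), "female": (0.2, 0.1)},
    "T3":     {"male": (0.59, 0.2), "female": (0.56, 0.1)},
    "T4":     {"male": (37.3, 12.6), "female": (36.3, 7.6)},
    "E2":     {"male": None, "female": (0.07, 0.07)},
}

_FEMALE_ONLY = ("P4", "E2")


def _require_codes(mapping: Mapping[str, float], codes: Sequence[str], name: str):
    missing = [c for c in codes if c not in mapping]
    if missing:
        raise ValueError(f"{name} missing analyte(s): {missing}")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement-noise and attenuation parameters.

    ``interday_cv_pct`` is the pooled interday CV target; the generator
    derives the between-run component from it. ``recovery_frac`` in (0, 1],
    ``matrix_effect_frac`` in (0, 2). ``carryover_frac`` is the residual
    signal fraction a blank inherits from the preceding high injection.
    """

    intraday_cv_pct: Mapping[str, float]
    interday_cv_pct: Mapping[str, float]
    recovery_frac: Mapping[str, float]
    matrix_effect_frac: Mapping[str, float]
    snr_at_loq: float = 10.0
    carryover_frac: float = 5e-5
    response_slope: float = 0.02   # area ratio per (ng/mL)

    def __post_init__(self) -> None:
        for name in ("intraday_cv_pct", "interday_cv_pct"):
            for code, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{code}] must be >= 0")
        for code, v in self.recovery_frac.items():
            if not 0 < v <= 1:
                raise ValueError(f"recovery_frac[{code}] must be in (0, 1]")
        for code, v in self.matrix_effect_frac.items():
            if not 0 < v < 2:
                raise ValueError(f"matrix_effect_frac[{code}] must be in (0, 2)")
        if self.snr_at_loq <= 0 or self.response_slope <= 0:
            raise ValueError("snr_at_loq and response_slope must be > 0")
        if self.carryover_frac < 0:
            raise ValueError("carryover_frac must be >= 0")

    @classmethod
    def default(cls) -> "NoiseModel":
        """Noise at the validated assay's per-analyte magnitudes."""
        return cls(
            intraday_cv_pct={c: v[0] for c, v in _ASSAY_CV_TABLE.items()},
            interday_cv_pct={c: v[1] for c, v in _ASSAY_CV_TABLE.items()},
            recovery_frac={c: v[2] / 100 for c, v in _ASSAY_CV_TABLE.items()},
            matrix_effect_frac={c: v[3] / 100 for c, v in _ASSAY_CV_TABLE.items()},
        )

    @classmethod
    def noiseless(cls, codes: Sequence[str] = tuple(_ASSAY_CV_TABLE)) -> "NoiseModel":
        """Zero random noise; recovery and matrix effect kept at defaults."""
        return cls(
            intraday_cv_pct={c: 0.0 for c in codes},
            interday_cv_pct={c: 0.0 for c in codes},
            recovery_frac={c: _ASSAY_CV_TABLE[c][2] / 100 for c in codes},
            matrix_effect_frac={c: _ASSAY_CV_TABLE[c][3] / 100 for c in codes},
            carryover_frac=0.0,
        )

    def intraday_sd(self, code: str) -> float:
        return self.intraday_cv_pct[code] / 100.0

    def between_run_sd(self, code: str) -> float:
        intra = self.intraday_cv_pct[code]
        inter = self.interday_cv_pct[code]
        return math.sqrt(max(inter**2 - intra**2, 0.0)) / 100.0


@dataclass(frozen=True)
class DegradationModel:
    """First-order storage loss: retention(d) = exp(−k·d), k per (analyte, °C)."""

    rates: Mapping[Tuple[str, float], float]  # (code, temp °C) -> k day⁻¹

    def __post_init__(self) -> None:
        for key, k in self.rates.items():
            if k < 0:
                raise ValueError(f"rate k{key} must be >= 0")

    @classmethod
    def default(cls, codes: Sequence[str] = tuple(_ASSAY_CV_TABLE)) -> "DegradationModel":
        """No loss frozen; at 20 °C slow loss (95% at day 28) except cortisol,
        parameterized to ≈86% retention at day 14 (below 85% by day 28)."""
        k_slow = -math.log(0.95) / 28.0
        k_f = -math.log(0.86) / 14.0
        rates = {}
        for c in codes:
            rates[(c, -18.0)] = 0.0
            rates[(c, 20.0)] = k_f if c == "F" else k_slow
        return cls(rates)

    @classmethod
    def none(cls, codes: Sequence[str] = tuple(_ASSAY_CV_TABLE)) -> "DegradationModel":
        return cls({(c, t): 0.0 for c in codes for t in (-18.0, 20.0)})

    def rate(self, code: str, temp_c: float) -> float:
        try:
            return self.rates[(code, float(temp_c))]
        except KeyError:
            raise KeyError(f"no degradation rate for ({code}, {temp_c} °C)")

    def retention(self, code: str, temp_c: float, days: float) -> float:
        return math.exp(-self.rate(code, temp_c) * days)


@dataclass(frozen=True)
class CohortModel:
    """Between-subject biology: lognormal serum levels, truncated-normal Hct."""

    serum_stats: Mapping[str, Mapping[str, Optional[Tuple[float, float]]]]
    hct_mean: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.40, "male": 0.47}
    )
    hct_sd: float = 0.02
    hct_bounds: Tuple[float, float] = (0.30, 0.55)

    @classmethod
    def default(cls) -> "CohortModel":
        return cls(serum_stats=_COHORT_TABLE)

    def codes_for(self, sex: str) -> Tuple[str, ...]:
        return tuple(
            c for c, by_sex in self.serum_stats.items()
            if by_sex.get(sex) is not None
        )

    def draw_serum(self, code: str, sex: str, rng: np.random.Generator,
                   n: int = 1) -> np.ndarray:
        ms = self.serum_stats[code].get(sex)
        if ms is None:
            raise ValueError(f"{code} is not modelled for sex {sex!r}")
        m, s = ms
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)

    def draw_hct(self, sex: str, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        mean = self.hct_mean[sex]
        lo, hi = self.hct_bounds
        a, b = (lo - mean) / self.hct_sd, (hi - mean) / self.hct_sd
        return stats.truncnorm.rvs(
            a, b, loc=mean, scale=self.hct_sd, size=n, random_state=rng
        )


# --- forward model ----------------------------------------------------------

def _signal_ratio(
    conc: float,
    code: str,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    run_effect: float = 0.0,
    with_recovery: bool = True,
    with_matrix: bool = True,
) -> float:
    """Expected analyte/ISTD area ratio of a given analyte concentration,
    with one draw of within-run noise. The ratio cannot go negative."""
    base = noise.response_slope * conc
    if with_recovery:
        base *= noise.recovery_frac[code]
    if with_matrix:
        base *= noise.matrix_effect_frac[code]
    eps = rng.normal(0.0, noise.intraday_sd(code)) if noise.intraday_sd(code) else 0.0
    return max(base * math.exp(run_effect) * (1.0 + eps), 0.0)


def _measurement_from_conc(
    c_vams_total: float,
    spec: AnalyteSpec,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    sample_id: str,
    role: Role = Role.SAMPLE,
    run_id: str = "run1",
    day_index: int = 0,
    run_effect: float = 0.0,
    nominal_conc: Optional[float] = None,
    hct: Optional[float] = None,
    storage_days: Optional[int] = None,
    storage_temp_c: Optional[float] = None,
    deg: Optional[DegradationModel] = None,
) -> PeakMeasurement:
    """Measurement of a sample whose total VAMS-tip concentration is known
    (calibrators, QCs, blanks). Applies storage degradation when given."""
    conc = c_vams_total
    if deg is not None and storage_days:
        conc *= deg.retention(spec.short_code, storage_temp_c, storage_days)
    ratio = _signal_ratio(conc, spec.short_code, noise, rng, run_effect=run_effect)
    snr = conc / spec.loq * noise.snr_at_loq
    return PeakMeasurement(
        sample_id=sample_id,
        analyte=spec.short_code,
        role=role,
        analyte_area=ratio * ISTD_AREA,
        istd_area=ISTD_AREA,
        run_id=run_id,
        day_index=day_index,
        snr=snr,
        nominal_conc=nominal_conc,
        hct=hct,
        storage_days=storage_days,
        storage_temp_c=storage_temp_c,
    )


def simulate_measurement(
    true_serum: float,
    hct: float,
    spec: AnalyteSpec,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    sample_id: str = "s1",
    run_id: str = "run1",
    day_index: int = 0,
    storage: Tuple[int, float] = (0, -18.0),
    deg: Optional[DegradationModel] = None,
    run_effect: Optional[float] = None,
) -> PeakMeasurement:
    """One VAMS measurement of a subject sample via the full forward model.

    The tip concentration is the compartment mixture of ``true_serum`` at
    ``hct`` plus the blank-matrix endogenous residual; storage degradation,
    recovery/matrix-effect attenuation, a between-run effect (drawn from
    the noise model unless supplied) and within-run noise follow.
    """
    c_vams = compartment.vams_from_serum(true_serum, hct, spec)
    c_total = c_vams + spec.blank_residual
    if run_effect is None:
        sd = noise.between_run_sd(spec.short_code)
        run_effect = rng.normal(0.0, sd) if sd else 0.0
    days, temp = storage
    return _measurement_from_conc(
        c_total, spec, noise, rng,
        sample_id=sample_id, role=Role.SAMPLE, run_id=run_id,
        day_index=day_index, run_effect=run_effect, hct=hct,
        storage_days=days, storage_temp_c=temp, deg=deg,
    )


def _rows(ms: Sequence[PeakMeasurement], purpose: str) -> list:
    out = []
    for m in ms:
        out.append({
            "sample_id": m.sample_id, "analyte": m.analyte,
            "role": m.role.value, "run_id": m.run_id,
            "day_index": m.day_index, "analyte_area": m.analyte_area,
            "istd_area": m.istd_area, "snr": m.snr,
            "nominal_conc": m.nominal_conc, "hct": m.hct,
            "storage_days": m.storage_days,
            "storage_temp_c": m.storage_temp_c, "purpose": purpose,
        })
    return out


def cal_levels(spec: AnalyteSpec, n_levels: int = 6) -> np.ndarray:
    """Default calibrator nominals: geometric levels spanning the working
    range (VAMS-concentration scale)."""
    low, high = spec.calibration_range
    return np.geomspace(low, high, n_levels)


def qc_conc(spec: AnalyteSpec) -> float:
    """Mid-working-range QC (QC II) concentration, VAMS scale."""
    low, high = spec.calibration_range
    return math.sqrt(low * high)


@dataclass(frozen=True)
class ValidationDesign:
    """Replicate design of a full validation batch."""

    cal_levels: int = 6
    cal_blanks: int = 2
    precision_runs: int = 3
    precision_reps: int = 6
    loq_level_factors: Tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)  # × LOQ
    loq_reps: int = 6
    recovery_reps: int = 6
    recovery_conc: float = 20.0          # ng/mL (200 for DHEA-S)
    recovery_conc_dheas: float = 200.0
    me_reps: int = 4
    carryover_conc: float = 50.0         # ng/mL (200 for DHEA-S)
    carryover_conc_dheas: float = 200.0
    hct_grid: Tuple[float, ...] = (0.30, 0.35, 0.40, 0.45, 0.50, 0.55,
                                   0.60, 0.65, 0.70)
    hct_reps: int = 3
    stability_days: Tuple[int, ...] = (0, 1, 3, 5, 7, 14, 28)
    stability_temps: Tuple[float, ...] = (20.0, -18.0)
    stability_reps: int = 4

    def __post_init__(self) -> None:
        if self.cal_levels < 3:
            raise ValueError("need >= 3 calibrator levels")
        if self.precision_runs < 2 or self.precision_reps < 2:
            raise ValueError("precision design needs >= 2 runs of >= 2 reps")
        if len(self.loq_level_factors) < 3 or self.loq_reps < 2:
            raise ValueError("LOQ design needs >= 3 levels of >= 2 reps")
        if self.recovery_reps < 2 or self.me_reps < 2:
            raise ValueError("recovery/matrix designs need >= 2 reps")
        if compartment.HCT_STANDARD not in self.hct_grid:
            raise ValueError("hct_grid must include the 0.40 reference")
        if 0 not in self.stability_days:
            raise ValueError("stability schedule must include day 0")


def _run_effects(
    codes: Sequence[str], run_ids: Sequence[str], noise: NoiseModel,
    rng: np.random.Generator,
) -> Dict[Tuple[str, str], float]:
    eff = {}
    for run in run_ids:
        for code in codes:
            sd = noise.between_run_sd(code)
            eff[(run, code)] = rng.normal(0.0, sd) if sd else 0.0
    return eff


def simulate_validation_batch(
    panel: Optional[Panel] = None,
    noise: Optional[NoiseModel] = None,
    deg: Optional[DegradationModel] = None,
    design: Optional[ValidationDesign] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a complete validation batch as one long-format peak table.

    Contains, per analyte: per-run calibration sets (calibrators + blanks),
    precision/accuracy QCs (runs × reps), the LOQ ladder, recovery and
    matrix-effect area sets, the carryover triplet, the hematocrit series,
    and the two-temperature stability grid. Ground-truth parameters are
    attached under ``df.attrs["truth"]``.
    """
    panel = panel or default_panel()
    noise = noise or NoiseModel.default()
    deg = deg or DegradationModel.default(tuple(panel))
    design = design or ValidationDesign()
    rng = np.random.default_rng(seed)

    run_ids = [f"run{i+1}" for i in range(design.precision_runs)]
    effects = _run_effects(list(panel), run_ids, noise, rng)
    rows: list = []

    for code, spec in panel.items():
        levels = cal_levels(spec, design.cal_levels)
        qc = qc_conc(spec)
        # calibration set in every run (blank matrix carries the residual)
        for run in run_ids:
            eff = effects[(run, code)]
            for b in range(design.cal_blanks):
                rows += _rows([_measurement_from_conc(
                    spec.blank_residual, spec, noise, rng,
                    sample_id=f"{code}-{run}-blank{b+1}", role=Role.BLANK,
                    run_id=run, run_effect=eff,
                )], "calibration")
            for i, lv in enumerate(levels):
                rows += _rows([_measurement_from_conc(
                    lv + spec.blank_residual, spec, noise, rng,
                    sample_id=f"{code}-{run}-cal{i+1}", role=Role.CALIBRATOR,
                    run_id=run, run_effect=eff, nominal_conc=lv,
                )], "calibration")
            # precision / accuracy QCs
            for r in range(design.precision_reps):
                rows += _rows([_measurement_from_conc(
                    qc + spec.blank_residual, spec, noise, rng,
                    sample_id=f"{code}-{run}-qc{r+1}", role=Role.QC,
                    run_id=run, run_effect=eff, nominal_conc=qc,
                )], "precision")

        eff1 = effects[(run_ids[0], code)]
        # LOQ ladder (run 1)
        for i, f in enumerate(design.loq_level_factors):
            lv = f * spec.loq
            for r in range(design.loq_reps):
                rows += _rows([_measurement_from_conc(
                    lv + spec.blank_residual, spec, noise, rng,
                    sample_id=f"{code}-loq{i+1}-{r+1}", role=Role.QC,
                    run_id=run_ids[0], run_effect=eff1, nominal_conc=lv,
                )], "loq")
        # recovery: pre-extraction spike (full losses) vs post-extraction
        rec_conc = (design.recovery_conc_dheas if code == "DHEA-S"
                    else design.recovery_conc)
        for r in range(design.recovery_reps):
            rows += _rows([PeakMeasurement(
                sample_id=f"{code}-recpre{r+1}", analyte=code, role=Role.QC,
                analyte_area=_signal_ratio(rec_conc, code, noise, rng,
                                           run_effect=eff1) * ISTD_AREA,
                istd_area=ISTD_AREA, run_id=run_ids[0],
                nominal_conc=rec_conc,
            )], "recovery_pre")
            rows += _rows([PeakMeasurement(
                sample_id=f"{code}-recpost{r+1}", analyte=code, role=Role.QC,
                analyte_area=_signal_ratio(rec_conc, code, noise, rng,
                                           run_effect=eff1,
                                           with_recovery=False) * ISTD_AREA,
                istd_area=ISTD_AREA, run_id=run_ids[0],
                nominal_conc=rec_conc,
            )], "recovery_post")
        # matrix effect: post-extraction matrix spike vs pure solvent spike
        for r in range(design.me_reps):
            rows += _rows([PeakMeasurement(
                sample_id=f"{code}-mematrix{r+1}", analyte=code, role=Role.QC,
                analyte_area=_signal_ratio(rec_conc, code, noise, rng,
                                           run_effect=eff1,
                                           with_recovery=False) * ISTD_AREA,
                istd_area=ISTD_AREA, run_id=run_ids[0],
                nominal_conc=rec_conc,
            )], "me_matrix")
            rows += _rows([PeakMeasurement(
                sample_id=f"{code}-mesolv{r+1}", analyte=code, role=Role.QC,
                analyte_area=_signal_ratio(rec_conc, code, noise, rng,
                                           run_effect=eff1,
                                           with_recovery=False,
                                           with_matrix=False) * ISTD_AREA,
                istd_area=ISTD_AREA, run_id=run_ids[0],
                nominal_conc=rec_conc,
            )], "me_solvent")
        # carryover: high injection followed by a blank
        co_conc = (design.carryover_conc_dheas if code == "DHEA-S"
                   else design.carryover_conc)
        high_area = _signal_ratio(co_conc, code, noise, rng,
                                  run_effect=eff1) * ISTD_AREA
        rows += _rows([PeakMeasurement(
            sample_id=f"{code}-cohigh", analyte=code, role=Role.QC,
            analyte_area=high_area, istd_area=ISTD_AREA,
            run_id=run_ids[0], nominal_conc=co_conc,
        )], "carryover_high")
        rows += _rows([PeakMeasurement(
            sample_id=f"{code}-coblank", analyte=code, role=Role.BLANK,
            analyte_area=noise.carryover_frac * high_area,
            istd_area=ISTD_AREA, run_id=run_ids[0],
        )], "carryover_blank")
        # hematocrit series: same serum level re-sampled at varying Hct
        serum_mid = compartment.serum_from_vams(qc, compartment.HCT_STANDARD, spec)
        for h in design.hct_grid:
            for r in range(design.hct_reps):
                m = simulate_measurement(
                    serum_mid, h, spec, noise, rng,
                    sample_id=f"{code}-hct{int(round(h*100))}-{r+1}",
                    run_id=run_ids[0], run_effect=eff1,
                )
                rows += _rows([m], "hct")
        # stability grid
        for temp in design.stability_temps:
            for day in design.stability_days:
                for r in range(design.stability_reps):
                    rows += _rows([_measurement_from_conc(
                        qc + spec.blank_residual, spec, noise, rng,
                        sample_id=f"{code}-stab{int(temp)}c-d{day}-{r+1}",
                        role=Role.QC, run_id=run_ids[0], run_effect=eff1,
                        nominal_conc=qc, storage_days=day,
                        storage_temp_c=temp, deg=deg,
                    )], "stability")

    df = pd.DataFrame(rows, columns=PEAK_COLUMNS + ["purpose"])
    df.attrs["truth"] = {
        "noise": noise, "degradation": deg, "design": design, "seed": seed,
        "qc_conc": {c: qc_conc(s) for c, s in panel.items()},
    }
    return df


def simulate_paired_study(
    n_subjects: int = 11,
    cohort: Optional[CohortModel] = None,
    noise: Optional[NoiseModel] = None,
    panel: Optional[Panel] = None,
    seed: int = 0,
    *,
    n_male: int = 1,
    replicates: int = 2,
    exact_calibration: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired venous-serum vs capillary-VAMS study.

    Each subject contributes a measured serum concentration (truth with
    multiplicative assay noise, replicates averaged) and VAMS replicate
    measurements at the subject's own hematocrit, all in one analytical
    run together with a calibration set. Returns
    ``(serum_table, vams_peak_table, truth_table)``.

    ``exact_calibration`` generates the run's calibrators and blanks
    without random noise, so the fitted curve inverts the response
    exactly. A noisy single-run calibration injects a *shared* error into
    every subject's VAMS concentration (calibration-transfer bias), which
    is realistic but deliberately excluded when studying the behaviour of
    the paired significance tests under exchangeable measurement error.
    """
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    if not 0 <= n_male <= n_subjects:
        raise ValueError("0 <= n_male <= n_subjects required")
    panel = panel or default_panel()
    cohort = cohort or CohortModel.default()
    noise = noise or NoiseModel.default()
    rng = np.random.default_rng(seed)
    run = "paired_run"

    rows: list = []
    # calibration set for the single run (no between-run term within a run)
    cal_noise = noise
    if exact_calibration:
        cal_noise = NoiseModel(
            intraday_cv_pct={c: 0.0 for c in noise.intraday_cv_pct},
            interday_cv_pct={c: 0.0 for c in noise.interday_cv_pct},
            recovery_frac=noise.recovery_frac,
            matrix_effect_frac=noise.matrix_effect_frac,
            snr_at_loq=noise.snr_at_loq,
            carryover_frac=noise.carryover_frac,
            response_slope=noise.response_slope,
        )
    for code, spec in panel.items():
        for b in range(2):
            rows += _rows([_measurement_from_conc(
                spec.blank_residual, spec, cal_noise, rng,
                sample_id=f"{code}-blank{b+1}", role=Role.BLANK, run_id=run,
            )], "calibration")
        for i, lv in enumerate(cal_levels(spec)):
            rows += _rows([_measurement_from_conc(
                lv + spec.blank_residual, spec, cal_noise, rng,
                sample_id=f"{code}-cal{i+1}", role=Role.CALIBRATOR,
                run_id=run, nominal_conc=lv,
            )], "calibration")

    serum_rows: list = []
    truth_rows: list = []
    sexes = ["male"] * n_male + ["female"] * (n_subjects - n_male)
    for i, sex in enumerate(sexes):
        sid = f"subj{i+1:02d}"
        hct = float(cohort.draw_hct(sex, rng, 1)[0])
        for code in cohort.codes_for(sex):
            if code not in panel:
                continue
            spec = panel[code]
            truth = float(cohort.draw_serum(code, sex, rng, 1)[0])
            sd = noise.intraday_sd(code)
            meas = truth * (1.0 + rng.normal(0.0, sd, size=replicates)) if sd \
                else np.full(replicates, truth)
            serum_rows.append({
                "subject_id": sid, "analyte": code,
                "c_serum": float(np.mean(meas)),
            })
            for r in range(replicates):
                m = simulate_measurement(
                    truth, hct, spec, noise, rng,
                    sample_id=f"{sid}-{code}-rep{r+1}", run_id=run,
                    run_effect=0.0,
                )
                rows += _rows([m], "paired")
            truth_rows.append({
                "subject_id": sid, "analyte": code, "sex": sex,
                "true_serum": truth, "hct": hct,
            })

    vams = pd.DataFrame(rows, columns=PEAK_COLUMNS + ["purpose"])
    serum = pd.DataFrame(serum_rows, columns=["subject_id", "analyte", "c_serum"])
    truth = pd.DataFrame(
        truth_rows, columns=["subject_id", "analyte", "sex", "true_serum", "hct"]
    )
    for df in (vams, serum, truth):
        df.attrs["seed"] = seed
    return serum, vams, truth


def simulate_cohort(
    n_female: int = 32,
    n_male: int = 18,
    cohort: Optional[CohortModel] = None,
    noise: Optional[NoiseModel] = None,
    panel: Optional[Panel] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Proof-of-concept-style cohort: one VAMS sample per subject.

    The female-only sex hormones (P4, E2) are sampled for female subjects
    only. A calibration set for the run is included. The ground truth is
    attached under ``df.attrs["truth"]``.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("subject counts must be >= 0")
    panel = panel or default_panel()
    cohort = cohort or CohortModel.default()
    noise = noise or NoiseModel.default()
    rng = np.random.default_rng(seed)
    run = "cohort_run"

    rows: list = []
    truth_rows: list = []
    if n_female + n_male > 0:
        for code, spec in panel.items():
            for b in range(2):
                rows += _rows([_measurement_from_conc(
                    spec.blank_residual, spec, noise, rng,
                    sample_id=f"{code}-blank{b+1}", role=Role.BLANK,
                    run_id=run,
                )], "calibration")
            for i, lv in enumerate(cal_levels(spec)):
                rows += _rows([_measurement_from_conc(
                    lv + spec.blank_residual, spec, noise, rng,
                    sample_id=f"{code}-cal{i+1}", role=Role.CALIBRATOR,
                    run_id=run, nominal_conc=lv,
                )], "calibration")

    subjects = [("female", i) for i in range(n_female)] + [
        ("male", i) for i in range(n_male)
    ]
    for sex, i in subjects:
        sid = f"{'F' if sex == 'female' else 'M'}{i+1:02d}"
        hct = float(cohort.draw_hct(sex, rng, 1)[0])
        for code in cohort.codes_for(sex):
            if code not in panel:
                continue
            spec = panel[code]
            truth = float(cohort.draw_serum(code, sex, rng, 1)[0])
            m = simulate_measurement(
                truth, hct, spec, noise, rng,
                sample_id=f"{sid}-{code}", run_id=run, run_effect=0.0,
            )
            rows += _rows([m], "cohort")
            truth_rows.append({
                "subject_id": sid, "analyte": code, "sex": sex,
                "true_serum": truth, "hct": hct,
            })

    df = pd.DataFrame(rows, columns=PEAK_COLUMNS + ["purpose"])
    df.attrs["truth"] = pd.DataFrame(
        truth_rows, columns=["subject_id", "analyte", "sex", "true_serum", "hct"]
    )
    df.attrs["seed"] = seed
    return df
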