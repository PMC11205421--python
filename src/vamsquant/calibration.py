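"""Internal-standard calibration with blank correction.

Quantification uses the analyte/ISTD peak-area ratio. Calibration curves
are ordinary least squares of (nominal concentration, blank-corrected area
ratio): the run's mean blank ratio — the response of the surrogate blank
matrix, which retains trace endogenous hormone for some analytes — is
subtracted from calibrators and unknowns alike before fitting and
quantification. Linearity is accepted when R² meets the configured minimum
and a Wald–Wolfowitz sign-runs test finds no systematic residual pattern.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AnalyteSpec, Panel, ThresholdConfig

__all__ = [
    "PeakMeasurement",
    "CalibrationCurve",
    "CalibrationError",
    "CensorFlag",
    "area_ratio",
    "runs_test_pvalue",
    "fit_calibration",
    "quantify",
    "measurement_from_row",
    "curves_from_table",
]


class CalibrationError(ValueError):
    pass


class Role(str, enum.Enum):
    BLANK = "blank"
    CALIBRATOR = "calibrator"
    QC = "qc"
    SAMPLE = "sample"


@dataclass(frozen=True)
class PeakMeasurement:
    """One integrated peak: a sample × analyte row of the peak table."""

    sample_id: str
    analyte: str
    role: Role
    analyte_area: float
    istd_area: float
    run_id: str = "run1"
    day_index: int = 0
    snr: Optional[float] = None
    nominal_conc: Optional[float] = None   # calibrator / QC only
    hct: Optional[float] = None
    storage_days: Optional[int] = None
    storage_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        if self.analyte_area < 0:
            raise CalibrationError(
                f"sample {self.sample_id!r}: analyte_area must be >= 0"
            )
        has_nominal = self.nominal_conc is not None
        needs_nominal = self.role in (Role.CALIBRATOR, Role.QC)
        if has_nominal != needs_nominal:
            raise CalibrationError(
                f"sample {self.sample_id!r}: nominal_conc must be present "
                "iff role is calibrator or qc"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Blank-corrected linear response of one analyte with fit diagnostics."""

    analyte: str
    slope: float          # ratio per (ng/mL)
    intercept: float      # ratio
    r2: float
    blank_ratio: float
    n_levels: int
    residuals: Tuple[float, ...]
    linear_ok: bool
    slope_stderr: float = float("nan")
    runs_p: float = float("nan")


def area_ratio(m: PeakMeasurement) -> float:
    """Analyte/ISTD peak-area ratio — the response used everywhere."""
    if m.istd_area <= 0:
        raise CalibrationError(
            f"sample {m.sample_id!r} ({m.analyte}): istd_area must be > 0"
        )
    return m.analyte_area / m.istd_area


def runs_test_pvalue(residuals: Sequence[float]) -> float:
    """Wald–Wolfowitz runs test on residual signs, lower tail.

    Tests for too FEW sign runs — clustered residuals, the signature of
    curvature or trend around the fitted line. (Too many runs means
    alternation, which is not a systematic calibration pattern.) Zero
    residuals are dropped; returns 1.0 when a sign class is empty (no
    pattern assessable). Normal approximation for the run count.
    """
    signs = [1 if r > 0 else -1 for r in residuals if r != 0]
    n_pos = signs.count(1)
    n_neg = signs.count(-1)
    if n_pos == 0 or n_neg == 0:
        return 1.0
    runs = 1 + sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(stats.norm.cdf(z))


def fit_calibration(
    cal_points: Sequence[Tuple[float, float]],
    blank_ratio: float,
    thresholds: ThresholdConfig,
    *,
    analyte: str = "",
    weighting: Optional[str] = None,
) -> CalibrationCurve:
    """Fit the blank-corrected calibration line.

    ``cal_points`` are (nominal ng/mL, raw area ratio); replicates at a
    level are averaged before fitting. Default is unweighted OLS; ``"1/x"``
    enables inverse-concentration weighting.
    """
    if blank_ratio < 0:
        raise CalibrationError("blank_ratio must be >= 0")
    by_level: Dict[float, List[float]] = {}
    for nominal, ratio in cal_points:
        by_level.setdefault(float(nominal), []).append(float(ratio))
    x = np.array(sorted(by_level), dtype=float)
    if x.size < 3:
        raise CalibrationError(
            f"need >= 3 distinct calibrator levels, got {x.size}"
        )
    y = np.array([np.mean(by_level[v]) for v in x]) - blank_ratio

    if weighting is None:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        stderr = res.stderr
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise CalibrationError("1/x weighting requires positive nominals")
        w = 1.0 / x
        W = np.sum(w)
        xb = np.sum(w * x) / W
        yb = np.sum(w * y) / W
        sxx = np.sum(w * (x - xb) ** 2)
        slope = np.sum(w * (x - xb) * (y - yb)) / sxx
        intercept = yb - slope * xb
        dof = max(x.size - 2, 1)
        s2 = np.sum(w * (y - intercept - slope * x) ** 2) / dof
        stderr = math.sqrt(s2 / sxx)
    else:
        raise CalibrationError(f"unknown weighting {weighting!r}")

    fitted = intercept + slope * x
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # residuals at floating-point noise level carry no sign information
    tiny = 1e-10 * max(float(np.max(np.abs(y))), 1e-300)
    runs_p = runs_test_pvalue(np.where(np.abs(resid) < tiny, 0.0, resid))
    pattern_flag = runs_p < 0.05
    linear_ok = bool(r2 >= thresholds.r2_min and not pattern_flag)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        blank_ratio=float(blank_ratio),
        n_levels=int(x.size),
        residuals=tuple(float(r) for r in resid),
        linear_ok=linear_ok,
        slope_stderr=float(stderr),
        runs_p=float(runs_p),
    )


class CensorFlag(str, enum.Enum):
    OK = "ok"
    BELOW_LOQ = "below_loq"


def quantify(
    m: PeakMeasurement, curve: CalibrationCurve, spec: AnalyteSpec
) -> Tuple[float, CensorFlag]:
    """Invert the calibration curve for one measurement.

    conc = (ratio − blank_ratio − intercept) / slope. Negative results are
    reported as 0; anything below the analyte's LOQ is flagged.
    """
    if not curve.linear_ok:
        raise CalibrationError(
            f"{curve.analyte or spec.short_code}: calibration curve rejected "
            f"(r2={curve.r2:.4f}, runs_p={curve.runs_p:.3f})"
        )
    if curve.slope <= 0:
        raise CalibrationError("calibration slope must be > 0")
    conc = (area_ratio(m) - curve.blank_ratio - curve.intercept) / curve.slope
    if conc < 0:
        conc = 0.0
    flag = CensorFlag.BELOW_LOQ if conc < spec.loq else CensorFlag.OK
    return conc, flag


# --- long-format peak-table helpers -----------------------------------------

def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return cast(value)


def measurement_from_row(row: Mapping) -> PeakMeasurement:
    """Build a PeakMeasurement from one long-format peak-table row
    (pandas NaN / empty cells in optional columns map to None)."""
    return PeakMeasurement(
        sample_id=str(row["sample_id"]),
        analyte=str(row["analyte"]),
        role=Role(str(row["role"]).strip()),
        analyte_area=float(row["analyte_area"]),
        istd_area=float(row["istd_area"]),
        run_id=str(row.get("run_id", "run1")),
        day_index=_opt(row.get("day_index"), int) or 0,
        snr=_opt(row.get("snr")),
        nominal_conc=_opt(row.get("nominal_conc")),
        hct=_opt(row.get("hct")),
        storage_days=_opt(row.get("storage_days"), int),
        storage_temp_c=_opt(row.get("storage_temp_c")),
    )


def curves_from_table(
    table: pd.DataFrame,
    panel: Panel,
    thresholds: ThresholdConfig,
) -> Dict[Tuple[str, str], CalibrationCurve]:
    """Fit one blank-corrected curve per (run_id, analyte) in a peak table.

    Blank rows of the run give the run's mean blank ratio; when a
    ``purpose`` column is present only ``calibration`` blanks count (so
    e.g. carryover blanks are never mistaken for matrix blanks).
    """
    curves: Dict[Tuple[str, str], CalibrationCurve] = {}
    df = table
    for (run, analyte), grp in df.groupby(["run_id", "analyte"], sort=False):
        cal = grp[grp["role"] == Role.CALIBRATOR.value]
        if cal.empty:
            continue
        blanks = grp[grp["role"] == Role.BLANK.value]
        if "purpose" in grp.columns and not blanks.empty:
            blanks = blanks[
                blanks["purpose"].fillna("calibration") == "calibration"
            ]
        if blanks.empty:
            blank_ratio = 0.0
        else:
            blank_ratio = float(np.mean(
                [area_ratio(measurement_from_row(r))
                 for _, r in blanks.iterrows()]
            ))
        points = [
            (float(r["nominal_conc"]), area_ratio(measurement_from_row(r)))
            for _, r in cal.iterrows()
        ]
        curves[(str(run), str(analyte))] = fit_calibration(
            points, blank_ratio, thresholds, analyte=str(analyte)
        )
    return curves
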