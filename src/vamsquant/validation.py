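"""Bioanalytical method-validation battery.

Computes the FDA-style validation figures of merit from replicate designs:
intra-/interday imprecision (CV of area ratios), accuracy against nominal,
limit of quantification (lowest level passing CV and SNR gates), extraction
recovery and matrix effect (mean-area ratios of paired sample sets),
injection carryover, hematocrit robustness against the Hct-0.40 reference,
and storage stability against the day-0 concentration. `validation_report`
aggregates everything with pass/fail against a ThresholdConfig.

Interday imprecision is the CV over all replicate values pooled across
runs; an ANOVA-style variance-component decomposition is available as an
option for the stricter reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    area_ratio,
    curves_from_table,
    measurement_from_row,
    quantify,
)
from .panel import Panel, ThresholdConfig

__all__ = [
    "ValidationError",
    "PrecisionResult",
    "LoqLevel",
    "StabilityResult",
    "HctRobustnessResult",
    "ValidationReport",
    "STABILITY_SCHEDULE",
    "STABLE_BEYOND",
    "imprecision",
    "accuracy",
    "estimate_loq",
    "recovery",
    "matrix_effect",
    "carryover",
    "hct_robustness",
    "stability_assess",
    "validation_report",
    "validate_batch",
]


class ValidationError(ValueError):
    pass


def _cv_pct(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0:
        raise ValidationError("zero mean: CV undefined")
    if values.size < 2:
        return 0.0
    return 100.0 * float(np.std(values, ddof=1)) / mean


# --- imprecision ------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionResult:
    analyte: str
    intraday_cv_pct: Tuple[float, ...]   # one CV per run
    interday_cv_pct: float               # pooled over all runs
    n_per_run: int
    n_runs: int
    passed: bool
    interday_cv_anova_pct: Optional[float] = None


def imprecision(
    runs: Mapping[str, Sequence[float]],
    thresholds: ThresholdConfig,
    *,
    analyte: str = "",
    anova: bool = False,
) -> PrecisionResult:
    """Intra- and interday CV from replicate area ratios grouped by run.

    Intraday CV is computed per run; interday CV pools every value across
    runs. With ``anova=True`` an additional one-way variance-component
    estimate (within + between run) is reported.
    """
    if not runs:
        raise ValidationError("no runs supplied")
    arrays = {r: np.asarray(v, dtype=float) for r, v in runs.items()}
    for r, a in arrays.items():
        if a.size < 2:
            raise ValidationError(f"run {r!r}: need >= 2 replicates")
    intraday = tuple(_cv_pct(a) for a in arrays.values())
    pooled = np.concatenate(list(arrays.values()))
    if len(arrays) >= 2:
        interday = _cv_pct(pooled)
    else:
        interday = intraday[0]

    interday_anova = None
    if anova and len(arrays) >= 2:
        grand = float(np.mean(pooled))
        k = len(arrays)
        n_i = np.array([a.size for a in arrays.values()])
        means = np.array([np.mean(a) for a in arrays.values()])
        ss_within = sum(
            float(np.sum((a - np.mean(a)) ** 2)) for a in arrays.values()
        )
        ms_within = ss_within / (pooled.size - k)
        ss_between = float(np.sum(n_i * (means - grand) ** 2))
        ms_between = ss_between / (k - 1)
        n0 = (pooled.size - np.sum(n_i**2) / pooled.size) / (k - 1)
        var_between = max((ms_between - ms_within) / n0, 0.0)
        interday_anova = 100.0 * math.sqrt(ms_within + var_between) / grand

    passed = max(intraday) <= thresholds.cv_max_pct and (
        interday <= thresholds.cv_max_pct
    )
    n_per_run = min(a.size for a in arrays.values())
    return PrecisionResult(
        analyte=analyte,
        intraday_cv_pct=intraday,
        interday_cv_pct=interday,
        n_per_run=int(n_per_run),
        n_runs=len(arrays),
        passed=bool(passed),
        interday_cv_anova_pct=interday_anova,
    )


# --- accuracy ---------------------------------------------------------------

def accuracy(measured: Sequence[float], nominal: float) -> float:
    """Mean measured concentration as a percentage of nominal."""
    if nominal <= 0:
        raise ValidationError("nominal must be > 0")
    vals = np.asarray(measured, dtype=float)
    if vals.size == 0:
        raise ValidationError("need >= 1 measurement")
    return 100.0 * float(np.mean(vals)) / nominal


def accuracy_passes(acc_pct: float, thresholds: ThresholdConfig) -> bool:
    return abs(100.0 - acc_pct) <= thresholds.accuracy_tol_pct


# --- limit of quantification ------------------------------------------------

@dataclass(frozen=True)
class LoqLevel:
    """Summary of one LOQ candidate level (replicate design)."""

    conc: float
    cv_pct: float
    mean_snr: float


#: Sentinel returned when no level satisfies the LOQ gates.
LOQ_NOT_REACHED = float("inf")


def estimate_loq(
    levels: Sequence[LoqLevel], thresholds: ThresholdConfig
) -> float:
    """Lowest concentration passing both LOQ gates with monotone closure.

    A level qualifies only if its CV ≤ loq_cv_max_pct, its mean SNR ≥
    loq_min_snr, and every higher level also qualifies (a noisy mid-level
    cannot yield a lower LOQ than the instability above it). Returns
    ``LOQ_NOT_REACHED`` (inf) when no level qualifies.
    """
    if not levels:
        raise ValidationError("no LOQ levels supplied")
    concs = [lv.conc for lv in levels]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValidationError("LOQ levels must be strictly ascending")
    result = LOQ_NOT_REACHED
    for lv in reversed(levels):
        ok = (
            lv.cv_pct <= thresholds.loq_cv_max_pct
            and lv.mean_snr >= thresholds.loq_min_snr
        )
        if ok:
            result = lv.conc
        else:
            break
    return result


# --- recovery / matrix effect / carryover -----------------------------------

def recovery(
    pre_spiked_areas: Sequence[float], post_spiked_areas: Sequence[float]
) -> float:
    """Extraction recovery: 100 · mean(pre-spike) / mean(post-spike)."""
    pre = np.asarray(pre_spiked_areas, dtype=float)
    post = np.asarray(post_spiked_areas, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValidationError("recovery requires nonempty area sets")
    post_mean = float(np.mean(post))
    if post_mean <= 0:
        raise ValidationError("post-spike mean area must be > 0")
    return 100.0 * float(np.mean(pre)) / post_mean


def matrix_effect(
    matrix_spiked_areas: Sequence[float], solvent_spiked_areas: Sequence[float]
) -> float:
    """Matrix effect: 100 · mean(matrix spike A) / mean(solvent spike B).

    < 100 indicates ion suppression, > 100 enhancement.
    """
    a = np.asarray(matrix_spiked_areas, dtype=float)
    b = np.asarray(solvent_spiked_areas, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("matrix effect requires nonempty area sets")
    b_mean = float(np.mean(b))
    if b_mean <= 0:
        raise ValidationError("solvent-spike mean area must be > 0")
    return 100.0 * float(np.mean(a)) / b_mean


def carryover(blank_after_high_area: float, high_area: float) -> float:
    """Residual blank signal after a high injection, as % of the high."""
    if high_area <= 0:
        raise ValidationError("high_area must be > 0")
    if blank_after_high_area < 0:
        raise ValidationError("blank area must be >= 0")
    return 100.0 * blank_after_high_area / high_area


# --- hematocrit robustness --------------------------------------------------

@dataclass(frozen=True)
class HctRobustnessResult:
    analyte: str
    ref_hct: float
    deviations: Tuple[Tuple[float, float], ...]  # (hct, deviation %)
    pass_range: Tuple[float, float]


def hct_robustness(
    measured: Sequence[Tuple[float, float]],
    ref_hct: float,
    thresholds: ThresholdConfig,
    *,
    analyte: str = "",
) -> HctRobustnessResult:
    """Measured-concentration deviation across hematocrit.

    deviation(h) = 100·(conc(h)/conc(ref) − 1), with conc(ref) taken at the
    reference hematocrit (linearly interpolated when not sampled). The pass
    range is the maximal contiguous hct interval containing the reference
    where every |deviation| ≤ hct_dev_max_pct.
    """
    if not measured:
        raise ValidationError("no measurements supplied")
    pts = sorted((float(h), float(c)) for h, c in measured)
    hs = np.array([p[0] for p in pts])
    cs = np.array([p[1] for p in pts])
    if ref_hct < hs[0] or ref_hct > hs[-1]:
        raise ValidationError(
            f"reference hct {ref_hct} outside measured range "
            f"[{hs[0]}, {hs[-1]}]"
        )
    c_ref = float(np.interp(ref_hct, hs, cs))
    if c_ref <= 0:
        raise ValidationError("reference concentration must be > 0")
    devs = [(h, 100.0 * (c / c_ref - 1.0)) for h, c in pts]

    ok = [abs(d) <= thresholds.hct_dev_max_pct for _, d in devs]
    i_ref = int(np.argmin(np.abs(hs - ref_hct)))
    if not ok[i_ref]:
        pass_range = (ref_hct, ref_hct)
    else:
        lo = i_ref
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        hi = i_ref
        while hi < len(devs) - 1 and ok[hi + 1]:
            hi += 1
        pass_range = (devs[lo][0], devs[hi][0])
    return HctRobustnessResult(
        analyte=analyte,
        ref_hct=float(ref_hct),
        deviations=tuple(devs),
        pass_range=pass_range,
    )


# --- storage stability ------------------------------------------------------

#: Scheduled storage durations of the stability study (days).
STABILITY_SCHEDULE = (0, 1, 3, 5, 7, 14, 28)
#: Sentinel: every scheduled day up to 28 passed.
STABLE_BEYOND = ">28"


@dataclass(frozen=True)
class StabilityResult:
    analyte: str
    temp_c: float
    series: Tuple[Tuple[int, float], ...]   # (day, mean conc ng/mL)
    stable_days: int                         # largest passing scheduled day
    pass_28d: bool

    @property
    def stable_days_label(self) -> str:
        return STABLE_BEYOND if self.pass_28d else str(self.stable_days)


def stability_assess(
    series: Sequence[Tuple[int, float]],
    thresholds: ThresholdConfig,
    *,
    analyte: str = "",
    temp_c: float = float("nan"),
) -> StabilityResult:
    """Storage stability from a scheduled-day mean-concentration series.

    ``stable_days`` is the largest scheduled day d such that every day ≤ d
    deviates from day 0 by at most stability_tol_pct; if day 28 passes the
    result carries the ">28" sentinel.
    """
    by_day = {int(d): float(c) for d, c in series}
    if 0 not in by_day:
        raise ValidationError("stability series must include day 0")
    c0 = by_day[0]
    if c0 <= 0:
        raise ValidationError("day-0 concentration must be > 0")
    days = sorted(by_day)
    stable = 0
    for d in days:
        dev = abs(100.0 * (by_day[d] / c0 - 1.0))
        if dev <= thresholds.stability_tol_pct:
            stable = d
        else:
            break
    pass_28d = stable >= 28
    return StabilityResult(
        analyte=analyte,
        temp_c=float(temp_c),
        series=tuple(sorted(by_day.items())),
        stable_days=stable,
        pass_28d=pass_28d,
    )


# --- aggregate report -------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-analyte validation summary with pass/fail per component.

    Recovery and matrix effect carry no numeric acceptance criterion (the
    deuterated ISTD compensates losses); they are reported informationally.
    ``overall_pass`` is the conjunction of the assessed boolean components;
    missing components are listed in ``not_assessed`` and excluded.
    """

    analyte: str
    precision: Optional[PrecisionResult] = None
    accuracy_pct: Optional[float] = None
    accuracy_pass: Optional[bool] = None
    loq_est: Optional[float] = None
    loq_claimed: Optional[float] = None
    loq_pass: Optional[bool] = None
    recovery_pct: Optional[float] = None
    matrix_effect_pct: Optional[float] = None
    carryover_pct: Optional[float] = None
    carryover_pass: Optional[bool] = None
    hct: Optional[HctRobustnessResult] = None
    stability: List[StabilityResult] = field(default_factory=list)
    stability_frozen_pass: Optional[bool] = None
    selectivity_pass: Optional[bool] = None   # chromatographic, pass-through
    linearity_ok: Optional[bool] = None
    not_assessed: List[str] = field(default_factory=list)
    overall_pass: bool = False

    def finalize(self) -> "ValidationReport":
        checks: Dict[str, Optional[bool]] = {
            "precision": self.precision.passed if self.precision else None,
            "accuracy": self.accuracy_pass,
            "loq": self.loq_pass,
            "carryover": self.carryover_pass,
            "stability_frozen": self.stability_frozen_pass,
            "linearity": self.linearity_ok,
            "selectivity": self.selectivity_pass,
        }
        self.not_assessed = [k for k, v in checks.items() if v is None]
        assessed = [v for v in checks.values() if v is not None]
        self.overall_pass = bool(assessed) and all(assessed)
        return self


def validation_report(
    analyte: str,
    thresholds: ThresholdConfig,
    *,
    precision: Optional[PrecisionResult] = None,
    accuracy_pct: Optional[float] = None,
    loq_est: Optional[float] = None,
    loq_claimed: Optional[float] = None,
    recovery_pct: Optional[float] = None,
    matrix_effect_pct: Optional[float] = None,
    carryover_pct: Optional[float] = None,
    hct: Optional[HctRobustnessResult] = None,
    stability: Sequence[StabilityResult] = (),
    selectivity_pass: Optional[bool] = None,
    linearity_ok: Optional[bool] = None,
) -> ValidationReport:
    """Aggregate component results into a per-analyte ValidationReport."""
    rep = ValidationReport(analyte=analyte)
    rep.precision = precision
    if accuracy_pct is not None:
        rep.accuracy_pct = accuracy_pct
        rep.accuracy_pass = accuracy_passes(accuracy_pct, thresholds)
    if loq_est is not None:
        rep.loq_est = loq_est
        rep.loq_claimed = loq_claimed
        if loq_claimed is not None:
            rep.loq_pass = bool(loq_est <= loq_claimed)
    if recovery_pct is not None:
        rep.recovery_pct = recovery_pct
    if matrix_effect_pct is not None:
        rep.matrix_effect_pct = matrix_effect_pct
    if carryover_pct is not None:
        rep.carryover_pct = carryover_pct
        rep.carryover_pass = bool(carryover_pct <= thresholds.carryover_max_pct)
    rep.hct = hct
    rep.stability = list(stability)
    frozen = [s for s in rep.stability if s.temp_c <= 0]
    if frozen:
        rep.stability_frozen_pass = all(s.pass_28d for s in frozen)
    rep.selectivity_pass = selectivity_pass
    rep.linearity_ok = linearity_ok
    return rep.finalize()


# --- whole-batch driver -----------------------------------------------------

def _ratios(rows: pd.DataFrame) -> List[float]:
    return [area_ratio(measurement_from_row(r)) for _, r in rows.iterrows()]


def _concs(
    rows: pd.DataFrame, curves, panel: Panel
) -> List[float]:
    out = []
    for _, r in rows.iterrows():
        m = measurement_from_row(r)
        curve = curves[(m.run_id, m.analyte)]
        conc, _ = quantify(m, curve, panel[m.analyte])
        out.append(conc)
    return out


def validate_batch(
    table: pd.DataFrame,
    panel: Panel,
    thresholds: ThresholdConfig,
    *,
    ref_hct: float = 0.40,
) -> Dict[str, ValidationReport]:
    """Run the full validation battery on a long-format peak table.

    The table must carry a ``purpose`` column routing rows to the battery
    components (calibration, precision, loq, recovery_pre/post,
    me_matrix/me_solvent, carryover_high/carryover_blank, hct, stability),
    as produced by the synthetic batch generator or an equivalently
    annotated instrument export. Components without rows are reported as
    not assessed.
    """
    if "purpose" not in table.columns:
        raise ValidationError("peak table needs a 'purpose' column")
    curves = curves_from_table(table, panel, thresholds)
    reports: Dict[str, ValidationReport] = {}
    for code in panel:
        sub = table[table["analyte"] == code]
        if sub.empty:
            continue
        spec = panel[code]
        by_purpose = {p: g for p, g in sub.groupby("purpose")}

        analyte_curves = {k: v for k, v in curves.items() if k[1] == code}
        linearity_ok = (
            all(c.linear_ok for c in analyte_curves.values())
            if analyte_curves else None
        )

        precision_res = None
        accuracy_pct = None
        prec = by_purpose.get("precision")
        if prec is not None and not prec.empty:
            runs = {
                str(run): _ratios(g) for run, g in prec.groupby("run_id")
            }
            precision_res = imprecision(runs, thresholds, analyte=code)
            if linearity_ok:
                nominal = float(prec["nominal_conc"].iloc[0])
                accuracy_pct = accuracy(
                    _concs(prec, curves, panel), nominal
                )

        loq_est = None
        loq = by_purpose.get("loq")
        if loq is not None and not loq.empty:
            levels = []
            for lv, g in sorted(loq.groupby("nominal_conc")):
                ratios = np.asarray(_ratios(g))
                levels.append(LoqLevel(
                    conc=float(lv),
                    cv_pct=_cv_pct(ratios),
                    mean_snr=float(np.mean(g["snr"].astype(float))),
                ))
            loq_est = estimate_loq(levels, thresholds)

        recovery_pct = None
        pre = by_purpose.get("recovery_pre")
        post = by_purpose.get("recovery_post")
        if pre is not None and post is not None:
            recovery_pct = recovery(
                pre["analyte_area"].astype(float),
                post["analyte_area"].astype(float),
            )

        me_pct = None
        mm = by_purpose.get("me_matrix")
        ms = by_purpose.get("me_solvent")
        if mm is not None and ms is not None:
            me_pct = matrix_effect(
                mm["analyte_area"].astype(float),
                ms["analyte_area"].astype(float),
            )

        carryover_pct = None
        co_h = by_purpose.get("carryover_high")
        co_b = by_purpose.get("carryover_blank")
        if co_h is not None and co_b is not None:
            carryover_pct = carryover(
                float(np.mean(co_b["analyte_area"].astype(float))),
                float(np.mean(co_h["analyte_area"].astype(float))),
            )

        hct_res = None
        hct_rows = by_purpose.get("hct")
        if hct_rows is not None and linearity_ok:
            by_h = []
            for h, g in hct_rows.groupby("hct"):
                by_h.append((float(h), float(np.mean(_concs(g, curves, panel)))))
            hct_res = hct_robustness(by_h, ref_hct, thresholds, analyte=code)

        stability_res: List[StabilityResult] = []
        stab = by_purpose.get("stability")
        if stab is not None and linearity_ok:
            for temp, g_t in stab.groupby("storage_temp_c"):
                series = [
                    (int(day), float(np.mean(_concs(g_d, curves, panel))))
                    for day, g_d in g_t.groupby("storage_days")
                ]
                stability_res.append(stability_assess(
                    series, thresholds, analyte=code, temp_c=float(temp)
                ))

        reports[code] = validation_report(
            code, thresholds,
            precision=precision_res,
            accuracy_pct=accuracy_pct,
            loq_est=loq_est,
            loq_claimed=spec.loq,
            recovery_pct=recovery_pct,
            matrix_effect_pct=me_pct,
            carryover_pct=carryover_pct,
            hct=hct_res,
            stability=stability_res,
            linearity_ok=linearity_ok,
        )
    return reports
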