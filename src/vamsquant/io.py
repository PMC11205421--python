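"""File formats, report serialization and pipeline drivers.

Interchange dialect is strict CSV (comma, UTF-8, '.' decimal; a different
delimiter may be passed explicitly). The long-format peak table has the
fixed header

    sample_id, analyte, role, run_id, day_index, analyte_area, istd_area,
    snr, nominal_conc, hct, storage_days, storage_temp_c

with optional trailing columns (e.g. ``purpose``) preserved. Reports are
JSON with a schema-version field and an embedded run manifest; numeric
values are stored at full precision and rounded only for display.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementResult, PairedSample, bland_altman
from .calibration import (
    CalibrationCurve,
    CensorFlag,
    curves_from_table,
    measurement_from_row,
    quantify,
)
from .compartment import HCT_STANDARD, serum_from_vams
from .panel import Panel, PartitionMode, ThresholdConfig
from .validation import ValidationReport

__all__ = [
    "PEAK_COLUMNS",
    "REPORT_SCHEMA_VERSION",
    "PeakTableError",
    "RunManifest",
    "read_peak_table",
    "write_peak_table",
    "read_paired_table",
    "quantify_peak_table",
    "paired_table_from_study",
    "compare_paired",
    "report_to_json",
    "agreement_to_json",
]

logger = logging.getLogger("vamsquant")

REPORT_SCHEMA_VERSION = 1

PEAK_COLUMNS = [
    "sample_id", "analyte", "role", "run_id", "day_index",
    "analyte_area", "istd_area", "snr", "nominal_conc", "hct",
    "storage_days", "storage_temp_c",
]
_MANDATORY = PEAK_COLUMNS[:7]
_ROLES = {"blank", "calibrator", "qc", "sample"}


class PeakTableError(ValueError):
    pass


@dataclass(frozen=True)
class RunManifest:
    """Provenance record embedded in every report."""

    command: str
    inputs: Tuple[str, ...] = ()
    config: Optional[str] = None
    seed: Optional[int] = None
    timestamp: str = ""
    version: str = __version__

    @classmethod
    def create(cls, command: str, inputs: Sequence[str] = (),
               config: Optional[str] = None,
               seed: Optional[int] = None) -> "RunManifest":
        return cls(
            command=command,
            inputs=tuple(str(p) for p in inputs),
            config=config,
            seed=seed,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def to_doc(self) -> dict:
        return dataclasses.asdict(self)


def read_peak_table(path: Union[str, Path], delimiter: str = ",") -> pd.DataFrame:
    """Read a long-format peak table CSV with strict schema validation.

    Empty optional cells become NaN (absent); role strings are trimmed and
    validated against the role enum; non-numeric areas are reported with
    their row number.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str,
                     keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing mandatory column(s) {missing}")
    for col in PEAK_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    out = df.copy()
    trimmed = df["role"].str.strip()
    if (trimmed != df["role"]).any():
        logger.info("%s: trimmed whitespace in role column", path)
    bad_roles = sorted(set(trimmed) - _ROLES)
    if bad_roles:
        raise PeakTableError(f"{path}: unknown role(s) {bad_roles}")
    out["role"] = trimmed
    for col in ("analyte_area", "istd_area", "snr", "nominal_conc", "hct",
                "storage_temp_c"):
        vals = []
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw == "":
                if col in ("analyte_area", "istd_area"):
                    raise PeakTableError(
                        f"{path}: row {i + 2}: {col} must not be empty"
                    )
                vals.append(math.nan)
                continue
            try:
                vals.append(float(raw))
            except ValueError:
                raise PeakTableError(
                    f"{path}: row {i + 2}: non-numeric {col} {raw!r}"
                ) from None
        out[col] = vals
    for col in ("day_index", "storage_days"):
        vals = []
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw == "":
                vals.append(math.nan)
                continue
            try:
                vals.append(int(float(raw)))
            except ValueError:
                raise PeakTableError(
                    f"{path}: row {i + 2}: non-integer {col} {raw!r}"
                ) from None
        out[col] = vals
    out["day_index"] = out["day_index"].fillna(0).astype(int)
    return out


def write_peak_table(df: pd.DataFrame, path: Union[str, Path],
                     delimiter: str = ",") -> None:
    """Write a peak table CSV (schema columns first, extras preserved)."""
    cols = [c for c in PEAK_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in PEAK_COLUMNS
    ]
    df[cols].to_csv(path, sep=delimiter, index=False)


def read_paired_table(path: Union[str, Path],
                      delimiter: str = ",") -> pd.DataFrame:
    """Read a paired-study table: subject_id, analyte, c_serum, c_vams."""
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in ("subject_id", "analyte", "c_serum", "c_vams")
               if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing column(s) {missing}")
    return df


# --- drivers ----------------------------------------------------------------

def quantify_peak_table(
    table: pd.DataFrame,
    panel: Panel,
    thresholds: ThresholdConfig,
    *,
    to_serum: bool = False,
    hct: Optional[float] = None,
    roles: Sequence[str] = ("sample", "qc"),
) -> pd.DataFrame:
    """Quantify every sample/QC row against its run's calibration curve.

    With ``to_serum`` the VAMS concentration is converted to its serum
    equivalent at the row's own hematocrit when present, else at ``hct``,
    else at the 0.40 standardization value. Conversions through a
    defaulted partition ratio are flagged in ``partition_defaulted``.
    """
    curves = curves_from_table(table, panel, thresholds)
    if not curves:
        raise PeakTableError("no calibrators in table: cannot quantify")
    rows = []
    for _, r in table[table["role"].isin(roles)].iterrows():
        m = measurement_from_row(r)
        key = (m.run_id, m.analyte)
        if key not in curves:
            raise PeakTableError(
                f"no calibration curve for run {m.run_id!r} / {m.analyte}"
            )
        spec = panel[m.analyte]
        conc, flag = quantify(m, curves[key], spec)
        rec = {
            "sample_id": m.sample_id, "analyte": m.analyte,
            "run_id": m.run_id, "conc_vams": conc, "flag": flag.value,
        }
        if to_serum:
            h = m.hct if m.hct is not None else hct
            if h is None:
                h = HCT_STANDARD
            serum, truncated = serum_from_vams(conc, h, spec, with_flag=True)
            rec.update({
                "hct_used": h,
                "conc_serum_eq": serum,
                "truncated": bool(truncated),
                "partition_defaulted": spec.partition.defaulted,
            })
        rows.append(rec)
    return pd.DataFrame(rows)


def paired_table_from_study(
    serum: pd.DataFrame,
    vams: pd.DataFrame,
    panel: Panel,
    thresholds: ThresholdConfig,
) -> pd.DataFrame:
    """Assemble the paired comparison table from a paired-study run.

    Quantifies the VAMS subject rows against the run's calibration,
    converts them to serum equivalents at each row's own hematocrit,
    averages replicates per subject, and joins the serum measurements.
    Subject sample ids must be ``<subject_id>-<analyte>-rep<k>``.
    """
    q = quantify_peak_table(vams, panel, thresholds, to_serum=True,
                            roles=("sample",))
    q = q.copy()
    # sample ids are <subject>-<analyte>-rep<k>; analyte codes may
    # themselves contain hyphens, so strip the known suffix pieces
    q["subject_id"] = [
        sid.rsplit("-rep", 1)[0].removesuffix(f"-{analyte}")
        for sid, analyte in zip(q["sample_id"], q["analyte"])
    ]
    mean_vams = (
        q.groupby(["subject_id", "analyte"], sort=False)["conc_serum_eq"]
        .mean().reset_index().rename(columns={"conc_serum_eq": "c_vams"})
    )
    return serum.merge(mean_vams, on=["subject_id", "analyte"])


def compare_paired(
    paired: pd.DataFrame, *, direction: str = "serum-vams"
) -> Tuple[Dict[str, AgreementResult], pd.DataFrame]:
    """Bland–Altman agreement per analyte from a paired table.

    Returns the per-analyte results and a tidy plot-data table
    (subject, analyte, mean, difference, percent difference).
    """
    results: Dict[str, AgreementResult] = {}
    plot_rows = []
    for analyte, grp in paired.groupby("analyte", sort=False):
        pairs = [
            PairedSample(str(r["subject_id"]), str(analyte),
                         float(r["c_serum"]), float(r["c_vams"]))
            for _, r in grp.iterrows()
        ]
        res = bland_altman(pairs, direction=direction)
        results[str(analyte)] = res
        for p in pairs:
            d = (p.c_serum - p.c_vams_corrected
                 if direction == "serum-vams"
                 else p.c_vams_corrected - p.c_serum)
            mean = (p.c_serum + p.c_vams_corrected) / 2
            plot_rows.append({
                "subject_id": p.subject_id, "analyte": analyte,
                "mean": mean, "difference": d,
                "pct_difference": 100.0 * d / mean if mean else math.nan,
            })
    return results, pd.DataFrame(plot_rows)


# --- report rendering -------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float):
        if math.isinf(obj):
            return "not_reached" if obj > 0 else "-inf"
        if math.isnan(obj):
            return None
        return obj
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, bool)) or obj is None:
        return obj
    return str(obj)


def report_to_json(
    reports: Mapping[str, ValidationReport],
    manifest: RunManifest,
    curves: Optional[Mapping[Tuple[str, str], CalibrationCurve]] = None,
) -> str:
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manifest": manifest.to_doc(),
        "blank_correction": "subtracted from calibrators and unknowns",
        "validation": {code: _jsonable(rep) for code, rep in reports.items()},
    }
    if curves:
        doc["calibration"] = {
            f"{run}/{analyte}": _jsonable(c)
            for (run, analyte), c in curves.items()
        }
    return json.dumps(doc, indent=2)


def agreement_to_json(
    results: Mapping[str, AgreementResult], manifest: RunManifest
) -> str:
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "manifest": manifest.to_doc(),
        "agreement": {a: _jsonable(r) for a, r in results.items()},
    }
    return json.dumps(doc, indent=2)
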