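"""Analyte panel registry.

Single source of truth for the eight-hormone capillary-blood (VAMS) panel:
identity, MS acquisition metadata (documentation only), blood-compartment
partition behaviour, limits of quantification, working ranges, and the
numeric acceptance thresholds applied throughout method validation.

Concentrations are ng/mL everywhere; hematocrit is a volume fraction.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Tuple

import yaml

__all__ = [
    "PartitionMode",
    "PartitionSpec",
    "MSMeta",
    "AnalyteSpec",
    "ThresholdConfig",
    "Panel",
    "PanelError",
    "default_panel",
    "load_panel",
    "dump_panel",
]


class PanelError(ValueError):
    """Raised for panel configuration violations; names the offending field."""


class PartitionMode(str, enum.Enum):
    """How a hormone distributes between serum and red blood cells."""

    RATIO = "ratio"   # equilibrium plasma-to-RBC concentration ratio
    FIXED = "fixed"   # RBC concentration is a constant, independent of serum


@dataclass(frozen=True)
class PartitionSpec:
    """Serum/RBC partition behaviour of one analyte.

    mode=RATIO uses ``plasma_to_rbc_ratio`` (r > 0): c_rbc = c_serum / r.
    mode=FIXED uses ``fixed_rbc_conc`` (ng/mL ≥ 0): c_rbc is constant.
    ``defaulted`` marks ratios not established experimentally for this
    analyte (a documented fallback); serum conversions carry a warning flag.
    """

    mode: PartitionMode
    plasma_to_rbc_ratio: Optional[float] = None
    fixed_rbc_conc: Optional[float] = None
    defaulted: bool = False

    def __post_init__(self) -> None:
        mode = PartitionMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is PartitionMode.RATIO:
            if self.fixed_rbc_conc is not None:
                raise PanelError(
                    "fixed_rbc_conc must not be set when mode is 'ratio'"
                )
            if self.plasma_to_rbc_ratio is None or not self.plasma_to_rbc_ratio > 0:
                raise PanelError("plasma_to_rbc_ratio must be > 0")
        else:
            if self.plasma_to_rbc_ratio is not None:
                raise PanelError(
                    "plasma_to_rbc_ratio must not be set when mode is 'fixed'"
                )
            if self.fixed_rbc_conc is None or self.fixed_rbc_conc < 0:
                raise PanelError("fixed_rbc_conc must be >= 0")


@dataclass(frozen=True)
class MSMeta:
    """LC-MS acquisition metadata. Documentation only — never computed on."""

    precursor_mz: float
    quantifier_mz: float
    qualifier_mz: Optional[float] = None
    retention_time_min: Optional[float] = None
    collision_energy_ev: Optional[float] = None


@dataclass(frozen=True)
class AnalyteSpec:
    """One hormone of the panel with all constants the pipeline needs."""

    name: str
    short_code: str
    partition: PartitionSpec
    loq: float                              # ng/mL
    calibration_range: Tuple[float, float]  # (low, high) ng/mL, VAMS scale
    istd_name: str
    blank_residual: float = 0.0             # endogenous level in blank matrix
    ms_meta: Optional[MSMeta] = None

    def __post_init__(self) -> None:
        if not self.loq > 0:
            raise PanelError(f"{self.short_code}: loq must be > 0")
        low, high = self.calibration_range
        object.__setattr__(self, "calibration_range", (float(low), float(high)))
        if not low < high:
            raise PanelError(
                f"{self.short_code}: calibration_range.low must be < high"
            )
        if self.loq > high:
            raise PanelError(
                f"{self.short_code}: loq must not exceed calibration_range.high"
            )
        if self.blank_residual < 0:
            raise PanelError(f"{self.short_code}: blank_residual must be >= 0")


@dataclass(frozen=True)
class ThresholdConfig:
    """Numeric acceptance criteria of the validation battery (FDA-style).

    All values strictly positive; r2_min < 1.
    """

    cv_max_pct: float = 15.0          # intra-/interday imprecision
    accuracy_tol_pct: float = 15.0    # |accuracy − 100|
    loq_cv_max_pct: float = 20.0      # CV gate at the LOQ
    loq_min_snr: float = 10.0         # signal-to-noise gate at the LOQ
    stability_tol_pct: float = 15.0   # deviation from day-0 concentration
    hct_dev_max_pct: float = 20.0     # deviation vs the Hct-0.40 reference
    carryover_max_pct: float = 0.01   # blank-after-high as % of high signal
    r2_min: float = 0.99              # calibration linearity

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise PanelError(f"{f.name} must be > 0")
        if not self.r2_min < 1:
            raise PanelError("r2_min must be < 1")


class Panel(Mapping[str, AnalyteSpec]):
    """Ordered, immutable mapping short_code -> AnalyteSpec."""

    def __init__(self, analytes: Sequence[AnalyteSpec]):
        codes = [a.short_code for a in analytes]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise PanelError(f"duplicate analyte code(s): {sorted(dupes)}")
        self._specs = {a.short_code: a for a in analytes}

    def __getitem__(self, code: str) -> AnalyteSpec:
        return self._specs[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return list(self._specs.items()) == list(other._specs.items())

    def __repr__(self) -> str:
        return f"Panel({list(self._specs)})"

    @property
    def analytes(self) -> Tuple[AnalyteSpec, ...]:
        return tuple(self._specs.values())


# --- default eight-analyte panel -------------------------------------------
#
# Partition ratios: the testosterone (4:1) and corticosterone (5:1)
# plasma-to-RBC ratios are applied to A4/DHEA-S/T and F respectively; T3 uses
# the literature 3.2:1; T4 uses a fixed RBC level of 0.54 ng/mL (mean of the
# reported 0.30–0.78 range). P4 and E2 have no established ratio: they fall
# back to the 4:1 steroid default with defaulted=True, so any serum
# conversion flags the uncertainty. Blank-matrix endogenous residuals were
# measurable for DHEA-S (45), T (0.001) and T4 (0.15 ng/mL).
#
# Calibration ranges are config-driven working ranges chosen to span each
# analyte's LOQ and the physiological concentration scale (ng/mL, VAMS).

_RATIO_STEROID = 4.0
_RATIO_F = 5.0
_RATIO_T3 = 3.2
_T4_RBC_FIXED = 0.54

_DEFAULTS = [
    # (name, code, partition, loq, cal_range, istd, blank_residual, ms_meta)
    ("4-Androstenedione", "A4",
     PartitionSpec(PartitionMode.RATIO, _RATIO_STEROID),
     0.5, (0.5, 50.0), "testosterone-d3", 0.0,
     MSMeta(287.2011, 97.07, 109.06, 8.36, 30)),
    ("Cortisol", "F",
     PartitionSpec(PartitionMode.RATIO, _RATIO_F),
     2.5, (2.5, 250.0), "cortisol-d4", 0.0,
     MSMeta(363.2171, 121.07, 327.20, 7.45, 25)),
    ("DHEA-S", "DHEA-S",
     PartitionSpec(PartitionMode.RATIO, _RATIO_STEROID),
     2.5, (2.5, 3000.0), "testosterone-d3", 45.0,
     MSMeta(367.1578, 96.96, None, 8.22, 35)),
    ("Progesterone", "P4",
     PartitionSpec(PartitionMode.RATIO, _RATIO_STEROID, defaulted=True),
     0.8, (0.8, 30.0), "progesterone-d9", 0.0,
     MSMeta(315.2324, 109.06, 97.06, 9.36, 20)),
    ("Testosterone", "T",
     PartitionSpec(PartitionMode.RATIO, _RATIO_STEROID),
     0.02, (0.02, 10.0), "testosterone-d3", 0.001,
     MSMeta(289.2167, 97.07, 109.06, 8.64, 25)),
    ("Triiodothyronine", "T3",
     PartitionSpec(PartitionMode.RATIO, _RATIO_T3),
     0.1, (0.1, 5.0), "T3-13C6", 0.0,
     MSMeta(651.7978, 605.79, 507.87, 7.83, 20)),
    ("Thyroxine", "T4",
     PartitionSpec(PartitionMode.FIXED, fixed_rbc_conc=_T4_RBC_FIXED),
     0.5, (0.5, 150.0), "T4-13C6", 0.15,
     MSMeta(777.6866, 731.69, 633.76, 8.37, 25)),
    ("17beta-Estradiol", "E2",
     PartitionSpec(PartitionMode.RATIO, _RATIO_STEROID, defaulted=True),
     0.04, (0.04, 2.0), "estradiol-d4", 0.0,
     MSMeta(431.1926, 367.2, None, 9.26, 50)),
]


def default_panel() -> Panel:
    """Return the default eight-analyte steroid/thyroid panel."""
    return Panel([AnalyteSpec(*row) for row in _DEFAULTS])


# --- serialization ----------------------------------------------------------

_ANALYTE_FIELDS = {
    "name", "short_code", "partition", "loq", "calibration_range",
    "istd_name", "blank_residual", "ms_meta",
}
_PARTITION_FIELDS = {"mode", "value", "defaulted"}


def _partition_to_doc(p: PartitionSpec) -> dict:
    value = (
        p.plasma_to_rbc_ratio if p.mode is PartitionMode.RATIO
        else p.fixed_rbc_conc
    )
    doc = {"mode": p.mode.value, "value": value}
    if p.defaulted:
        doc["defaulted"] = True
    return doc


def _partition_from_doc(doc: Mapping, ctx: str) -> PartitionSpec:
    if not isinstance(doc, Mapping):
        raise PanelError(f"{ctx}: partition must be a mapping {{mode, value}}")
    unknown = set(doc) - _PARTITION_FIELDS
    if unknown:
        raise PanelError(f"{ctx}: unknown partition field(s) {sorted(unknown)}")
    try:
        mode = PartitionMode(doc["mode"])
    except (KeyError, ValueError) as exc:
        raise PanelError(f"{ctx}: partition.mode must be 'ratio' or 'fixed'") from exc
    value = doc.get("value")
    if value is None:
        raise PanelError(f"{ctx}: partition.value is required")
    kwargs = dict(defaulted=bool(doc.get("defaulted", False)))
    if mode is PartitionMode.RATIO:
        if not float(value) > 0:
            raise PanelError(f"{ctx}: plasma_to_rbc_ratio must be > 0")
        return PartitionSpec(mode, plasma_to_rbc_ratio=float(value), **kwargs)
    if float(value) < 0:
        raise PanelError(f"{ctx}: fixed_rbc_conc must be >= 0")
    return PartitionSpec(mode, fixed_rbc_conc=float(value), **kwargs)


def _analyte_to_doc(a: AnalyteSpec) -> dict:
    doc = {
        "name": a.name,
        "short_code": a.short_code,
        "partition": _partition_to_doc(a.partition),
        "loq": a.loq,
        "calibration_range": list(a.calibration_range),
        "istd_name": a.istd_name,
        "blank_residual": a.blank_residual,
    }
    if a.ms_meta is not None:
        doc["ms_meta"] = {
            k: v for k, v in dataclasses.asdict(a.ms_meta).items() if v is not None
        }
    return doc


def _analyte_from_doc(doc: Mapping) -> AnalyteSpec:
    if not isinstance(doc, Mapping):
        raise PanelError("each analyte record must be a mapping")
    code = doc.get("short_code", "<missing short_code>")
    unknown = set(doc) - _ANALYTE_FIELDS
    if unknown:
        raise PanelError(f"{code}: unknown field(s) {sorted(unknown)}")
    missing = {"name", "short_code", "partition", "loq",
               "calibration_range", "istd_name"} - set(doc)
    if missing:
        raise PanelError(f"{code}: missing required field(s) {sorted(missing)}")
    ms_meta = None
    if doc.get("ms_meta") is not None:
        ms_meta = MSMeta(**doc["ms_meta"])
    rng = doc["calibration_range"]
    if not (isinstance(rng, Sequence) and len(rng) == 2):
        raise PanelError(f"{code}: calibration_range must be [low, high]")
    return AnalyteSpec(
        name=str(doc["name"]),
        short_code=str(doc["short_code"]),
        partition=_partition_from_doc(doc["partition"], str(code)),
        loq=float(doc["loq"]),
        calibration_range=(float(rng[0]), float(rng[1])),
        istd_name=str(doc["istd_name"]),
        blank_residual=float(doc.get("blank_residual", 0.0)),
        ms_meta=ms_meta,
    )


def dump_panel(panel: Panel, fmt: str = "yaml") -> str:
    """Serialize a panel to a YAML (default) or JSON document string."""
    docs = [_analyte_to_doc(a) for a in panel.analytes]
    if fmt == "yaml":
        return yaml.safe_dump(docs, sort_keys=False)
    if fmt == "json":
        return json.dumps(docs, indent=2)
    raise ValueError(f"unknown format {fmt!r}")


def load_panel(document: str | Sequence[Mapping]) -> Panel:
    """Parse a panel configuration (YAML/JSON text or a parsed list).

    All AnalyteSpec invariants are enforced; unknown fields and duplicate
    short codes are rejected with errors naming the offending field.
    """
    if isinstance(document, str):
        parsed = yaml.safe_load(document)  # YAML is a JSON superset
    else:
        parsed = document
    if not isinstance(parsed, Sequence) or isinstance(parsed, (str, bytes)):
        raise PanelError("panel document must be a top-level list of analytes")
    return Panel([_analyte_from_doc(d) for d in parsed])
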