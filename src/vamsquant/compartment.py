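"""Whole-blood two-compartment model for VAMS samples.

A dried VAMS tip holds whole blood: a serum fraction (1 − Hct) and a red
blood cell fraction (Hct). The total tip concentration is the volume-
weighted mixture

    c_vams = (1 − h) · c_serum + h · c_rbc

with the RBC concentration tied to serum by the analyte's partition
behaviour: c_rbc = c_serum / r for a plasma-to-RBC ratio r, or a fixed
constant (thyroxine). At the standardization hematocrit of 0.40 this is the
familiar 0.6/0.4 split (18 µL serum in a 30 µL tip).

Back-conversion to a serum equivalent solves the two linear relations
simultaneously; for ratio-mode analytes the closed form is

    c_serum = c_vams / ((1 − h) + h / r)

which is exact and order-free. The same machinery predicts the relative
hematocrit bias of a measurement calibrated at Hct 0.40.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .panel import AnalyteSpec, PartitionMode

__all__ = [
    "HCT_STANDARD",
    "VAMS_VOLUME_UL",
    "PartitionContext",
    "ConcentrationSet",
    "HctBiasProfile",
    "rbc_from_serum",
    "vams_from_serum",
    "serum_from_vams",
    "hct_bias_profile",
]

#: Standardization hematocrit used to prepare calibrators and QCs.
HCT_STANDARD = 0.40
#: Nominal blood volume absorbed by one VAMS tip (µL).
VAMS_VOLUME_UL = 30.0

_HCT_MAX = 0.95

ArrayLike = Union[float, np.ndarray]


def _check_hct(hct: ArrayLike) -> None:
    h = np.asarray(hct, dtype=float)
    if np.any(h < 0) or np.any(h > _HCT_MAX):
        raise ValueError(f"hct must be within [0, {_HCT_MAX}], got {hct!r}")


@dataclass(frozen=True)
class PartitionContext:
    """Volume split of a whole-blood sample at a given hematocrit."""

    hct: float

    def __post_init__(self) -> None:
        _check_hct(self.hct)

    @property
    def serum_fraction(self) -> float:
        return 1.0 - self.hct

    @property
    def rbc_fraction(self) -> float:
        return self.hct

    def serum_volume_ul(self, total_ul: float = VAMS_VOLUME_UL) -> float:
        """Serum volume (µL) of a tip of ``total_ul`` at this hematocrit."""
        return self.serum_fraction * total_ul


@dataclass(frozen=True)
class ConcentrationSet:
    """A consistent (serum, RBC, total VAMS) concentration triple, ng/mL."""

    c_serum: float
    c_rbc: float
    c_vams: float
    hct: float = HCT_STANDARD

    def __post_init__(self) -> None:
        _check_hct(self.hct)
        for name in ("c_serum", "c_rbc", "c_vams"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mix = (1.0 - self.hct) * self.c_serum + self.hct * self.c_rbc
        scale = max(abs(self.c_vams), abs(mix), 1e-300)
        if abs(self.c_vams - mix) > 1e-9 * scale:
            raise ValueError(
                "c_vams is inconsistent with the serum/RBC mixture "
                f"({self.c_vams} vs {mix})"
            )


def rbc_from_serum(c_serum: ArrayLike, spec: AnalyteSpec) -> ArrayLike:
    """RBC concentration implied by a serum concentration.

    Ratio mode: c_serum / r. Fixed mode: the constant RBC level regardless
    of c_serum.
    """
    c = np.asarray(c_serum, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_serum must be >= 0")
    if spec.partition.mode is PartitionMode.FIXED:
        out = np.full_like(c, spec.partition.fixed_rbc_conc)
    else:
        out = c / spec.partition.plasma_to_rbc_ratio
    return out if out.ndim else float(out)


def vams_from_serum(
    c_serum: ArrayLike, hct: ArrayLike, spec: AnalyteSpec
) -> ArrayLike:
    """Total VAMS (whole-blood) concentration from a serum concentration.

    c_vams = (1 − h)·c_serum + h·c_rbc with c_rbc from the partition spec.
    At h = 0 this returns c_serum.
    """
    _check_hct(hct)
    c = np.asarray(c_serum, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_serum must be >= 0")
    h = np.asarray(hct, dtype=float)
    out = (1.0 - h) * c + h * np.asarray(rbc_from_serum(c, spec))
    return out if out.ndim else float(out)


def serum_from_vams(
    c_vams: ArrayLike,
    hct: ArrayLike,
    spec: AnalyteSpec,
    *,
    with_flag: bool = False,
) -> Union[ArrayLike, Tuple[ArrayLike, Union[bool, np.ndarray]]]:
    """Serum-equivalent concentration from a total VAMS concentration.

    Ratio mode uses the exact simultaneous solution
    c_serum = c_vams / ((1 − h) + h/r); fixed mode uses
    (c_vams − h·c_rbc) / (1 − h), floored at 0. With ``with_flag=True`` the
    second return value marks fixed-mode results truncated at zero (a
    near-blank sample whose RBC constant exceeds the measured total).
    """
    _check_hct(hct)
    h = np.asarray(hct, dtype=float)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("hct = 1 leaves no serum compartment")
    c = np.asarray(c_vams, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_vams must be >= 0")
    if spec.partition.mode is PartitionMode.RATIO:
        r = spec.partition.plasma_to_rbc_ratio
        out = c / ((1.0 - h) + h / r)
        trunc = np.zeros_like(out, dtype=bool)
    else:
        raw = (c - h * spec.partition.fixed_rbc_conc) / (1.0 - h)
        trunc = raw < 0
        out = np.maximum(raw, 0.0)
    if not out.ndim:
        out = float(out)
        trunc = bool(trunc)
    if with_flag:
        return out, trunc
    return out


@dataclass(frozen=True)
class HctBiasProfile:
    """Predicted relative measurement deviation across hematocrit.

    ``points`` holds (hct, deviation %) relative to the reference
    hematocrit; ``pass_range`` is the contiguous sub-range of the grid
    around the reference where |deviation| stays within the tolerance.
    """

    analyte: str
    ref_hct: float
    points: Tuple[Tuple[float, float], ...]
    pass_range: Tuple[float, float]

    def deviation_at(self, hct: float) -> float:
        for h, d in self.points:
            if abs(h - hct) < 1e-12:
                return d
        raise KeyError(f"hct {hct} not in profile grid")


def hct_bias_profile(
    spec: AnalyteSpec,
    hct_grid: Sequence[float],
    ref_hct: float = HCT_STANDARD,
    *,
    tol_pct: float = 20.0,
    test_conc: Optional[float] = None,
) -> HctBiasProfile:
    """Relative bias of an uncorrected measurement calibrated at ``ref_hct``.

    deviation(h) = 100·(c_vams(h)/c_vams(ref) − 1) for a sample of fixed
    serum concentration. For ratio-mode analytes this is independent of the
    concentration (asserted internally at three decades); fixed-mode
    analytes require ``test_conc``.
    """
    grid = [float(h) for h in hct_grid]
    if not grid:
        raise ValueError("hct_grid must not be empty")
    _check_hct(grid)
    _check_hct(ref_hct)

    if spec.partition.mode is PartitionMode.RATIO:
        concs = (0.01, 1.0, 1000.0) if test_conc is None else (test_conc,)
    else:
        if test_conc is None:
            raise ValueError("fixed-mode partition requires test_conc")
        concs = (test_conc,)

    devs = None
    for c in concs:
        ref = vams_from_serum(c, ref_hct, spec)
        if ref <= 0:
            raise ValueError("reference VAMS concentration is zero")
        cur = [100.0 * (vams_from_serum(c, h, spec) / ref - 1.0) for h in grid]
        if devs is None:
            devs = cur
        elif not np.allclose(devs, cur, rtol=1e-9, atol=1e-12):
            raise AssertionError(
                "ratio-mode hct bias unexpectedly depends on concentration"
            )

    order = np.argsort(grid)
    pts = [(grid[i], devs[i]) for i in order]
    # contiguous passing sub-range containing the reference hematocrit
    ok = [abs(d) <= tol_pct for _, d in pts]
    hs = [h for h, _ in pts]
    i_ref = int(np.argmin([abs(h - ref_hct) for h in hs]))
    if not ok[i_ref]:
        lo = hi = ref_hct
    else:
        lo_i = i_ref
        while lo_i > 0 and ok[lo_i - 1]:
            lo_i -= 1
        hi_i = i_ref
        while hi_i < len(hs) - 1 and ok[hi_i + 1]:
            hi_i += 1
        lo, hi = hs[lo_i], hs[hi_i]
    return HctBiasProfile(
        analyte=spec.short_code,
        ref_hct=float(ref_hct),
        points=tuple(pts),
        pass_range=(lo, hi),
    )
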