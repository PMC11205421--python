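"""Paired serum vs corrected-VAMS agreement analysis.

Bland–Altman statistics on paired concentration measurements: mean
difference (bias), SD of differences, 95% limits of agreement
LoA = bias ± 1.96·SD, t-based confidence intervals for the bias
(var sd²/n) and for each limit (large-sample var 3·sd²/n), percentage
differences relative to the pairwise mean for plotting, Shapiro–Wilk
normality screening of the differences, and a paired significance test
(paired t by default, Wilcoxon signed-rank fallback for non-normal
differences).

Difference direction is fixed to serum − corrected VAMS; flipping the
direction negates the bias and swaps/negates the limits while leaving
p-values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "Z_LOA",
    "PairedSample",
    "AgreementResult",
    "AgreementError",
    "loa_midpoint",
    "bland_altman",
    "paired_comparison",
]

#: Normal quantile used for the 95% limits of agreement.
Z_LOA = 1.96


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSample:
    """One subject's paired serum and serum-equivalent VAMS concentration."""

    subject_id: str
    analyte: str
    c_serum: float
    c_vams_corrected: float

    def __post_init__(self) -> None:
        if self.c_serum < 0 or self.c_vams_corrected < 0:
            raise AgreementError("concentrations must be >= 0")


@dataclass(frozen=True)
class AgreementResult:
    analyte: str
    n: int
    bias: float                      # mean difference, ng/mL
    sd_diff: float                   # sample SD (n − 1)
    loa_low: float
    loa_high: float
    ci_bias: Tuple[float, float]
    ci_loa_low: Tuple[float, float]
    ci_loa_high: Tuple[float, float]
    shapiro_p: float
    paired_p: float
    paired_t_p: float                # always reported, whatever test_used
    test_used: str
    pct_differences: Tuple[float, ...]
    excluded_pairs: Tuple[str, ...] = ()   # zero-mean pairs dropped from %
    degenerate: bool = False


def loa_midpoint(loa_low: float, loa_high: float) -> float:
    """Midpoint of symmetric limits of agreement — recovers the bias."""
    if loa_low > loa_high:
        raise AgreementError("loa_low must be <= loa_high")
    return (loa_low + loa_high) / 2.0


def paired_comparison(
    serum: Sequence[float],
    vams: Sequence[float],
    *,
    allow_wilcoxon: bool = True,
) -> Tuple[float, float, str]:
    """Normality screening and paired significance test on differences.

    Shapiro–Wilk on serum − vams; if p ≥ 0.05 (or the fallback is
    disabled) a two-sided paired t-test, otherwise a Wilcoxon signed-rank
    test flagged by the returned test name. All-zero differences are
    degenerate: p = 1.
    """
    d = np.asarray(serum, dtype=float) - np.asarray(vams, dtype=float)
    if d.size < 3:
        raise AgreementError("need >= 3 pairs")
    if np.all(d == 0):
        return 1.0, 1.0, "degenerate"
    if np.std(d, ddof=1) == 0:
        # constant nonzero shift: normality untestable, t-test undefined
        return 1.0, 0.0, "degenerate"
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= 0.05 or not allow_wilcoxon:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
        test = "paired-t"
    else:
        p = float(stats.wilcoxon(d).pvalue)
        test = "wilcoxon"
    return shapiro_p, p, test


def bland_altman(
    pairs: Sequence[PairedSample],
    *,
    direction: str = "serum-vams",
    allow_wilcoxon: bool = True,
) -> AgreementResult:
    """Bland–Altman agreement statistics for one analyte's paired samples.

    ``direction`` is ``"serum-vams"`` (default) or ``"vams-serum"``.
    Percentage differences (plot convention: difference over pairwise
    mean) drop pairs whose mean is zero and record them in
    ``excluded_pairs``.
    """
    n = len(pairs)
    if n < 3:
        raise AgreementError("need >= 3 pairs")
    analytes = {p.analyte for p in pairs}
    if len(analytes) > 1:
        raise AgreementError(f"mixed analytes in one comparison: {analytes}")
    serum = np.array([p.c_serum for p in pairs])
    vams = np.array([p.c_vams_corrected for p in pairs])
    if direction == "serum-vams":
        d = serum - vams
    elif direction == "vams-serum":
        d = vams - serum
    else:
        raise AgreementError(f"unknown direction {direction!r}")

    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low = bias - Z_LOA * sd
    loa_high = bias + Z_LOA * sd
    t = float(stats.t.ppf(0.975, n - 1))
    half_bias = t * sd / np.sqrt(n)
    half_loa = t * sd * np.sqrt(3.0 / n)

    means = (serum + vams) / 2.0
    pct: List[float] = []
    excluded: List[str] = []
    for p, di, mi in zip(pairs, d, means):
        if mi == 0:
            excluded.append(p.subject_id)
        else:
            pct.append(100.0 * di / mi)

    if np.all(d == d[0]):
        shapiro_p, paired_p, test = (
            (1.0, 1.0, "degenerate") if d[0] == 0 else (1.0, 0.0, "degenerate")
        )
        t_p = paired_p
    else:
        a, b = (serum, vams) if direction == "serum-vams" else (vams, serum)
        shapiro_p, paired_p, test = paired_comparison(
            a, b, allow_wilcoxon=allow_wilcoxon
        )
        t_p = (paired_p if test == "paired-t"
               else float(stats.ttest_1samp(d, 0.0).pvalue))

    return AgreementResult(
        analyte=next(iter(analytes)),
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_low=(loa_low - half_loa, loa_low + half_loa),
        ci_loa_high=(loa_high - half_loa, loa_high + half_loa),
        shapiro_p=shapiro_p,
        paired_p=paired_p,
        paired_t_p=t_p,
        test_used=test,
        pct_differences=tuple(pct),
        excluded_pairs=tuple(excluded),
        degenerate=(test == "degenerate"),
    )
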