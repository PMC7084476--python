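"""Boxplot / interquartile-range outlier screening per exposure window.

A result is an outlier when it lies more than 1.5·IQR above the third
quartile or below the first quartile (Tukey fences).  The screen also
recomputes the robust consensus without the flagged results so the
sensitivity of the assigned value to outlier removal can be checked: the
two variants are declared statistically indistinguishable when they differ
by less than two combined standard uncertainties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .campaign import ExposureWindow, ParticipantCode, Submission
from .consensus import InsufficientDataError, algorithm_a, uncertainty_of_reference

__all__ = ["OutlierReport", "iqr_outliers", "sensitivity_check", "quartiles"]


def quartiles(values: Sequence[float], method: str = "linear") -> tuple[float, float]:
    """First and third quartiles.

    ``method="linear"`` interpolates order statistics (the spreadsheet
    default); ``method="tukey"`` uses Tukey hinges (medians of the lower and
    upper halves, the median included in both when the count is odd).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if method == "linear":
        q1, q3 = np.percentile(x, [25, 75], method="linear")
        return float(q1), float(q3)
    if method == "tukey":
        n = x.size
        half = (n + 1) // 2
        return float(np.median(x[:half])), float(np.median(x[n - half:]))
    raise ValueError(f"unknown quartile method {method!r}")


@dataclass(frozen=True)
class OutlierReport:
    window_label: str
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outlier_codes: list[ParticipantCode]
    e_ref_all: float
    u_e_ref_all: float
    p_all: int
    e_ref_without_outliers: float
    u_e_ref_without_outliers: float
    p_without_outliers: int


def iqr_outliers(
    submissions: Sequence[Submission],
    window: ExposureWindow,
    quartile_method: str = "linear",
) -> OutlierReport:
    """Flag results strictly outside the 1.5·IQR fences and recompute the
    consensus without them.

    Values exactly on a fence are not outliers.  Needs at least 4 results
    for quartiles to be meaningful.
    """
    subs = [s for s in submissions if s.window_label == window.label]
    if len(subs) < 4:
        raise InsufficientDataError(
            f"IQR screen needs >= 4 results for window {window.label}, got {len(subs)}"
        )
    values = np.array([s.exposure for s in subs], dtype=float)
    q1, q3 = quartiles(values, quartile_method)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = [s for s, v in zip(subs, values) if v < lower or v > upper]
    flagged_codes = [s.code for s in flagged]

    res_all = algorithm_a(values)
    u_all = uncertainty_of_reference(res_all.s_star, values.size)

    kept = values[(values >= lower) & (values <= upper)]
    if kept.size >= 2:
        res_kept = algorithm_a(kept)
        e_kept, u_kept, p_kept = (
            res_kept.e_ref,
            uncertainty_of_reference(res_kept.s_star, kept.size),
            int(kept.size),
        )
    else:  # pathological: nearly everything flagged; fall back to the full set
        e_kept, u_kept, p_kept = res_all.e_ref, u_all, int(values.size)

    return OutlierReport(
        window_label=window.label,
        q1=q1,
        q3=q3,
        iqr=iqr,
        lower_fence=lower,
        upper_fence=upper,
        outlier_codes=flagged_codes,
        e_ref_all=res_all.e_ref,
        u_e_ref_all=u_all,
        p_all=int(values.size),
        e_ref_without_outliers=e_kept,
        u_e_ref_without_outliers=u_kept,
        p_without_outliers=p_kept,
    )


def sensitivity_check(report: OutlierReport) -> bool:
    """True when the all-results and outlier-free assigned values agree
    within two combined standard uncertainties."""
    return abs(report.e_ref_all - report.e_ref_without_outliers) <= 2.0 * math.hypot(
        report.u_e_ref_all, report.u_e_ref_without_outliers
    )
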