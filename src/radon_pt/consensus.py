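"""Robust consensus (assigned) value per exposure window.

The assigned value E_ref and robust standard deviation s* come from
ISO 13528:2015 Algorithm A: initialise at the median and the scaled median
absolute deviation (1.483·MAD), then repeatedly winsorize at E_ref ± 1.5·s*
and re-estimate E_ref as the mean and s* as 1.134 times the standard
deviation of the winsorized values.  The standard uncertainty of the
assigned value is u(E_ref) = 1.25·s*/√p, and the assigned value is fit for
proficiency assessment when u(E_ref) < 0.3·σp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .campaign import ExposureWindow, Submission

__all__ = [
    "AlgorithmAResult",
    "ConsensusResult",
    "InsufficientDataError",
    "algorithm_a",
    "uncertainty_of_reference",
    "consensus_for_window",
]


class InsufficientDataError(ValueError):
    """Fewer results than the operation can work with."""


@dataclass(frozen=True)
class AlgorithmAResult:
    e_ref: float
    s_star: float
    iterations: int
    converged: bool
    degenerate: bool  # True when the initial MAD was zero (no spread to iterate on)


@dataclass(frozen=True)
class ConsensusResult:
    """Assigned value of one exposure window and its quality bookkeeping.

    sigma_p is the standard deviation for proficiency assessment, a fixed
    fraction of E_ref; criterion_ok records u(E_ref) < 0.3·sigma_p.
    """

    window_label: str
    e_ref: float
    s_star: float
    u_e_ref: float
    p: int
    sigma_p: float
    iterations: int
    converged: bool
    criterion_ok: bool
    degenerate: bool = False
    low_count_warning: bool = False


def algorithm_a(
    values: Sequence[float],
    tolerance: float = 1e-9,
    max_iterations: int = 1000,
    sd_ddof: int = 1,
) -> AlgorithmAResult:
    """Robust average and robust standard deviation by iterative winsorization.

    Parameters
    ----------
    values
        At least two finite results.
    tolerance
        Relative change of both E_ref and s* below which iteration stops.
    sd_ddof
        Delta degrees of freedom of the winsorized standard deviation
        (1 = sample form, the default; 0 = population form).

    The result is invariant under permutation of the inputs and equivariant
    under affine rescaling.  If the initial MAD is zero the winsorization
    interval collapses, so the median is returned immediately with s* = 0
    and the ``degenerate`` flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientDataError(
            f"Algorithm A needs at least 2 values, got {x.size}"
        )
    if np.any(~np.isfinite(x)):
        raise ValueError("Algorithm A input contains non-finite values")

    e_ref = float(np.median(x))
    s_star = 1.483 * float(np.median(np.abs(x - e_ref)))
    if s_star == 0.0:
        return AlgorithmAResult(e_ref, 0.0, 0, True, True)

    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        delta = 1.5 * s_star
        w = np.clip(x, e_ref - delta, e_ref + delta)
        e_new = float(w.mean())
        s_new = 1.134 * float(w.std(ddof=sd_ddof))
        de = abs(e_new - e_ref) <= tolerance * max(abs(e_ref), np.finfo(float).tiny)
        ds = abs(s_new - s_star) <= tolerance * max(s_star, np.finfo(float).tiny)
        e_ref, s_star = e_new, s_new
        if de and ds:
            converged = True
            break
        if s_star == 0.0:  # all values collapsed onto the mean
            converged = True
            break
    return AlgorithmAResult(e_ref, s_star, iterations, converged, False)


def uncertainty_of_reference(s_star: float, p: int) -> float:
    """Standard uncertainty of the assigned value, u(E_ref) = 1.25·s*/√p."""
    if p < 1:
        raise InsufficientDataError(f"p must be >= 1, got {p}")
    if s_star < 0:
        raise ValueError(f"s_star must be >= 0, got {s_star}")
    return 1.25 * s_star / math.sqrt(p)


def consensus_for_window(
    submissions: Sequence[Submission],
    window: ExposureWindow,
    tolerance: float = 1e-9,
    max_iterations: int = 1000,
    min_results: int = 5,
) -> ConsensusResult:
    """Run Algorithm A on all exposures reported for one window and package
    the assigned value with u(E_ref), σp and the fitness criterion.

    Fewer than ``min_results`` results is not fatal (the field campaign had
    45 and 41) but sets ``low_count_warning``.
    """
    wrong = [s for s in submissions if s.window_label != window.label]
    if wrong:
        raise ValueError(
            f"submissions for window {window.label} contain other labels: "
            f"{sorted({s.window_label for s in wrong})}"
        )
    values = [s.exposure for s in submissions]
    res = algorithm_a(values, tolerance=tolerance, max_iterations=max_iterations)
    p = len(values)
    u = uncertainty_of_reference(res.s_star, p)
    sigma_p = window.sigma_p_fraction * res.e_ref
    return ConsensusResult(
        window_label=window.label,
        e_ref=res.e_ref,
        s_star=res.s_star,
        u_e_ref=u,
        p=p,
        sigma_p=sigma_p,
        iterations=res.iterations,
        converged=res.converged,
        criterion_ok=u < 0.3 * sigma_p,
        degenerate=res.degenerate,
        low_count_warning=p < min_results,
    )
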