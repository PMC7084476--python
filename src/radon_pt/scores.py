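"""Performance scores against the assigned value.

Three indices per submission: the relative percentage difference
D(%) = 100·(E_i − E_ref)/E_ref, the zeta score
ζ = (E_i − E_ref)/√(u²(E_i) + u²(E_ref)) which folds in the participant's
own uncertainty claim, and the z-score z = (E_i − E_ref)/σp against the
proficiency standard deviation.  |score| ≤ 2.0 is satisfactory,
2.0 < |score| < 3.0 signals a problem, |score| ≥ 3.0 is not satisfactory.

The joint ζ/z action table distinguishes whether the result itself or the
claimed uncertainty is at fault; the intermediate "problem" band inherits
the not-satisfactory action but is flagged borderline so three-band counts
remain available.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .campaign import ParticipantCode, Submission
from .consensus import ConsensusResult

__all__ = [
    "ScoreClass",
    "JointAction",
    "ScoreRecord",
    "classify_score",
    "relative_difference",
    "zeta_score",
    "z_score",
    "joint_interpretation",
    "score_submission",
    "score_submissions",
    "scores_to_frame",
]


class ScoreClass(str, enum.Enum):
    SATISFACTORY = "satisfactory"
    PROBLEM = "problem"
    NOT_SATISFACTORY = "not_satisfactory"


class JointAction(str, enum.Enum):
    NO_ACTION = "no_action_required"
    UNCERTAINTY_TOO_LOW = "claimed_uncertainty_too_low"
    RESULT_OUT_OF_REQUIREMENTS = "result_outside_requirements"
    FULL_REVALUATION = "complete_revaluation"


ACTION_TEXT = {
    JointAction.NO_ACTION: "Participant's result is good. No action is required.",
    JointAction.UNCERTAINTY_TOO_LOW: (
        "Participant's claimed uncertainty is too low, but the result fulfills "
        "the intercomparison requirements."
    ),
    JointAction.RESULT_OUT_OF_REQUIREMENTS: (
        "Participant's uncertainty assessment is accurate but the results do "
        "not fulfill the intercomparison requirements."
    ),
    JointAction.FULL_REVALUATION: (
        "Participant's result is biased in excess. A complete revaluation "
        "should be performed."
    ),
}


def classify_score(score: float) -> ScoreClass:
    """Three-band classification: |s| ≤ 2.0, 2.0 < |s| < 3.0, |s| ≥ 3.0."""
    a = abs(score)
    if a <= 2.0:
        return ScoreClass.SATISFACTORY
    if a < 3.0:
        return ScoreClass.PROBLEM
    return ScoreClass.NOT_SATISFACTORY


def relative_difference(e_i: float, e_ref: float) -> float:
    """D(%) = 100·(E_i − E_ref)/E_ref; requires E_ref > 0."""
    if e_ref <= 0:
        raise ValueError(f"E_ref must be > 0 for D(%), got {e_ref}")
    return 100.0 * (e_i - e_ref) / e_ref


def zeta_score(e_i: float, u_e_i: float, e_ref: float, u_e_ref: float) -> float:
    """ζ = (E_i − E_ref)/√(u²(E_i) + u²(E_ref)).

    With zero combined uncertainty the score is undefined unless the
    deviation is also zero, in which case 0 is returned as the limit.
    """
    if u_e_i < 0 or u_e_ref < 0:
        raise ValueError("uncertainties must be >= 0")
    denom = math.hypot(u_e_i, u_e_ref)
    if denom == 0.0:
        if e_i == e_ref:
            return 0.0
        raise ValueError(
            "zeta score undefined: zero combined uncertainty with nonzero deviation"
        )
    return (e_i - e_ref) / denom


def z_score(e_i: float, e_ref: float, sigma_p: float) -> float:
    """z = (E_i − E_ref)/σp; requires σp > 0."""
    if sigma_p <= 0:
        raise ValueError(f"sigma_p must be > 0, got {sigma_p}")
    return (e_i - e_ref) / sigma_p


def joint_interpretation(
    zeta_class: ScoreClass, z_class: ScoreClass
) -> tuple[JointAction, bool]:
    """Map the (ζ, z) classification pair to the recommended action.

    Returns ``(action, borderline)`` where ``borderline`` is True when either
    score fell in the intermediate problem band (treated as not satisfactory
    for the choice of action).
    """
    borderline = ScoreClass.PROBLEM in (zeta_class, z_class)
    zeta_bad = zeta_class is not ScoreClass.SATISFACTORY
    z_bad = z_class is not ScoreClass.SATISFACTORY
    if not zeta_bad and not z_bad:
        action = JointAction.NO_ACTION
    elif zeta_bad and not z_bad:
        action = JointAction.UNCERTAINTY_TOO_LOW
    elif not zeta_bad and z_bad:
        action = JointAction.RESULT_OUT_OF_REQUIREMENTS
    else:
        action = JointAction.FULL_REVALUATION
    return action, borderline


@dataclass(frozen=True)
class ScoreRecord:
    code: ParticipantCode
    window_label: str
    d_percent: float
    zeta: float
    z: float
    zeta_class: ScoreClass
    z_class: ScoreClass
    joint_action: JointAction
    borderline: bool


def score_submission(sub: Submission, consensus: ConsensusResult) -> ScoreRecord:
    """Score one submission against the full-precision consensus values."""
    d = relative_difference(sub.exposure, consensus.e_ref)
    zeta = zeta_score(sub.exposure, sub.u_k1, consensus.e_ref, consensus.u_e_ref)
    z = z_score(sub.exposure, consensus.e_ref, consensus.sigma_p)
    zc, zsc = classify_score(zeta), classify_score(z)
    action, borderline = joint_interpretation(zc, zsc)
    return ScoreRecord(
        sub.code, sub.window_label, d, zeta, z, zc, zsc, action, borderline
    )


def score_submissions(
    submissions: Sequence[Submission], consensus: ConsensusResult
) -> list[ScoreRecord]:
    return [
        score_submission(s, consensus)
        for s in submissions
        if s.window_label == consensus.window_label
    ]


def scores_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Score table with one row per submission per window."""
    return pd.DataFrame(
        {
            "code": [str(r.code) for r in records],
            "window": [r.window_label for r in records],
            "D_percent": [r.d_percent for r in records],
            "zeta": [r.zeta for r in records],
            "z": [r.z for r in records],
            "zeta_class": [r.zeta_class.value for r in records],
            "z_class": [r.z_class.value for r in records],
            "action": [r.joint_action.value for r in records],
            "borderline": [r.borderline for r in records],
        }
    )
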