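"""Campaign orchestration: consensus → scores → outlier screen → summary,
plus report rendering at the campaign's print precision.

The summary table mirrors the usual intercomparison layout: for each device
class and exposure window, the percentage of results with |D| ≤ 10% and
≤ 20%, and the three classification bands of ζ and z.  Percentages are
computed over that class-and-window's own result count, which is always
reported alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .campaign import DeviceKind, ExposureWindow, Submission
from .consensus import ConsensusResult, consensus_for_window
from .outliers import OutlierReport, iqr_outliers, sensitivity_check
from .scores import ScoreRecord, score_submissions, scores_to_frame

__all__ = [
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "summary_table",
    "render_report",
    "consensus_frame",
]

SUMMARY_ROWS = [
    "abs_D_le_10pct",
    "abs_D_le_20pct",
    "abs_zeta_le_2",
    "abs_zeta_2_to_3",
    "abs_zeta_ge_3",
    "abs_z_le_2",
    "abs_z_2_to_3",
    "abs_z_ge_3",
    "n_results",
]


class PipelineError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    consensus: dict[str, ConsensusResult]
    scores: list[ScoreRecord]
    outliers: dict[str, OutlierReport]
    sensitivity_ok: dict[str, bool]
    summary: pd.DataFrame


def run_pipeline(
    submissions: Sequence[Submission],
    windows: Mapping[str, ExposureWindow],
    min_results: int = 5,
    quartile_method: str = "linear",
) -> PipelineResult:
    """Execute the full analysis for every window and return all stages.

    The consensus always uses all results (outlier screening is diagnostic,
    not exclusionary); scores are computed from full-precision consensus
    values.  Deterministic for fixed input.
    """
    by_window = {
        label: [s for s in submissions if s.window_label == label] for label in windows
    }
    consensus: dict[str, ConsensusResult] = {}
    scores: list[ScoreRecord] = []
    outliers: dict[str, OutlierReport] = {}
    sens_ok: dict[str, bool] = {}
    for label, window in windows.items():
        subs = by_window[label]
        if not subs:
            raise PipelineError("consensus", f"no submissions for window {label}")
        try:
            consensus[label] = consensus_for_window(subs, window, min_results=min_results)
        except Exception as exc:
            raise PipelineError("consensus", f"window {label}: {exc}") from exc
        try:
            scores.extend(score_submissions(subs, consensus[label]))
        except Exception as exc:
            raise PipelineError("scores", f"window {label}: {exc}") from exc
        try:
            outliers[label] = iqr_outliers(subs, window, quartile_method)
            sens_ok[label] = sensitivity_check(outliers[label])
        except Exception as exc:
            raise PipelineError("outlier_screen", f"window {label}: {exc}") from exc
    summary = summary_table(scores)
    return PipelineResult(consensus, scores, outliers, sens_ok, summary)


def summary_table(scores: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Percentage-of-results table per (device class, window) column.

    The three ζ bands (and likewise the three z bands) partition the
    results, so each triple sums to 100%.
    """
    columns: dict[tuple[str, str], list[float]] = {}
    keys = sorted(
        {(r.code.device_kind.value, r.window_label) for r in scores}
    )
    for kind, label in keys:
        sel = [
            r
            for r in scores
            if r.code.device_kind.value == kind and r.window_label == label
        ]
        n = len(sel)
        d = np.array([r.d_percent for r in sel])
        zeta = np.array([r.zeta for r in sel])
        z = np.array([r.z for r in sel])

        def pct(mask: np.ndarray) -> float:
            return 100.0 * float(mask.sum()) / n

        columns[(kind, label)] = [
            pct(np.abs(d) <= 10.0),
            pct(np.abs(d) <= 20.0),
            pct(np.abs(zeta) <= 2.0),
            pct((np.abs(zeta) > 2.0) & (np.abs(zeta) < 3.0)),
            pct(np.abs(zeta) >= 3.0),
            pct(np.abs(z) <= 2.0),
            pct((np.abs(z) > 2.0) & (np.abs(z) < 3.0)),
            pct(np.abs(z) >= 3.0),
            float(n),
        ]
    df = pd.DataFrame(columns, index=SUMMARY_ROWS)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["device_class", "window"])
    return df


def consensus_frame(consensus: Mapping[str, ConsensusResult], rounded: bool = True) -> pd.DataFrame:
    """Reference-parameter table (window, E_ref, u(E_ref), σp, s*, p).

    With ``rounded=True`` values are integers at the campaign report's print
    precision (round-half-even); full precision otherwise.
    """
    rows = []
    for label in sorted(consensus):
        c = consensus[label]
        vals = (c.e_ref, c.u_e_ref, c.sigma_p, c.s_star)
        if rounded:
            vals = tuple(int(_round_half_even(v)) for v in vals)
        rows.append({
            "window": label,
            "E_ref": vals[0],
            "u_E_ref": vals[1],
            "sigma_p": vals[2],
            "s_star": vals[3],
            "p": c.p,
        })
    return pd.DataFrame(rows)


def _round_half_even(x: float) -> float:
    return float(np.round(x))


def _consensus_json(consensus: Mapping[str, ConsensusResult]) -> dict:
    return {
        label: {
            "E_ref": c.e_ref,
            "s_star": c.s_star,
            "u_E_ref": c.u_e_ref,
            "sigma_p": c.sigma_p,
            "p": c.p,
            "iterations": c.iterations,
            "converged": c.converged,
            "criterion_ok": c.criterion_ok,
            "degenerate": c.degenerate,
            "low_count_warning": c.low_count_warning,
        }
        for label, c in consensus.items()
    }


def _outliers_json(outliers: Mapping[str, OutlierReport], sens: Mapping[str, bool]) -> dict:
    return {
        label: {
            "Q1": r.q1,
            "Q3": r.q3,
            "IQR": r.iqr,
            "lower_fence": r.lower_fence,
            "upper_fence": r.upper_fence,
            "outlier_codes": [str(c) for c in r.outlier_codes],
            "E_ref_all": r.e_ref_all,
            "u_E_ref_all": r.u_e_ref_all,
            "p_all": r.p_all,
            "E_ref_without_outliers": r.e_ref_without_outliers,
            "u_E_ref_without_outliers": r.u_e_ref_without_outliers,
            "p_without_outliers": r.p_without_outliers,
            "sensitivity_ok": bool(sens.get(label, True)),
        }
        for label, r in outliers.items()
    }


def render_report(
    result: PipelineResult, out_dir: str | Path, format: str = "csv"
) -> list[Path]:
    """Write the report artefacts in the requested format.

    ``csv``/``markdown`` render the reference-parameter table at print
    precision plus the percentage summary; ``json`` keeps full precision.
    The per-submission score table is always written as CSV.  Returns the
    paths written.
    """
    if format not in ("csv", "json", "markdown"):
        raise ValueError(f"unknown report format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    scores_path = out / "scores.csv"
    scores_to_frame(result.scores).to_csv(scores_path, index=False)
    written.append(scores_path)

    ref = consensus_frame(result.consensus, rounded=(format != "json"))
    summary = result.summary.copy()
    if format != "json":
        # percentages as integers, as campaign reports print them
        summary.loc[summary.index != "n_results"] = summary.loc[
            summary.index != "n_results"
        ].round(0)

    if format == "json":
        path = out / "report.json"
        payload = {
            "consensus": _consensus_json(result.consensus),
            "outliers": _outliers_json(result.outliers, result.sensitivity_ok),
            "summary": {
                f"{kind}/{label}": dict(zip(SUMMARY_ROWS, summary[(kind, label)]))
                for kind, label in summary.columns
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)
    elif format == "csv":
        p1 = out / "reference_parameters.csv"
        ref.to_csv(p1, index=False)
        p2 = out / "summary.csv"
        flat = summary.copy()
        flat.columns = [f"{kind}/{label}" for kind, label in summary.columns]
        flat.to_csv(p2, index_label="metric")
        written.extend([p1, p2])
    else:  # markdown
        path = out / "report.md"
        lines = ["# Campaign report", "", "## Reference parameters", ""]
        lines.append(ref.to_markdown(index=False))
        lines += ["", "## Performance summary (%)", ""]
        flat = summary.copy()
        flat.columns = [f"{kind}/{label}" for kind, label in summary.columns]
        lines.append(flat.to_markdown())
        outl = _outliers_json(result.outliers, result.sensitivity_ok)
        lines += ["", "## Outlier screen", ""]
        for label, r in outl.items():
            lines.append(
                f"- {label}: fences [{r['lower_fence']:.1f}, {r['upper_fence']:.1f}], "
                f"outliers: {', '.join(r['outlier_codes']) or 'none'}; "
                f"consensus with/without outliers "
                f"{r['E_ref_all']:.1f}/{r['E_ref_without_outliers']:.1f} "
                f"({'no statistical difference' if r['sensitivity_ok'] else 'STATISTICALLY DIFFERENT'})"
            )
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    outliers_path = out / "outliers.json"
    outliers_path.write_text(
        json.dumps(_outliers_json(result.outliers, result.sensitivity_ok), indent=2)
    )
    written.append(outliers_path)
    return written
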