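"""Core campaign data model: participant codes, exposure windows, submissions,
monitor time series, and the delimited-text formats they travel in.

Units are fixed campaign-wide: radon concentration in kBq·m⁻³, exposure
(time-integrated concentration) in kBq·m⁻³·h.  Timestamps are naive local
campaign time; no timezone arithmetic is performed.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeviceKind",
    "ParticipantCode",
    "ExposureWindow",
    "Submission",
    "MonitorSeries",
    "CodeParseError",
    "SubmissionValidationError",
    "CoverageError",
    "parse_code",
    "read_submissions",
    "write_submissions",
    "read_monitor_series",
    "write_monitor_series",
    "integrate_exposure",
]

SUBMISSION_COLUMNS = ["code", "window", "exposure_kBqm3h", "u_k1_kBqm3h"]
SERIES_COLUMNS = ["code", "timestamp_iso8601", "concentration_kBqm3"]


class CodeParseError(ValueError):
    """A participant code does not follow the LxxTn scheme."""


class SubmissionValidationError(ValueError):
    """A submission table violates a field constraint or the (code, window)
    uniqueness rule; carries the offending row number when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class CoverageError(ValueError):
    """A monitor series does not cover the requested exposure window."""


class DeviceKind(str, enum.Enum):
    ACTIVE = "active"
    PASSIVE = "passive"

    @property
    def letter(self) -> str:
        return "A" if self is DeviceKind.ACTIVE else "P"


_CODE_RE = re.compile(r"^L(?P<lab>\d{2})(?P<kind>[A-Z])(?P<group>\d+)$")


@dataclass(frozen=True, order=True)
class ParticipantCode:
    """Anonymised participant code ``LxxTn``: zero-padded lab number ``xx``
    (01–99), device letter ``T`` (A = active monitor, P = passive detector
    group), and the correlative group index ``n`` for labs entering more
    than one device of a kind."""

    lab_number: int
    device_kind: DeviceKind
    group_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.lab_number <= 99:
            raise CodeParseError(
                f"lab number must be in 1..99, got {self.lab_number}"
            )
        if self.group_index < 1:
            raise CodeParseError(
                f"group index must be >= 1, got {self.group_index}"
            )

    def __str__(self) -> str:
        return f"L{self.lab_number:02d}{self.device_kind.letter}{self.group_index}"

    @classmethod
    def parse(cls, text: str) -> "ParticipantCode":
        m = _CODE_RE.match(text.strip())
        if m is None:
            raise CodeParseError(
                f"code {text!r} does not match the LxxTn scheme "
                "(L, two-digit lab number, device letter A/P, group index)"
            )
        kind_letter = m.group("kind")
        if kind_letter not in ("A", "P"):
            raise CodeParseError(
                f"code {text!r}: device letter {kind_letter!r} is not 'A' or 'P'"
            )
        lab = int(m.group("lab"))
        if lab == 0:
            raise CodeParseError(f"code {text!r}: lab number 00 is reserved")
        kind = DeviceKind.ACTIVE if kind_letter == "A" else DeviceKind.PASSIVE
        return cls(lab, kind, int(m.group("group")))


def parse_code(text: str) -> ParticipantCode:
    """Parse a participant code of the form ``LxxTn`` (e.g. ``L07P1``)."""
    return ParticipantCode.parse(text)


# Exposure schedule of the field campaign: both windows open together at
# 12:00 on day one; E1 closes after 13 h, E2 after 70 h.
_E1_START = datetime(2018, 11, 5, 12, 0)
_E1_END = datetime(2018, 11, 6, 1, 0)
_E2_END = datetime(2018, 11, 8, 10, 0)


@dataclass(frozen=True)
class ExposureWindow:
    """A labelled exposure interval with its proficiency standard deviation
    expressed as a fraction of the assigned value (20% for the short first
    window E1, 10% for the longer second window E2)."""

    label: str
    start: datetime
    end: datetime
    sigma_p_fraction: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"window {self.label}: end {self.end} must be after start {self.start}"
            )
        if not 0 < self.sigma_p_fraction <= 1:
            raise ValueError(
                f"window {self.label}: sigma_p_fraction must be in (0, 1], "
                f"got {self.sigma_p_fraction}"
            )
        if not math.isfinite(self.duration_hours):
            raise ValueError(f"window {self.label}: non-finite duration")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @classmethod
    def e1(cls) -> "ExposureWindow":
        return cls("E1", _E1_START, _E1_END, 0.20)

    @classmethod
    def e2(cls) -> "ExposureWindow":
        return cls("E2", _E1_START, _E2_END, 0.10)


def default_windows() -> dict[str, ExposureWindow]:
    """The two overlapping campaign windows, keyed by label."""
    e1, e2 = ExposureWindow.e1(), ExposureWindow.e2()
    return {e1.label: e1, e2.label: e2}


@dataclass(frozen=True)
class Submission:
    """One participant result for one exposure window: the exposure in
    kBq·m⁻³·h and its standard uncertainty at coverage factor k = 1."""

    code: ParticipantCode
    window_label: str
    exposure: float
    u_k1: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.exposure) or self.exposure < 0:
            raise SubmissionValidationError(
                f"{self.code}/{self.window_label}: exposure must be finite and "
                f">= 0, got {self.exposure}"
            )
        if not math.isfinite(self.u_k1) or self.u_k1 < 0:
            raise SubmissionValidationError(
                f"{self.code}/{self.window_label}: u_k1 must be finite and "
                f">= 0, got {self.u_k1}"
            )


@dataclass
class MonitorSeries:
    """Hourly radon-concentration record (kBq·m⁻³).  ``code`` is None for the
    chamber reference trace, otherwise the active monitor that recorded it."""

    code: ParticipantCode | None
    timestamps: np.ndarray  # datetime64[s], strictly increasing, nominally hourly
    concentration: np.ndarray  # kBq·m⁻³, nonnegative

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.timestamps.shape != self.concentration.shape:
            raise ValueError("timestamps and concentration lengths differ")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps).astype(int) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.concentration)) or np.any(self.concentration < 0):
            raise ValueError("concentrations must be finite and nonnegative")

    def __len__(self) -> int:
        return self.timestamps.size


def integrate_exposure(
    series: MonitorSeries, window: ExposureWindow, rule: str = "left"
) -> float:
    """Time-integrate a concentration series over a window, in kBq·m⁻³·h.

    With the default left-rectangular ``rule`` each hourly sample represents
    the hour that follows it, and window membership is half-open
    ``[start, end)`` so adjacent windows never double-count an hour.  The
    ``"trapezoid"`` rule instead interpolates linearly between samples on the
    closed interval.

    Raises :class:`CoverageError` if the series does not span the window on
    an unbroken hourly grid.
    """
    start = np.datetime64(window.start, "s")
    end = np.datetime64(window.end, "s")
    ts = series.timestamps
    if ts.size == 0 or ts[0] > start or ts[-1] < end - np.timedelta64(3600, "s"):
        have = "empty series" if ts.size == 0 else f"series spans [{ts[0]}, {ts[-1]}]"
        raise CoverageError(
            f"window {window.label} [{window.start}, {window.end}) not covered: {have}"
        )
    if rule == "left":
        mask = (ts >= start) & (ts < end)
        sub = ts[mask]
        n_expected = int(round(window.duration_hours))
        if sub.size != n_expected or (
            sub.size >= 2 and not np.all(np.diff(sub).astype(int) == 3600)
        ):
            raise CoverageError(
                f"window {window.label}: expected {n_expected} hourly samples "
                f"in [{window.start}, {window.end}), found {sub.size}"
            )
        return float(series.concentration[mask].sum())
    if rule == "trapezoid":
        mask = (ts >= start) & (ts <= end)
        hours = ts[mask].astype("int64") / 3600.0
        if hours.size < 2:
            raise CoverageError(
                f"window {window.label}: need at least 2 samples for trapezoid rule"
            )
        return float(np.trapezoid(series.concentration[mask], hours))
    raise ValueError(f"unknown integration rule {rule!r}")


# ---------------------------------------------------------------------------
# Delimited-text IO


def write_submissions(submissions: Sequence[Submission], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "code": [str(s.code) for s in submissions],
            "window": [s.window_label for s in submissions],
            "exposure_kBqm3h": [s.exposure for s in submissions],
            "u_k1_kBqm3h": [s.u_k1 for s in submissions],
        }
    )
    df.to_csv(path, index=False)


def read_submissions(
    path: str | Path, known_windows: Iterable[str] = ("E1", "E2")
) -> list[Submission]:
    """Read a submissions CSV (columns ``code,window,exposure_kBqm3h,
    u_k1_kBqm3h``), validating every row; duplicate (code, window) pairs and
    unknown window labels are rejected with the offending row number."""
    df = pd.read_csv(path, dtype={"code": str, "window": str})
    missing = [c for c in SUBMISSION_COLUMNS if c not in df.columns]
    if missing:
        raise SubmissionValidationError(
            f"missing column(s) {missing}; expected header {SUBMISSION_COLUMNS}"
        )
    known = set(known_windows)
    out: list[Submission] = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            code = ParticipantCode.parse(rec.code)
        except CodeParseError as exc:
            raise SubmissionValidationError(str(exc), row=i) from exc
        if known and rec.window not in known:
            raise SubmissionValidationError(
                f"unknown window label {rec.window!r} (known: {sorted(known)})", row=i
            )
        key = (str(code), rec.window)
        if key in seen:
            raise SubmissionValidationError(f"duplicate (code, window) {key}", row=i)
        seen.add(key)
        try:
            out.append(
                Submission(code, rec.window, float(rec.exposure_kBqm3h), float(rec.u_k1_kBqm3h))
            )
        except (SubmissionValidationError, ValueError) as exc:
            raise SubmissionValidationError(str(exc), row=i) from exc
    return out


def write_monitor_series(series: Sequence[MonitorSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "code": str(s.code) if s.code is not None else "CHAMBER",
                    "timestamp_iso8601": np.datetime_as_string(s.timestamps, unit="s"),
                    "concentration_kBqm3": s.concentration,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_monitor_series(path: str | Path) -> list[MonitorSeries]:
    """Read one or more monitor series from CSV (columns ``code,
    timestamp_iso8601,concentration_kBqm3``), one series per code."""
    df = pd.read_csv(path, dtype={"code": str})
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SubmissionValidationError(
            f"missing column(s) {missing}; expected header {SERIES_COLUMNS}"
        )
    out = []
    for code_text, grp in df.groupby("code", sort=True):
        code = None if code_text == "CHAMBER" else ParticipantCode.parse(code_text)
        ts = grp["timestamp_iso8601"].to_numpy(dtype="datetime64[s]")
        order = np.argsort(ts)
        out.append(
            MonitorSeries(code, ts[order], grp["concentration_kBqm3"].to_numpy(float)[order])
        )
    return out
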