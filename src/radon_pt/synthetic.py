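"""Synthetic radon-chamber campaigns with full ground truth.

The generator emulates a field intercomparison in a ~45 m³ unventilated
chamber fed by underground soil radon: the concentration rises to a plateau
of about 30 kBq·m⁻³ during the short first exposure window (E1, 13 h), then
decays to below 2 kBq·m⁻³ by the end of the long window (E2, 70 h).  A mix
of passive detector groups (each reporting the mean of ~10 individual
detectors) and active monitors (hourly concentration records with Poisson
counting noise set by the instrument sensitivity) submits exposures for both
windows.  A configurable subset of the passive groups carries a
holder-degassing contamination bias that multiplies the E1 exposure by a
factor drawn from [1.4, 2.6] — radon adsorbed in the holder material keeps
exposing the detector after the window closes, which only matters after E1
when the chamber is still near its concentration peak.

Every random draw flows from the single campaign seed, so campaigns are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Mapping, Sequence

import numpy as np

from .campaign import (
    DeviceKind,
    ExposureWindow,
    MonitorSeries,
    ParticipantCode,
    Submission,
    default_windows,
    integrate_exposure,
)

__all__ = [
    "ChamberParams",
    "DeviceModel",
    "CampaignConfig",
    "CampaignTruth",
    "simulate_chamber",
    "simulate_passive_group",
    "simulate_active_monitor",
    "generate_campaign",
]

#: Sensitivities (cpm at 1 kBq·m⁻³) spanning the instrument classes fielded
#: in practice, from ionization chambers down to PIN-photodiode monitors.
SENSITIVITY_POOL = (50.0, 20.0, 7.0, 1.8, 0.1)


@dataclass(frozen=True)
class ChamberParams:
    """Parametric rise–plateau–decay concentration curve (kBq·m⁻³, hours).

    Defaults were tuned once against the campaign anchors — a plateau near
    30 kBq·m⁻³ at the end of E1, under 2 kBq·m⁻³ at the end of E2, and true
    exposures near 356 / 1014 kBq·m⁻³·h — and then frozen.
    """

    baseline_concentration: float = 0.5
    plateau_concentration: float = 30.0
    rise_rate: float = 1.0  # h⁻¹, saturating approach to the plateau
    decay_rate: float = 0.048  # h⁻¹, exponential decay after decay_start
    decay_start: float = 13.0  # hours after campaign start
    noise_cv: float = 0.03  # hourly multiplicative room fluctuation

    def __post_init__(self) -> None:
        for name in ("baseline_concentration", "plateau_concentration", "rise_rate", "decay_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def backbone(self, hours: np.ndarray) -> np.ndarray:
        """Noiseless concentration at the given hours since campaign start."""
        t = np.asarray(hours, dtype=float)
        b, p = self.baseline_concentration, self.plateau_concentration
        rise = b + (p - b) * -np.expm1(-self.rise_rate * t)
        c_peak = b + (p - b) * -np.expm1(-self.rise_rate * self.decay_start)
        decay = c_peak * np.exp(-self.decay_rate * (t - self.decay_start))
        return np.where(t <= self.decay_start, rise, decay)


@dataclass(frozen=True)
class DeviceModel:
    """Response model of one participant device.

    ``degassing_factor`` ≥ 1 multiplies the first-window exposure seen by a
    passive group (1.0 = uncontaminated); ``sensitivity_cpm_per_kBqm3``
    drives the Poisson counting noise of an active monitor.
    """

    kind: DeviceKind
    n_detectors: int = 10
    reporting_cv: float = 0.10
    calibration_bias: float = 1.0
    degassing_factor: float = 1.0
    sensitivity_cpm_per_kBqm3: float | None = None

    def __post_init__(self) -> None:
        if self.reporting_cv < 0:
            raise ValueError("reporting_cv must be >= 0")
        if self.degassing_factor < 1.0:
            raise ValueError("degassing_factor must be >= 1")
        if self.calibration_bias <= 0:
            raise ValueError("calibration_bias must be > 0")
        if self.kind is DeviceKind.PASSIVE and self.n_detectors < 2:
            raise ValueError("passive groups need >= 2 detectors for a standard error")
        if self.kind is DeviceKind.ACTIVE and self.sensitivity_cpm_per_kBqm3 is not None:
            if self.sensitivity_cpm_per_kBqm3 <= 0:
                raise ValueError("sensitivity must be > 0")


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions of a synthetic campaign."""

    n_passive: int = 23
    n_active: int = 22
    n_labs: int = 20
    contaminated_fraction: float = 5 / 23
    degassing_low: float = 1.4
    degassing_high: float = 2.6
    reporting_cv: float = 0.10
    n_detectors: int = 10
    between_lab_cv: float = 0.0  # multiplicative calibration spread across participants
    e2_dropout_passive: int = 3  # participants reporting E1 only (campaign p: 45 → 41)
    e2_dropout_active: int = 1
    storage_level_kBqm3: float = 0.008  # < 10 Bq·m⁻³ storage area
    storage_hours: float = 48.0
    sensitivity_pool: tuple[float, ...] = SENSITIVITY_POOL
    chamber: ChamberParams = field(default_factory=ChamberParams)

    def __post_init__(self) -> None:
        if self.n_passive < 0 or self.n_active < 0:
            raise ValueError("device counts must be >= 0")
        if not 0.0 <= self.contaminated_fraction <= 1.0:
            raise ValueError(
                f"contaminated_fraction must be in [0, 1], got {self.contaminated_fraction}"
            )
        if not 1.0 <= self.degassing_low <= self.degassing_high:
            raise ValueError("need 1 <= degassing_low <= degassing_high")
        if self.e2_dropout_passive > self.n_passive or self.e2_dropout_active > self.n_active:
            raise ValueError("dropout exceeds device count")


@dataclass
class CampaignTruth:
    """Ground truth of a generated campaign: the realized chamber series, the
    noiseless backbone, the true exposures the devices actually received, the
    per-participant device models, and which codes were contaminated."""

    chamber_series: MonitorSeries
    chamber_backbone: np.ndarray
    true_exposures: dict[str, float]
    device_models: dict[str, DeviceModel]
    contaminated_codes: list[ParticipantCode]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and coefficient of variation."""
    if cv == 0.0 or mean == 0.0:
        return np.full(size, mean, dtype=float)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2), size)


def simulate_chamber(
    params: ChamberParams,
    windows: Mapping[str, ExposureWindow],
    rng: np.random.Generator,
) -> tuple[MonitorSeries, dict[str, float]]:
    """Hourly chamber concentration over the span of the windows, plus the
    true exposure delivered in each window.

    The realized series is the parametric backbone perturbed by hourly
    multiplicative lognormal jitter (room fluctuation); the true exposures
    are integrals of the realized series, since that is the concentration
    the devices were actually exposed to.
    """
    if not windows:
        raise ValueError("at least one window is required")
    start = min(w.start for w in windows.values())
    end = max(w.end for w in windows.values())
    n_hours = int(math.ceil((end - start).total_seconds() / 3600.0))
    timestamps = np.datetime64(start, "s") + np.arange(n_hours + 1) * np.timedelta64(3600, "s")
    hours = np.arange(n_hours + 1, dtype=float)
    backbone = params.backbone(hours)
    jitter = _lognormal_vector(rng, params.noise_cv, hours.size)
    series = MonitorSeries(None, timestamps, backbone * jitter)
    true_exposures = {
        label: integrate_exposure(series, w) for label, w in windows.items()
    }
    return series, true_exposures


def _lognormal_vector(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), size)


def simulate_passive_group(
    code: ParticipantCode,
    window_label: str,
    true_exposure: float,
    model: DeviceModel,
    rng: np.random.Generator,
    storage_exposure: float = 0.0,
    apply_degassing: bool = True,
) -> Submission:
    """Reported exposure of one passive detector group.

    Each of the ``n_detectors`` exposed detectors reads a lognormal draw
    around the biased truth plus the (negligible) storage-area exposure; an
    equally sized transit set reads the storage exposure alone and is
    subtracted as background.  The group reports the mean with the standard
    error of the mean as its k=1 uncertainty.
    """
    if true_exposure < 0:
        raise ValueError("true_exposure must be >= 0")
    n = model.n_detectors
    degas = model.degassing_factor if apply_degassing else 1.0
    mean = true_exposure * model.calibration_bias * degas + storage_exposure
    exposed = _lognormal(rng, mean, model.reporting_cv, n)
    transit = _lognormal(rng, storage_exposure, model.reporting_cv, n)
    reported = max(float(exposed.mean() - transit.mean()), 0.0)
    sem = math.hypot(
        float(exposed.std(ddof=1)) / math.sqrt(n),
        float(transit.std(ddof=1)) / math.sqrt(n),
    )
    return Submission(code, window_label, reported, sem)


def simulate_active_monitor(
    code: ParticipantCode,
    chamber: MonitorSeries,
    model: DeviceModel,
    windows: Mapping[str, ExposureWindow],
    rng: np.random.Generator,
) -> tuple[MonitorSeries, list[Submission]]:
    """Observed hourly series and per-window submissions of one active monitor.

    Expected counts per hour are sensitivity × concentration × 60 min; the
    observed concentration is the Poisson count divided back by the same
    factor (and scaled by any calibration bias), so low-sensitivity monitors
    produce visibly noisier series.  The reported k=1 uncertainty is the
    counting-statistics propagation √(Σ counts)/(sensitivity·60).
    An infinite sensitivity reproduces the chamber series exactly.
    """
    s = model.sensitivity_cpm_per_kBqm3
    if s is None or s <= 0:
        raise ValueError("active monitor needs a positive sensitivity")
    factor = s * 60.0  # expected counts per hour per kBq·m⁻³
    if math.isinf(factor):
        observed_counts = None
        observed = chamber.concentration.copy()
    else:
        observed_counts = rng.poisson(factor * chamber.concentration).astype(float)
        observed = observed_counts / factor
    series = MonitorSeries(code, chamber.timestamps.copy(), model.calibration_bias * observed)
    submissions = []
    for label, window in windows.items():
        exposure = integrate_exposure(series, window)
        if observed_counts is None:
            u = 0.0
        else:
            start = np.datetime64(window.start, "s")
            end = np.datetime64(window.end, "s")
            mask = (chamber.timestamps >= start) & (chamber.timestamps < end)
            u = model.calibration_bias * math.sqrt(float(observed_counts[mask].sum())) / factor
        submissions.append(Submission(code, label, exposure, u))
    return series, submissions


def _assign_codes(n: int, kind: DeviceKind, n_labs: int) -> list[ParticipantCode]:
    """Distribute n devices over labs 1..n_labs, cycling group indices."""
    codes = []
    for i in range(n):
        lab = i % n_labs + 1
        group = i // n_labs + 1
        codes.append(ParticipantCode(lab, kind, group))
    return codes


def generate_campaign(
    config: CampaignConfig | None = None,
    seed: int = 0,
    windows: Mapping[str, ExposureWindow] | None = None,
) -> tuple[list[Submission], list[MonitorSeries], CampaignTruth]:
    """Generate a full synthetic campaign.

    Returns all submissions (both windows), the observed active-monitor
    series, and the ground truth.  Contaminated passive groups (a
    ``contaminated_fraction`` of them, rounded) receive a degassing factor
    drawn uniformly from [degassing_low, degassing_high], applied to the
    first window only: by the end of the long window the chamber is below
    2 kBq·m⁻³, so post-exposure degassing no longer adds a measurable dose.
    """
    config = config or CampaignConfig()
    windows = dict(windows or default_windows())
    rng = np.random.default_rng(seed)

    chamber, true_exposures = simulate_chamber(config.chamber, windows, rng)
    storage_exposure = config.storage_level_kBqm3 * config.storage_hours

    passive_codes = _assign_codes(config.n_passive, DeviceKind.PASSIVE, config.n_labs)
    active_codes = _assign_codes(config.n_active, DeviceKind.ACTIVE, config.n_labs)

    n_contam = int(round(config.contaminated_fraction * config.n_passive))
    contam_idx = rng.choice(config.n_passive, size=n_contam, replace=False) if n_contam else []
    contaminated = [passive_codes[i] for i in sorted(contam_idx)]
    contam_set = set(contaminated)

    device_models: dict[str, DeviceModel] = {}
    for code in passive_codes:
        bias = float(_lognormal(rng, 1.0, config.between_lab_cv, 1)[0])
        degas = (
            float(rng.uniform(config.degassing_low, config.degassing_high))
            if code in contam_set
            else 1.0
        )
        device_models[str(code)] = DeviceModel(
            DeviceKind.PASSIVE,
            n_detectors=config.n_detectors,
            reporting_cv=config.reporting_cv,
            calibration_bias=bias,
            degassing_factor=degas,
        )
    for code in active_codes:
        bias = float(_lognormal(rng, 1.0, config.between_lab_cv, 1)[0])
        sens = float(rng.choice(np.asarray(config.sensitivity_pool, dtype=float)))
        device_models[str(code)] = DeviceModel(
            DeviceKind.ACTIVE,
            calibration_bias=bias,
            sensitivity_cpm_per_kBqm3=sens,
        )

    # Participants present for E1 only (the campaign's p drops 45 -> 41 in E2).
    drop_passive = set(
        rng.choice(config.n_passive, size=config.e2_dropout_passive, replace=False)
    ) if config.e2_dropout_passive else set()
    drop_active = set(
        rng.choice(config.n_active, size=config.e2_dropout_active, replace=False)
    ) if config.e2_dropout_active else set()

    window_order = sorted(windows)  # E1 before E2; deterministic
    first_label = window_order[0]

    submissions: list[Submission] = []
    for i, code in enumerate(passive_codes):
        model = device_models[str(code)]
        for label in window_order:
            if label != first_label and i in drop_passive:
                continue
            submissions.append(
                simulate_passive_group(
                    code,
                    label,
                    true_exposures[label],
                    model,
                    rng,
                    storage_exposure=storage_exposure,
                    apply_degassing=(label == first_label),
                )
            )

    monitor_series: list[MonitorSeries] = []
    for j, code in enumerate(active_codes):
        model = device_models[str(code)]
        labels = [
            lb for lb in window_order if not (lb != first_label and j in drop_active)
        ]
        series, subs = simulate_active_monitor(
            code, chamber, model, {lb: windows[lb] for lb in labels}, rng
        )
        monitor_series.append(series)
        submissions.extend(subs)

    hours = np.arange(len(chamber), dtype=float)
    truth = CampaignTruth(
        chamber_series=chamber,
        chamber_backbone=config.chamber.backbone(hours),
        true_exposures=true_exposures,
        device_models=device_models,
        contaminated_codes=contaminated,
    )
    return submissions, monitor_series, truth
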