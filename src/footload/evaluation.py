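"""Validation against reference force sensors and excessive-load profiling.

Validation is correlation-based: the estimated forefoot load of each step is
compared with the reference force trace over the step's forefoot window
(about 60 samples at 100 Hz) using the Pearson coefficient, then summarized
as mean +/- SD over the protocol's steps.  The reference for a step is the
single force channel with the largest peak in the window (the four sensors
sit on the 1st and 2nd metatarsal heads and saturate at 40 N).

Excessive forefoot load is defined per patient from a level-corridor
baseline: steps whose peak load exceeds the mean + 2 SD of the per-step
maxima of the first 15 baseline steps are excessive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import ForceRecording, ParameterError, ProtocolError

__all__ = [
    "RefWindow",
    "StepCorrelation",
    "ValidationSummary",
    "ExcessiveLoadProfile",
    "DailyWalkReport",
    "reference_forefoot",
    "per_step_pearson",
    "categorize_correlation",
    "summarize_validation",
    "excessive_threshold",
    "threshold_from_stats",
    "classify_excessive",
    "daily_report",
]

#: steps the protocol drops: corridor drops the 1st and last, stairs the last
PROTOCOL_EXCLUSIONS = {"corridor": (1, 1), "stairs": (0, 1)}
PROTOCOL_STEPS = {"corridor": 30, "stairs": 9}


@dataclass
class RefWindow:
    """Reference force trace for one step: the max-peak channel, windowed."""

    t: np.ndarray
    force: np.ndarray
    channel: int
    saturated: np.ndarray  # boolean mask, samples at/above the sensor limit

    @property
    def any_saturated(self) -> bool:
        return bool(np.any(self.saturated))


def reference_forefoot(force: ForceRecording, window: tuple) -> RefWindow:
    """Select the channel with the largest peak within the window.

    Ties go to the lowest channel index.  Samples at or above the saturation
    limit are flagged; an all-zero window raises a data warning via the
    returned channel's flag rather than an exception.
    """
    t0, t1 = window
    mask = (force.t >= t0) & (force.t <= t1)
    if not np.any(mask):
        raise ParameterError(f"window ({t0}, {t1}) lies outside the force recording")
    sub = force.channels[mask]
    peaks = sub.max(axis=0)
    channel = int(np.argmax(peaks))  # argmax takes the first maximum: lowest index
    series = sub[:, channel]
    return RefWindow(
        t=force.t[mask],
        force=series,
        channel=channel,
        saturated=series >= force.saturation_limit,
    )


def per_step_pearson(est_fl: np.ndarray, ref_fl: np.ndarray) -> float:
    """Pearson product-moment correlation over one step's forefoot window."""
    est_fl = np.asarray(est_fl, dtype=float)
    ref_fl = np.asarray(ref_fl, dtype=float)
    if est_fl.shape != ref_fl.shape:
        raise ParameterError("estimated and reference series must have equal length")
    if len(est_fl) < 3:
        raise ParameterError("need at least 3 samples to correlate")
    if np.ptp(est_fl) == 0 or np.ptp(ref_fl) == 0:
        raise ParameterError("zero variance in a step window; correlation undefined")
    return float(stats.pearsonr(est_fl, ref_fl).statistic)


def categorize_correlation(r: float) -> str:
    """Band label for |r|: weak <= 0.35 < moderate <= 0.65 < strong <= 0.9 < excellent."""
    if not -1.0 <= r <= 1.0 + 1e-12:
        raise ParameterError(f"correlation {r} outside [-1, 1]")
    a = abs(r)
    if a <= 0.35:
        return "weak"
    if a <= 0.65:
        return "moderate"
    if a <= 0.9:
        return "strong"
    return "excellent"


@dataclass
class StepCorrelation:
    step_id: int
    foot: str
    r: float


@dataclass
class ValidationSummary:
    mean_r: float
    sd_r: float
    n_steps: int
    category: str
    protocol: str
    correlations: list = field(default_factory=list)  # list[StepCorrelation]


def summarize_validation(
    step_correlations: list,
    protocol: str = "corridor",
    n_required: int | None = None,
) -> ValidationSummary:
    """Mean +/- SD of per-step correlations under a walking protocol.

    The corridor protocol excludes the first and last step, stairs the last
    step only.  ``n_required`` (default: 30 for corridor, 9 for stairs) is
    the number of steps the summary is taken over; extra steps beyond it are
    ignored, a shortfall raises :class:`ProtocolError`.
    """
    if protocol not in PROTOCOL_EXCLUSIONS:
        raise ParameterError(f"unknown protocol {protocol!r}")
    head, tail = PROTOCOL_EXCLUSIONS[protocol]
    if n_required is None:
        n_required = PROTOCOL_STEPS[protocol]
    included = step_correlations[head: len(step_correlations) - tail]
    if len(included) < n_required:
        raise ProtocolError(
            f"{protocol} protocol needs {n_required} steps after exclusions, "
            f"got {len(included)}"
        )
    included = included[:n_required]
    rs = np.array([c.r for c in included])
    mean_r = float(np.mean(rs))
    sd_r = float(np.std(rs))
    return ValidationSummary(
        mean_r=mean_r,
        sd_r=sd_r,
        n_steps=len(included),
        category=categorize_correlation(mean_r),
        protocol=protocol,
        correlations=list(included),
    )


# ---------------------------------------------------------------------------
# Excessive forefoot load


def threshold_from_stats(
    mean_fl: float, sd_fl: float, k_sd: float = 2.0, decimals: int = 1
) -> float:
    """Excessive-load threshold (kgf): mean + k*SD, rounded for reporting."""
    if sd_fl < 0:
        raise ParameterError("SD must be non-negative")
    return round(mean_fl + k_sd * sd_fl, decimals)


def excessive_threshold(
    baseline_max_fl: np.ndarray,
    k_sd: float = 2.0,
    n_baseline: int = 15,
    decimals: int = 1,
) -> float:
    """Threshold from a corridor baseline: the first ``n_baseline`` per-step
    maxima define mean + ``k_sd`` * SD (population denominator), rounded to
    ``decimals``.
    """
    baseline_max_fl = np.asarray(baseline_max_fl, dtype=float)
    if len(baseline_max_fl) < n_baseline:
        raise ProtocolError(
            f"baseline needs {n_baseline} steps, got {len(baseline_max_fl)}"
        )
    base = baseline_max_fl[:n_baseline]
    return threshold_from_stats(
        float(np.mean(base)), float(np.std(base)), k_sd=k_sd, decimals=decimals
    )


@dataclass
class ExcessiveLoadProfile:
    baseline_mean: float
    baseline_sd: float
    threshold: float
    max_fl_per_step: np.ndarray
    n_excessive: int
    rate: int | None  # steps per excessive event, rounded; None if no events

    @property
    def n_steps(self) -> int:
        return len(self.max_fl_per_step)


def classify_excessive(
    max_fl_per_step: np.ndarray, threshold: float
) -> tuple[int, int | None]:
    """Count steps whose peak load strictly exceeds the threshold.

    Returns ``(n_excessive, rate)`` where ``rate`` is the rounded number of
    steps per excessive event, or None when nothing exceeds the threshold.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    max_fl_per_step = np.asarray(max_fl_per_step, dtype=float)
    n_exc = int(np.sum(max_fl_per_step > threshold))
    rate = round(len(max_fl_per_step) / n_exc) if n_exc else None
    return n_exc, rate


# ---------------------------------------------------------------------------
# Daily-walk report


@dataclass
class BoutSummary:
    start: float
    end: float
    duration: float
    n_steps: int
    n_excessive: int
    mean_cycle_s: float | None


@dataclass
class DailyWalkReport:
    recorded_s: float
    threshold_kgf: float
    bouts: list                      # list[BoutSummary]
    total_bout_time_s: float
    total_steps: int
    n_excessive: int
    rate: int | None
    mean_cycle_s: float | None
    max_fl_kgf: float | None
    max_fl_bout: int | None
    max_fl_time_s: float | None


def daily_report(
    bouts: list,
    fl_by_bout: list,
    threshold: float,
    recorded_s: float,
) -> DailyWalkReport:
    """Aggregate a free-living recording into a daily-walk report.

    ``bouts`` are :class:`~footload.gait_events.WalkingBout` objects and
    ``fl_by_bout`` the matching
    :class:`~footload.load_model.ForefootLoadSeries` per bout.
    """
    from .gait_events import gait_cycle_stats  # local import avoids a cycle

    if len(bouts) != len(fl_by_bout):
        raise ParameterError("bouts and forefoot-load series must align")
    summaries = []
    cycles = []
    total_steps = 0
    n_excessive = 0
    max_fl = None
    max_ctx = (None, None)
    for b, (bout, fl) in enumerate(zip(bouts, fl_by_bout)):
        maxima = fl.max_fl_per_step
        n_exc = int(np.sum(maxima > threshold)) if len(maxima) else 0
        mean_cycle, n_steps = gait_cycle_stats(bout.steps)
        summaries.append(
            BoutSummary(
                start=bout.start,
                end=bout.end,
                duration=bout.duration,
                n_steps=len(maxima),
                n_excessive=n_exc,
                mean_cycle_s=mean_cycle,
            )
        )
        if mean_cycle is not None:
            cycles.append((mean_cycle, n_steps))
        total_steps += len(maxima)
        n_excessive += n_exc
        for sl in fl.steps:
            if max_fl is None or sl.max_fl > max_fl:
                max_fl = sl.max_fl
                max_ctx = (b, sl.step.hc)
    rate = round(total_steps / n_excessive) if n_excessive else None
    mean_cycle_s = (
        float(sum(c * n for c, n in cycles) / sum(n for _, n in cycles))
        if cycles
        else None
    )
    return DailyWalkReport(
        recorded_s=float(recorded_s),
        threshold_kgf=float(threshold),
        bouts=summaries,
        total_bout_time_s=float(math.fsum(b.duration for b in summaries)),
        total_steps=total_steps,
        n_excessive=n_excessive,
        rate=rate,
        mean_cycle_s=mean_cycle_s,
        max_fl_kgf=max_fl,
        max_fl_bout=max_ctx[0],
        max_fl_time_s=max_ctx[1],
    )
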