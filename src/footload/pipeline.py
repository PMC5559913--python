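"""End-to-end orchestration: raw recordings -> filtered signals -> tilt ->
vertical accelerations -> gait events -> GRF -> per-step forefoot load,
plus the validation and daily-walk workflows built on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gait_events, kinematics, load_model
from .evaluation import (
    ExcessiveLoadProfile,
    StepCorrelation,
    ValidationSummary,
    classify_excessive,
    daily_report,
    excessive_threshold,
    per_step_pearson,
    reference_forefoot,
    summarize_validation,
)
from .io_formats import (
    SEGMENTS,
    AnalysisConfig,
    DataError,
    ForceRecording,
    ImuRecording,
    ParameterError,
    SubjectProfile,
    screen_sampling,
    split_at_gaps,
)
from .preprocess import FilterSpec, critically_damped_lowpass, remove_static_offset

__all__ = [
    "TrialEstimate",
    "estimate_trial",
    "validate_trial",
    "excessive_profile",
    "analyze_daily",
]

FULL_MODE_SEGMENTS = SEGMENTS
FOOT_ONLY_SEGMENTS = ("foot_L", "foot_R")


@dataclass
class ProcessedSegment:
    """One segment after filtering, offset removal and tilt propagation."""

    segment_id: str
    t: np.ndarray
    acc_dyn: np.ndarray       # offset-free filtered acceleration, (n, 3)
    gyro_filt: np.ndarray     # filtered angular velocity, (n, 3)
    theta: np.ndarray
    theta0: float
    a_vert: np.ndarray        # dynamic vertical acceleration


@dataclass
class TrialEstimate:
    """Everything the estimator derives from one trial."""

    grf: load_model.GrfSeries
    events: gait_events.GaitEventSet
    steps: list
    fl: load_model.ForefootLoadSeries
    segments: dict = field(default_factory=dict)   # id -> ProcessedSegment
    n_discarded_steps: int = 0
    mode: str = "full"


def _filter_spec(config: AnalysisConfig) -> FilterSpec:
    return FilterSpec(cutoff=config.filter_cutoff_hz, order=config.filter_order)


def _stationary_mask(
    gyro_pitch: np.ndarray, fs: float, thresh: float = 0.1, min_s: float = 0.5
) -> np.ndarray:
    """Samples inside sufficiently long low-angular-rate runs."""
    quiet = np.abs(gyro_pitch) < thresh
    mask = np.zeros_like(quiet)
    n_min = int(round(min_s * fs))
    i = 0
    n = len(quiet)
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            if j - i >= n_min:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def process_segment(
    rec: ImuRecording,
    config: AnalysisConfig,
    reinit_stationary: bool = False,
) -> ProcessedSegment:
    """Filter, remove static offsets, and propagate tilt for one segment.

    With ``reinit_stationary`` the tilt integration is re-anchored to the
    accelerometer-derived tilt at every detected stationary interval, which
    bounds gyro drift over long free-living recordings.
    """
    spec = _filter_spec(config)
    acc_f = np.column_stack(
        [critically_damped_lowpass(rec.acc[:, i], rec.fs, spec) for i in range(3)]
    )
    gyro_f = np.column_stack(
        [critically_damped_lowpass(rec.gyro[:, i], rec.fs, spec) for i in range(3)]
    )
    acc_dyn = np.empty_like(acc_f)
    for i in range(3):
        acc_dyn[:, i], _ = remove_static_offset(
            acc_f[:, i], rec.fs, config.static_window_s
        )
    kind = kinematics.segment_kind(rec.segment_id)
    filtered_rec = ImuRecording(rec.segment_id, rec.t, acc_f, gyro_f, rec.fs)
    theta0 = kinematics.static_tilt(
        filtered_rec, config.static_window_s, kind=kind, g=config.g
    )
    theta = kinematics.integrate_pitch(rec.t, gyro_f[:, 0], theta0).theta

    if reinit_stationary:
        mask = _stationary_mask(gyro_f[:, 0], rec.fs)
        # re-anchor at each stationary run using the gravity direction there
        runs = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for a, b in zip(runs[::2], runs[1::2]):
            ay = float(np.mean(acc_f[a:b, 1]))
            az = float(np.mean(acc_f[a:b, 2]))
            if np.hypot(ay, az) < 0.5 * config.g:
                continue
            if kind == kinematics.FOOT_KIND:
                th_static = float(np.arctan2(-ay, az))
            else:
                th_static = float(np.arctan2(az, -ay))
            theta[a:] += th_static - theta[(a + b) // 2]

    if kind == kinematics.FOOT_KIND:
        a_vert = kinematics.vertical_accel_foot(acc_dyn[:, 1], acc_dyn[:, 2], theta)
    else:
        a_vert = kinematics.vertical_accel_long_segment(
            acc_dyn[:, 1], acc_dyn[:, 2], theta
        )
    return ProcessedSegment(
        segment_id=rec.segment_id,
        t=rec.t,
        acc_dyn=acc_dyn,
        gyro_filt=gyro_f,
        theta=theta,
        theta0=theta0,
        a_vert=a_vert,
    )


def estimate_trial(
    recordings: dict,
    subject: SubjectProfile,
    config: AnalysisConfig | None = None,
    mode: str = "full",
    reinit_stationary: bool = False,
) -> TrialEstimate:
    """Run the full estimation chain on one trial's recordings.

    ``recordings`` maps segment ids to :class:`ImuRecording`; ``mode`` is
    ``full`` (all seven segments) or ``foot_only`` (the two foot sensors,
    the configuration worn in daily life).
    """
    config = config or AnalysisConfig()
    needed = FULL_MODE_SEGMENTS if mode == "full" else FOOT_ONLY_SEGMENTS
    if mode not in ("full", "foot_only"):
        raise ParameterError(f"unknown mode {mode!r}")
    missing = [s for s in needed if s not in recordings]
    if missing:
        raise DataError(
            f"mode {mode!r} requires segment recordings {list(needed)}; "
            f"missing: {missing}"
        )
    base = recordings[needed[0]]
    for seg in needed[1:]:
        if len(recordings[seg].t) != len(base.t) or not np.allclose(
            recordings[seg].t, base.t
        ):
            raise DataError(f"recordings {needed[0]} and {seg} are not time-aligned")

    processed = {
        seg: process_segment(recordings[seg], config, reinit_stationary)
        for seg in needed
    }

    events = gait_events.detect_gait_events(
        base.t,
        a3z_dyn={s: processed[f"foot_{s}"].acc_dyn[:, 2] for s in ("L", "R")},
        r3x={s: processed[f"foot_{s}"].gyro_filt[:, 0] for s in ("L", "R")},
        config=config,
    )
    steps, n_discarded = gait_events.segment_steps(events, config)

    masses = load_model.segment_masses(subject.body_mass, config)
    a_vert = {seg: p.a_vert for seg, p in processed.items()}
    if mode == "full":
        grf = load_model.estimate_grf_full(base.t, a_vert, masses)
    else:
        grf = load_model.estimate_grf_foot_only(base.t, a_vert, masses)
    fl = load_model.extract_forefoot_load(grf, steps)
    return TrialEstimate(
        grf=grf,
        events=events,
        steps=steps,
        fl=fl,
        segments=processed,
        n_discarded_steps=n_discarded,
        mode=mode,
    )


def _filtered_force(force: ForceRecording, config: AnalysisConfig) -> ForceRecording:
    spec = _filter_spec(config)
    fs = 1.0 / float(np.median(np.diff(force.t)))
    channels = np.column_stack(
        [
            np.clip(critically_damped_lowpass(force.channels[:, i], fs, spec), 0, None)
            for i in range(4)
        ]
    )
    return ForceRecording(force.t, channels, force.saturation_limit)


def validate_trial(
    recordings: dict,
    force: ForceRecording,
    subject: SubjectProfile,
    config: AnalysisConfig | None = None,
    protocol: str = "corridor",
    mode: str = "full",
    n_required: int | None = None,
    require_clean_sampling: bool = True,
) -> tuple[ValidationSummary, TrialEstimate]:
    """Correlate estimated forefoot load with the force-sensor reference.

    Reference traces receive the same low-pass filter as the motion data.
    Trials with sampling defects are excluded from validation (raises
    :class:`DataError`) unless ``require_clean_sampling`` is disabled.
    """
    config = config or AnalysisConfig()
    if require_clean_sampling:
        bad = [
            seg
            for seg, rec in recordings.items()
            if not screen_sampling(rec, config.sampling_tolerance).ok
        ]
        if bad:
            raise DataError(f"sampling errors in segment(s) {bad}; trial excluded")
    est = estimate_trial(recordings, subject, config, mode=mode)
    force_f = _filtered_force(force, config)
    correlations = []
    for i, sl in enumerate(est.fl.steps):
        ref = reference_forefoot(force_f, sl.step.forefoot_window)
        ref_on_grid = np.interp(sl.t, ref.t, ref.force)
        try:
            r = per_step_pearson(sl.fl_kgf, ref_on_grid)
        except ParameterError:
            continue  # zero-variance window: step excluded
        correlations.append(StepCorrelation(step_id=i, foot=sl.step.foot, r=r))
    summary = summarize_validation(correlations, protocol=protocol, n_required=n_required)
    return summary, est


def excessive_profile(
    baseline_fl: load_model.ForefootLoadSeries,
    config: AnalysisConfig | None = None,
) -> ExcessiveLoadProfile:
    """Excessive-load profile from a designated corridor baseline trial."""
    config = config or AnalysisConfig()
    maxima = baseline_fl.max_fl_per_step
    base = maxima[: config.baseline_steps]
    threshold = excessive_threshold(
        maxima,
        k_sd=config.k_sd,
        n_baseline=config.baseline_steps,
        decimals=config.round_decimals,
    )
    n_exc, rate = classify_excessive(maxima, threshold)
    return ExcessiveLoadProfile(
        baseline_mean=float(np.mean(base)),
        baseline_sd=float(np.std(base)),
        threshold=threshold,
        max_fl_per_step=maxima,
        n_excessive=n_exc,
        rate=rate,
    )


def analyze_daily(
    recordings: dict,
    subject: SubjectProfile,
    threshold: float,
    config: AnalysisConfig | None = None,
    mode: str = "foot_only",
):
    """Free-living analysis: bouts, per-step loads, excessive-load counts.

    Long recordings tolerate sampling gaps: each segment stream is split at
    its gaps and the aligned chunks are processed independently.  Tilt
    integration is re-anchored at stationary intervals.
    """
    config = config or AnalysisConfig()
    needed = FOOT_ONLY_SEGMENTS if mode == "foot_only" else FULL_MODE_SEGMENTS
    missing = [s for s in needed if s not in recordings]
    if missing:
        raise DataError(f"daily analysis missing segment(s): {missing}")

    # split every stream at the union of all gap boundaries
    reports = {seg: screen_sampling(recordings[seg], config.sampling_tolerance)
               for seg in needed}
    boundaries = sorted({i for rep in reports.values() for i, _ in rep.gaps})
    chunk_lists = {}
    for seg in needed:
        rep = reports[seg]
        rep = type(rep)(ok=not boundaries, gaps=[(i, 0.0) for i in boundaries],
                        fs=rep.fs, n=rep.n)
        chunk_lists[seg] = split_at_gaps(recordings[seg], rep)
    n_chunks = min(len(v) for v in chunk_lists.values())

    all_steps = []
    grfs = []
    for c in range(n_chunks):
        chunk = {seg: chunk_lists[seg][c] for seg in needed}
        if chunk[needed[0]].duration < config.static_window_s + 1.0:
            continue
        est = estimate_trial(
            chunk, subject, config, mode=mode, reinit_stationary=True
        )
        all_steps.extend(est.steps)
        grfs.append(est.grf)

    bouts = gait_events.detect_bouts(
        all_steps, gap_s=config.bout_max_gap_s, min_duration_s=config.bout_min_duration_s
    )
    fl_by_bout = []
    for bout in bouts:
        fls = load_model.ForefootLoadSeries()
        for grf in grfs:
            part = load_model.extract_forefoot_load(
                grf, [s for s in bout.steps if grf.t[0] <= s.hc <= grf.t[-1]]
            )
            fls.steps.extend(part.steps)
            fls.n_skipped += part.n_skipped
        fl_by_bout.append(fls)
    recorded_s = float(recordings[needed[0]].duration)
    report = daily_report(bouts, fl_by_bout, threshold, recorded_s)
    return report, bouts, fl_by_bout
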