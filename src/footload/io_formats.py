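"""On-disk formats: IMU / force-sensor CSV logs, YAML analysis config, JSON reports.

All CSV files are comma separated with one header row.  Time is in seconds from
recording start.  An optional leading comment line of the form

    # acc_unit=m/s2 gyro_unit=rad/s

declares sensor units; accelerations default to m/s^2 and angular velocities to
rad/s.  Supported alternatives (``acc_unit=g``, ``gyro_unit=deg/s``) are
converted on read so that every in-memory series is SI.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "DataError",
    "ParameterError",
    "ProtocolError",
    "SEGMENTS",
    "FOOT_SEGMENTS",
    "ImuRecording",
    "ForceRecording",
    "SubjectProfile",
    "AnalysisConfig",
    "SamplingReport",
    "read_imu_csv",
    "write_imu_csv",
    "read_force_csv",
    "write_force_csv",
    "screen_sampling",
    "split_at_gaps",
    "write_report",
    "read_report",
]

#: gravitational constant used throughout (m/s^2); 1 kgf = G newtons
G = 9.8

SEGMENTS = ("sacrum", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")
FOOT_SEGMENTS = ("foot_L", "foot_R")

IMU_COLUMNS = ("time", "ax", "ay", "az", "gx", "gy", "gz")
FORCE_COLUMNS = ("time", "f1", "f2", "f3", "f4")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class DataError(ValueError):
    """A file parses but its content violates a data invariant."""


class ParameterError(ValueError):
    """An operation was called with invalid parameters."""


class ProtocolError(RuntimeError):
    """A measurement protocol requirement is not met (e.g. too few steps)."""


@dataclass
class ImuRecording:
    """Time series from one inertial sensor fixed to a body segment.

    Axes follow the segment-local convention: ``x`` is the medio-lateral pitch
    axis, ``y``/``z`` span the sagittal plane.  ``acc`` is in m/s^2 and
    ``gyro`` in rad/s, both shaped ``(n, 3)``.
    """

    segment_id: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.segment_id not in SEGMENTS:
            raise ParameterError(
                f"unknown segment {self.segment_id!r}; expected one of {SEGMENTS}"
            )
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.t.ndim != 1 or len(self.t) == 0:
            raise DataError("time vector must be 1-D and non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"{self.segment_id}: time vector is not strictly increasing")
        for name, arr in (("acc", self.acc), ("gyro", self.gyro)):
            if arr.shape != (len(self.t), 3):
                raise DataError(
                    f"{self.segment_id}: {name} has shape {arr.shape}, "
                    f"expected ({len(self.t)}, 3)"
                )

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class ForceRecording:
    """Four forefoot force channels (N), two per metatarsal head (MTH1/MTH2).

    The physical sensors saturate; readings at or above ``saturation_limit``
    are pinned and should be treated as censored.
    """

    t: np.ndarray
    channels: np.ndarray
    saturation_limit: float = 40.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape != (len(self.t), 4):
            raise DataError(
                f"force channels have shape {self.channels.shape}, "
                f"expected ({len(self.t)}, 4)"
            )
        if np.any(np.diff(self.t) <= 0):
            raise DataError("force time vector is not strictly increasing")
        if np.any(self.channels < -1e-9):
            raise DataError("force channels contain negative values")


@dataclass
class SubjectProfile:
    subject_id: str
    body_mass: float  # kg
    notes: str = ""

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ParameterError("body mass must be positive")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the estimation pipeline with their defaults."""

    # preprocessing
    filter_cutoff_hz: float = 20.0
    filter_order: int = 4
    static_window_s: float = 1.0
    # gait events
    min_hc_gap_s: float = 0.2       # contralateral TO -> ipsilateral HC
    min_stance_s: float = 0.6       # ipsilateral HC -> TO
    stance_fraction_band: tuple = (0.45, 0.75)
    min_stance_duration_s: float = 0.4
    min_swing_duration_s: float = 0.2
    # walking bouts
    bout_max_gap_s: float = 1.5
    bout_min_duration_s: float = 30.0
    # anthropometry (fraction of body mass, per side; upper body = remainder)
    fraction_foot: float = 0.011
    fraction_shank: float = 0.051
    fraction_thigh: float = 0.110
    g: float = G
    # excessive-load profiling
    baseline_steps: int = 15
    k_sd: float = 2.0
    round_decimals: int = 1
    # sampling screen
    sampling_tolerance: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "filter_cutoff_hz", "static_window_s", "min_hc_gap_s", "min_stance_s",
            "min_stance_duration_s", "min_swing_duration_s", "bout_max_gap_s",
            "bout_min_duration_s", "g",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.filter_order <= 0 or self.filter_order % 2:
            raise ParameterError("filter_order must be a positive even integer")
        fracs = (self.fraction_foot, self.fraction_shank, self.fraction_thigh)
        if any(not 0 < f < 1 for f in fracs):
            raise ParameterError("mass fractions must lie in (0, 1)")
        if 2 * sum(fracs) >= 1:
            raise ParameterError(
                "leg mass fractions leave no upper-body mass: 2*(foot+shank+thigh) >= 1"
            )
        lo, hi = self.stance_fraction_band
        if not 0 < lo < hi < 1:
            raise ParameterError("stance_fraction_band must satisfy 0 < lo < hi < 1")
        if self.baseline_steps < 2:
            raise ParameterError("baseline_steps must be at least 2")

    @property
    def fraction_upper(self) -> float:
        return 1.0 - 2.0 * (self.fraction_foot + self.fraction_shank + self.fraction_thigh)

    # --- YAML round trip -------------------------------------------------
    _YAML_MAP = {
        "filter.cutoff_hz": "filter_cutoff_hz",
        "filter.order": "filter_order",
        "preprocess.static_window_s": "static_window_s",
        "events.min_hc_gap_s": "min_hc_gap_s",
        "events.min_stance_s": "min_stance_s",
        "events.stance_fraction_band": "stance_fraction_band",
        "events.min_stance_duration_s": "min_stance_duration_s",
        "events.min_swing_duration_s": "min_swing_duration_s",
        "bouts.max_gap_s": "bout_max_gap_s",
        "bouts.min_duration_s": "bout_min_duration_s",
        "masses.fraction_foot": "fraction_foot",
        "masses.fraction_shank": "fraction_shank",
        "masses.fraction_thigh": "fraction_thigh",
        "model.g": "g",
        "excessive.baseline_steps": "baseline_steps",
        "excessive.k_sd": "k_sd",
        "excessive.round_decimals": "round_decimals",
        "sampling.tolerance": "sampling_tolerance",
    }

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for section, val in raw.items():
            if isinstance(val, dict):
                for key, v in val.items():
                    flat[f"{section}.{key}"] = v
            else:
                flat[section] = val
        kwargs = {}
        for dotted, value in flat.items():
            try:
                attr = cls._YAML_MAP[dotted]
            except KeyError:
                raise FormatError(f"unknown config key {dotted!r}") from None
            if attr == "stance_fraction_band":
                value = tuple(value)
            kwargs[attr] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        nested: dict = {}
        for dotted, attr in self._YAML_MAP.items():
            section, key = dotted.split(".")
            value = getattr(self, attr)
            if isinstance(value, tuple):
                value = list(value)
            nested.setdefault(section, {})[key] = value
        with open(path, "w") as fh:
            yaml.safe_dump(nested, fh, sort_keys=True)


@dataclass
class SamplingReport:
    """Result of screening a recording for sampling defects."""

    ok: bool
    gaps: list = field(default_factory=list)  # (index, interval_s) pairs
    fs: float = 0.0
    n: int = 0

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _read_units_header(path) -> dict:
    units = {"acc_unit": "m/s2", "gyro_unit": "rad/s"}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split():
            if "=" in token:
                key, _, val = token.partition("=")
                units[key.strip()] = val.strip()
    return units


_ACC_SCALE = {"m/s2": 1.0, "g": G}
_GYRO_SCALE = {"rad/s": 1.0, "deg/s": np.pi / 180.0}


def read_imu_csv(path, segment_id: str, fs: float | None = None) -> ImuRecording:
    """Read one segment's IMU log; units are converted to m/s^2 and rad/s."""
    path = Path(path)
    units = _read_units_header(path)
    try:
        acc_scale = _ACC_SCALE[units["acc_unit"]]
        gyro_scale = _GYRO_SCALE[units["gyro_unit"]]
    except KeyError as exc:
        raise FormatError(f"{path}: unsupported unit {exc}") from None
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float) * acc_scale
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * gyro_scale
    return ImuRecording(segment_id=segment_id, t=t, acc=acc, gyro=gyro, fs=fs)


def write_imu_csv(rec: ImuRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.acc, rec.gyro]), columns=list(IMU_COLUMNS)
    )
    with open(path, "w") as fh:
        fh.write("# acc_unit=m/s2 gyro_unit=rad/s\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_force_csv(path, saturation_limit: float = 40.0) -> ForceRecording:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in FORCE_COLUMNS]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    t = df["time"].to_numpy(dtype=float)
    channels = df[["f1", "f2", "f3", "f4"]].to_numpy(dtype=float)
    return ForceRecording(t=t, channels=channels, saturation_limit=saturation_limit)


def write_force_csv(force: ForceRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([force.t, force.channels]), columns=list(FORCE_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Sampling screen


def screen_sampling(rec: ImuRecording, tolerance: float = 0.1) -> SamplingReport:
    """Flag recordings whose inter-sample intervals deviate from 1/fs.

    A gap is an interval differing from the nominal period by more than
    ``tolerance`` (as a fraction of the period).  Trials with any gap are
    excluded from validation analyses; long free-living recordings are instead
    split at each gap (see :func:`split_at_gaps`).
    """
    if rec.n < 2:
        return SamplingReport(ok=True, gaps=[], fs=rec.fs, n=rec.n)
    period = 1.0 / rec.fs
    dt = np.diff(rec.t)
    bad = np.abs(dt - period) > tolerance * period
    gaps = [(int(i), float(dt[i])) for i in np.nonzero(bad)[0]]
    return SamplingReport(ok=not gaps, gaps=gaps, fs=rec.fs, n=rec.n)


def split_at_gaps(rec: ImuRecording, report: SamplingReport) -> list:
    """Split a recording into uniformly sampled chunks at each reported gap."""
    if report.ok:
        return [rec]
    edges = [0] + [i + 1 for i, _ in report.gaps] + [rec.n]
    chunks = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a >= 2:
            chunks.append(
                ImuRecording(rec.segment_id, rec.t[a:b], rec.acc[a:b], rec.gyro[a:b], rec.fs)
            )
    return chunks


# ---------------------------------------------------------------------------
# JSON reports


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path) -> None:
    """Serialize a report (dataclass or plain mapping) to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON ({exc})") from exc
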