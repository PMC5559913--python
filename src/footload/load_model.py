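"""Whole-body vertical ground reaction force from a seven-rigid-link model.

The body is modeled as an upper body (mass ``m_b``) plus thigh, shank and
foot on each side (masses ``m_1 .. m_3`` per side).  With all motion in the
sagittal plane, the vertical plantar load is the sum of the mass-acceleration
products of all segments:

    N(t) = m_b (a_b + g) + sum_i m_i (a_iR + a_iL + 2 g)

where the ``a`` are *dynamic* (gravity-free) vertical accelerations; gravity
appears explicitly through the ``g`` terms, so that quiet standing yields
exactly body weight.  ``N`` is whole-body and is not apportioned between the
feet during double support; since the load under one foot cannot exceed the
total, the estimate never understates the forefoot load.

Loads are also reported in kilogram-force (kgf = N / g, with g = 9.8 m/s^2),
the unit used for excessive-load thresholds.

Segment masses come from anthropometric fractions of body mass (defaults:
foot 0.011, shank 0.051, thigh 0.110 per side; upper body the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnalysisConfig, ParameterError

__all__ = [
    "BodySegmentMasses",
    "GrfSeries",
    "StepLoad",
    "ForefootLoadSeries",
    "segment_masses",
    "estimate_grf_full",
    "estimate_grf_foot_only",
    "extract_forefoot_load",
]


@dataclass(frozen=True)
class BodySegmentMasses:
    """Per-segment masses (kg); leg masses are per side."""

    m_upper: float
    m_thigh: float
    m_shank: float
    m_foot: float
    g: float = 9.8

    def __post_init__(self) -> None:
        if min(self.m_upper, self.m_thigh, self.m_shank, self.m_foot) <= 0:
            raise ParameterError("all segment masses must be positive")

    @property
    def body_mass(self) -> float:
        return self.m_upper + 2.0 * (self.m_thigh + self.m_shank + self.m_foot)

    def foot_mass_reported(self, decimals: int = 1) -> float:
        """Foot mass rounded for reporting (kg)."""
        return round(self.m_foot, decimals)


def segment_masses(
    body_mass: float, config: AnalysisConfig | None = None
) -> BodySegmentMasses:
    """Split body mass into segment masses using anthropometric fractions.

    The upper body takes the remainder, so the masses close exactly:
    ``m_upper + 2*(m_thigh + m_shank + m_foot) == body_mass``.
    """
    if body_mass <= 0:
        raise ParameterError("body mass must be positive")
    config = config or AnalysisConfig()
    m_foot = config.fraction_foot * body_mass
    m_shank = config.fraction_shank * body_mass
    m_thigh = config.fraction_thigh * body_mass
    m_upper = body_mass - 2.0 * (m_foot + m_shank + m_thigh)
    return BodySegmentMasses(
        m_upper=m_upper, m_thigh=m_thigh, m_shank=m_shank, m_foot=m_foot, g=config.g
    )


@dataclass
class GrfSeries:
    """Estimated vertical plantar load: newtons and kgf, with the time base."""

    t: np.ndarray
    newton: np.ndarray
    mode: str  # "full" | "foot_only"
    g: float = 9.8

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.newton = np.asarray(self.newton, dtype=float)
        if self.t.shape != self.newton.shape:
            raise ParameterError("time and load series must have equal length")
        if not np.all(np.isfinite(self.newton)):
            raise ParameterError("load series contains non-finite values")

    @property
    def kgf(self) -> np.ndarray:
        return self.newton / self.g


def _stack_series(series: dict, keys: tuple) -> dict:
    out = {}
    n = None
    for key in keys:
        arr = np.asarray(series[key], dtype=float)
        if n is None:
            n = len(arr)
        elif len(arr) != n:
            raise ParameterError(f"vertical-acceleration series {key} length mismatch")
        out[key] = arr
    return out


def estimate_grf_full(
    t: np.ndarray,
    a_vert: dict,
    masses: BodySegmentMasses,
) -> GrfSeries:
    """Vertical GRF from all seven segments' dynamic vertical accelerations.

    ``a_vert`` maps segment ids (``sacrum``, ``thigh_L`` .. ``foot_R``) to
    gravity-free vertical acceleration series (m/s^2).
    """
    keys = ("sacrum", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")
    a = _stack_series(a_vert, keys)
    g = masses.g
    n = masses.m_upper * (a["sacrum"] + g)
    for name, m in (
        ("thigh", masses.m_thigh),
        ("shank", masses.m_shank),
        ("foot", masses.m_foot),
    ):
        n = n + m * (a[f"{name}_R"] + a[f"{name}_L"] + 2.0 * g)
    return GrfSeries(t=t, newton=n, mode="full")


def estimate_grf_foot_only(
    t: np.ndarray,
    a_vert: dict,
    masses: BodySegmentMasses,
) -> GrfSeries:
    """Vertical GRF using only the two foot sensors.

    All non-foot dynamic accelerations are taken as zero, which preserves the
    model's structure and its static closure (quiet standing still yields
    body weight); since validation is correlation-based, the resulting
    additive constant is immaterial.
    """
    a = _stack_series(a_vert, ("foot_L", "foot_R"))
    g = masses.g
    n = (
        masses.m_upper * g
        + 2.0 * g * (masses.m_thigh + masses.m_shank + masses.m_foot)
        + masses.m_foot * (a["foot_R"] + a["foot_L"])
    )
    return GrfSeries(t=t, newton=n, mode="foot_only")


@dataclass
class StepLoad:
    """Forefoot-load samples of one step over its forefoot-contact window."""

    step: object
    t: np.ndarray
    fl_kgf: np.ndarray

    @property
    def max_fl(self) -> float:
        return float(np.max(self.fl_kgf))


@dataclass
class ForefootLoadSeries:
    """Per-step forefoot loads; samples outside the windows are undefined."""

    steps: list = field(default_factory=list)  # list[StepLoad]
    n_skipped: int = 0

    @property
    def max_fl_per_step(self) -> np.ndarray:
        return np.array([s.max_fl for s in self.steps])


def extract_forefoot_load(grf: GrfSeries, steps: list) -> ForefootLoadSeries:
    """Restrict the load series (kgf) to each step's forefoot window.

    Steps whose window falls outside the series' time span are skipped and
    counted in ``n_skipped``.
    """
    kgf = grf.kgf
    out = ForefootLoadSeries()
    for step in steps:
        t0, t1 = step.forefoot_window
        if t0 < grf.t[0] or t1 > grf.t[-1]:
            out.n_skipped += 1
            continue
        mask = (grf.t >= t0) & (grf.t <= t1)
        if not np.any(mask):
            out.n_skipped += 1
            continue
        out.steps.append(StepLoad(step=step, t=grf.t[mask], fl_kgf=kgf[mask]))
    return out
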