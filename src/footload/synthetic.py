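"""Physically consistent synthetic gait trials with known ground truth.

The generator prescribes a heel-contact / toe-off schedule for both feet, a
per-foot double-hump vertical load profile, and smooth segment tilt
trajectories, then *inverts* the estimation model: it solves the whole-body
Newton equation for the trunk's vertical acceleration so that the seven
segments' accelerations reproduce the prescribed total load exactly, and
maps every vertical acceleration back into the sensor frames given the tilt
series.  Running the estimation pipeline on a noise-free trial therefore
recovers the prescribed load up to filtering and integration error, and the
prescribed events up to grid resolution.

Foot signals are shaped so their sign changes mark the events:

* the dynamic foot z-acceleration is a smooth one-harmonic waveform with
  exactly two zero crossings per gait cycle - downward at heel contact and
  upward early in stance, where the timing rules discard it;
* the foot pitch angular velocity is a triplet of raised-sine lobes around
  each toe off (heel-rise, push-off reversal, swing correction) whose areas
  cancel, so the tilt angle returns to its initial value every cycle.

Force-sensor references share the forefoot-window load across four channels
with fixed weights, saturate at the sensor limit, and decay to zero outside
the windows.

Every random term (sensor noise) comes from one seeded generator, so trials
are bit-reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .gait_events import Step
from .io_formats import ForceRecording, ImuRecording, ParameterError
from .load_model import segment_masses

__all__ = [
    "GaitSimConfig",
    "SimulatedTrial",
    "simulate_grf_profile",
    "simulate_trial",
    "simulate_force_sensors",
    "simulate_daily_walk",
    "inject_sampling_gaps",
]


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions of a simulated level-corridor walking trial.

    Defaults emulate the laboratory protocol the estimator targets: a healthy
    adult (61 kg, the cohort mean) walking at a self-selected pace
    (1.1 s/cycle, stance 60% of the cycle) for about 30 steps, sampled at
    100 Hz, with a standard double-hump vertical load profile peaking at
    1.2 and 1.1 body weights.
    """

    body_mass: float = 61.0          # kg
    cadence: float = 1.1             # s per gait cycle
    n_steps: int = 30                # complete (analyzable) steps, both feet
    stance_fraction: float = 0.6
    fs: float = 100.0
    static_window_s: float = 1.0
    tail_s: float = 0.5
    # vertical load profile (fractions of body weight / of stance duration)
    hump_amplitudes: tuple = (1.2, 1.1)
    hump_times: tuple = (0.25, 0.75)
    hump_width: float = 0.2
    valley_time: float = 0.5
    valley_width: float = 0.3
    # foot signal shaping
    a3z_swing_amp: float = 8.0       # m/s^2, peak of the swing lobe
    gyro_lobe_amps: tuple = (1.5, 1.0)  # rad/s, heel-rise and swing lobes
    # free sensor-frame components and leg motion
    lateral_acc_amp: float = 0.5     # m/s^2, sagittal y-axis extra motion
    leg_acc_amp: float = 1.5         # m/s^2, thigh/shank vertical accel
    long_tilt_amp: float = 0.08      # rad, thigh/shank/trunk tilt oscillation
    theta0_foot: float = 0.05        # rad, initial foot tilt
    theta0_long: float = math.pi / 2 - 0.08
    # noise (SD, added to every axis)
    accel_noise_sd: float = 0.0      # m/s^2
    gyro_noise_sd: float = 0.0       # rad/s
    force_noise_sd: float = 0.0      # N
    seed: int = 0
    # force-sensor model
    force_weights: tuple = (0.4, 0.3, 0.2, 0.1)
    forefoot_coupling: float = 0.07  # fraction of total load seen by the sensors
    saturation_n: float = 40.0
    # planted excessive steps: chronological step index -> load scale factor
    excessive_steps: dict = field(default_factory=dict)
    # route most load variation through the foot accelerations instead of the
    # trunk (exercises the foot-only estimation mode)
    foot_dominated: bool = False
    g: float = 9.8
    min_hc_gap_s: float = 0.2        # detector constraints the schedule must obey
    min_stance_s: float = 0.6

    def __post_init__(self) -> None:
        if self.cadence <= 0 or self.body_mass <= 0 or self.n_steps < 1:
            raise ParameterError("cadence, body_mass and n_steps must be positive")
        if not 0.4 < self.stance_fraction < 0.8:
            raise ParameterError("stance_fraction must lie in (0.4, 0.8)")
        if min(self.hump_amplitudes) <= 0:
            raise ParameterError("hump amplitudes must be positive")
        stance = self.stance_fraction * self.cadence
        if stance < self.min_stance_s:
            raise ParameterError(
                f"stance duration {stance:.3f} s is shorter than the detector's "
                f"minimum stance {self.min_stance_s} s; increase cadence or "
                "stance_fraction"
            )
        if self.stance_fraction <= 0.5:
            raise ParameterError("stance_fraction must exceed 0.5 (double support)")


@dataclass
class Schedule:
    """Prescribed event times (s) and derived steps for one trial."""

    hc: dict            # side -> array of HC times (incl. terminal landing)
    to: dict            # side -> array of TO times (incl. initial liftoff)
    steps: list         # chronological list of complete Step objects
    t_end: float


def _build_schedule(config: GaitSimConfig, t0: float = 0.0) -> Schedule:
    T = config.cadence
    sf = config.stance_fraction
    swing = (1.0 - sf) * T
    ts = t0 + config.static_window_s
    n = config.n_steps
    m_l = (n + 1) // 2
    m_r = n // 2

    to_l = ts + T * np.arange(m_l + 1)
    hc_l = ts + swing + T * np.arange(m_l + 1)          # last one: terminal landing
    to_r = ts + 0.5 * T + T * np.arange(m_r + 1)
    hc_r = ts + 0.5 * T + swing + T * np.arange(m_r + 1)

    steps = []
    for k in range(m_l):
        steps.append(
            Step(
                foot="L",
                hc=float(hc_l[k]),
                to=float(to_l[k + 1]),
                forefoot_start=float(to_r[k]),
                forefoot_end=float(to_l[k + 1]),
                cycle_duration=T,
            )
        )
    for k in range(m_r):
        steps.append(
            Step(
                foot="R",
                hc=float(hc_r[k]),
                to=float(to_r[k + 1]),
                forefoot_start=float(to_l[k + 1]),
                forefoot_end=float(to_r[k + 1]),
                cycle_duration=T,
            )
        )
    steps.sort(key=lambda s: s.hc)
    t_end = max(hc_l[-1], hc_r[-1]) + 0.4 * T + config.tail_s
    return Schedule(
        hc={"L": hc_l, "R": hc_r}, to={"L": to_l, "R": to_r}, steps=steps, t_end=t_end
    )


# ---------------------------------------------------------------------------
# waveform helpers


def _sin2_bump(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Raised-sine bump on [start, start+width], peak 1, area width/2."""
    u = (t - start) / width
    out = np.zeros_like(t)
    mask = (u >= 0) & (u <= 1)
    out[mask] = np.sin(np.pi * u[mask]) ** 2
    return out


def _ramp(t: np.ndarray, start: float, width: float, rising: bool = True) -> np.ndarray:
    """Half-cosine ramp 0->1 over [start, start+width] (or 1->0)."""
    u = np.clip((t - start) / width, 0.0, 1.0)
    r = 0.5 * (1.0 - np.cos(np.pi * u))
    return r if rising else 1.0 - r


def _contact(t: np.ndarray, hc: np.ndarray, to: np.ndarray, ds: float) -> np.ndarray:
    """Smooth contact indicator: up-ramps after each HC, down-ramps into each TO.

    The foot stands on the ground before its first liftoff and after its
    terminal landing, so the contact intervals are [start, TO_0],
    [HC_0, TO_1], ..., [HC_last, end].
    """
    hc = np.sort(np.asarray(hc, dtype=float))
    to = np.sort(np.asarray(to, dtype=float))
    starts = [None] + list(hc)
    ends = list(to) + [None]
    c = np.zeros_like(t)
    for a, b in zip(starts, ends):
        w = np.ones_like(t)
        if a is not None:
            w = w * _ramp(t, a, ds, rising=True)
            w[t < a] = 0.0
        if b is not None:
            w = w * _ramp(t, b - ds, ds, rising=False)
            w[t > b] = 0.0
        c += w
    return np.clip(c, 0.0, 1.0)


def _stance_modulation(
    t: np.ndarray, schedule: Schedule, side: str, config: GaitSimConfig
) -> np.ndarray:
    """Two-hump load modulation h(t): 1 at phase boundaries, peaks A1/A2.

    The midstance valley depth is solved so that the extra impulse of the
    humps cancels and the net vertical impulse over a cycle stays zero.
    """
    a1, a2 = config.hump_amplitudes
    w = config.hump_width
    wv = config.valley_width
    p1, p2 = config.hump_times
    pv = config.valley_time
    a_valley = 1.0 - ((a1 - 1.0) + (a2 - 1.0)) * w / wv

    h = np.ones_like(t)
    steps = [s for s in schedule.steps if s.foot == side]
    order = {id(s): i for i, s in enumerate(schedule.steps)}
    for s in steps:
        scale = config.excessive_steps.get(order[id(s)], 1.0)
        stance = s.to - s.hc
        phase = (t - s.hc) / stance
        shape = (
            (a1 - 1.0) * _sin2_bump(phase, p1 - w / 2, w)
            + (a2 - 1.0) * _sin2_bump(phase, p2 - w / 2, w)
            + (a_valley - 1.0) * _sin2_bump(phase, pv - wv / 2, wv)
        )
        h = h + scale * shape
    return h


def _per_foot_loads(
    t: np.ndarray, schedule: Schedule, config: GaitSimConfig
) -> dict:
    """Per-foot vertical load (kgf): weight share times hump modulation."""
    ds = (config.stance_fraction - 0.5) * config.cadence
    c = {
        side: _contact(t, schedule.hc[side], schedule.to[side], ds)
        for side in ("L", "R")
    }
    total = c["L"] + c["R"]
    total[total < 1e-12] = 1.0  # never both airborne in walking
    loads = {}
    for side in ("L", "R"):
        share = c[side] / total
        loads[side] = config.body_mass * share * _stance_modulation(
            t, schedule, side, config
        )
    return loads


def _a3z_waveform(
    t: np.ndarray, schedule: Schedule, side: str, config: GaitSimConfig
) -> np.ndarray:
    """Dynamic foot z-acceleration: two zero crossings per cycle.

    ``A (cos(2 pi phi + beta) - cos beta)`` crosses downward at phase 0 (heel
    contact) and back upward at phase delta/T, inside early stance where the
    joint detector discards it; it is strictly positive over the rest of the
    cycle (swing lobe).
    """
    T = config.cadence
    ds = (config.stance_fraction - 0.5) * T
    stance = config.stance_fraction * T
    delta = ds + min(0.1, 0.4 * (stance - ds))
    beta = math.pi * (1.0 - delta / T)
    amp = config.a3z_swing_amp / (1.0 - math.cos(beta))

    hc = schedule.hc[side]
    to = schedule.to[side]
    hc0, hc_term = hc[0], hc[-1]
    to0 = to[0]
    phase = (t - hc0) / T
    x = amp * (np.cos(2.0 * np.pi * phase + beta) - math.cos(beta))
    # active only from initial liftoff to shortly after the terminal landing
    x *= _ramp(t, to0, 0.15 * T, rising=True)
    x *= _ramp(t, hc_term + delta + 0.05 * T, 0.15 * T, rising=False)
    x[t < to0] = 0.0
    x[t > hc_term + delta + 0.2 * T] = 0.0
    return x


def _r3x_waveform(
    t: np.ndarray, schedule: Schedule, side: str, config: GaitSimConfig
) -> np.ndarray:
    """Foot pitch angular velocity: lobe triplet around each toe off.

    Heel-rise (positive, ends at TO), push-off reversal (negative), swing
    correction (positive); lobe areas cancel so the tilt is cyclic.
    """
    T = config.cadence
    a_rise, a_swing = config.gyro_lobe_amps
    w_rise, w_neg, w_swing = 0.15 * T, 0.25 * T, 0.15 * T
    a_neg = (a_rise * w_rise + a_swing * w_swing) / w_neg
    x = np.zeros_like(t)
    for u in schedule.to[side]:
        x += a_rise * _sin2_bump(t, u - w_rise, w_rise)
        x -= a_neg * _sin2_bump(t, u, w_neg)
        x += a_swing * _sin2_bump(t, u + w_neg, w_swing)
    return x


# ---------------------------------------------------------------------------
# public operations


def simulate_grf_profile(config: GaitSimConfig | None = None):
    """Prescribed whole-body vertical load N*(t).

    Returns ``(t, n_star_kgf)``: a smooth double-hump curve per stance,
    body-weight between and outside walking periods.
    """
    config = config or GaitSimConfig()
    schedule = _build_schedule(config)
    t = np.arange(0.0, schedule.t_end, 1.0 / config.fs)
    loads = _per_foot_loads(t, schedule, config)
    return t, loads["L"] + loads["R"]


def simulate_force_sensors(
    t: np.ndarray,
    n_star_newton: np.ndarray,
    windows: list,
    config: GaitSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ForceRecording:
    """Four-channel forefoot force reference.

    Within each forefoot window the channels share ``forefoot_coupling`` of
    the total load with fixed positive weights (edge-tapered so channels
    decay to zero outside the windows), clipped at the saturation limit,
    plus seeded noise.
    """
    config = config or GaitSimConfig()
    rng = rng or np.random.default_rng(config.seed)
    gate = np.zeros_like(t)
    edge = 0.05
    for (w0, w1) in windows:
        gate += _ramp(t, w0 - edge, edge, rising=True) * _ramp(
            t, w1, edge, rising=False
        ) * ((t >= w0 - edge) & (t <= w1 + edge))
    gate = np.clip(gate, 0.0, 1.0)
    level = config.forefoot_coupling * n_star_newton * gate
    channels = np.column_stack(
        [np.minimum(w * level, config.saturation_n) for w in config.force_weights]
    )
    if config.force_noise_sd > 0:
        channels = channels + rng.normal(0.0, config.force_noise_sd, channels.shape)
    channels = np.clip(channels, 0.0, config.saturation_n)
    return ForceRecording(
        t=np.array(t, dtype=float), channels=channels,
        saturation_limit=config.saturation_n,
    )


@dataclass
class SimulatedTrial:
    """A complete synthetic trial: sensor streams plus ground truth."""

    config: GaitSimConfig
    t: np.ndarray
    recordings: dict            # segment_id -> ImuRecording (noise applied)
    force: ForceRecording
    n_star_kgf: np.ndarray      # prescribed whole-body load
    a_vert: dict                # segment_id -> true dynamic vertical accel
    theta: dict                 # segment_id -> true tilt series
    events: dict                # side -> {"HC": times, "TO": times}
    steps: list                 # complete Step objects, chronological
    max_fl_per_step: np.ndarray # true per-step peak load over the window, kgf

    @property
    def n_star_newton(self) -> np.ndarray:
        return self.n_star_kgf * self.config.g

    def foot_recordings(self) -> dict:
        return {k: v for k, v in self.recordings.items() if k.startswith("foot")}


def simulate_trial(config: GaitSimConfig | None = None) -> SimulatedTrial:
    """Generate one walking trial; see the module docstring for the scheme."""
    config = config or GaitSimConfig()
    g = config.g
    schedule = _build_schedule(config)
    t = np.arange(0.0, schedule.t_end, 1.0 / config.fs)
    rng = np.random.default_rng(config.seed)
    masses = segment_masses(config.body_mass)

    loads = _per_foot_loads(t, schedule, config)
    n_star_kgf = loads["L"] + loads["R"]
    n_star_newton = n_star_kgf * g

    T = config.cadence
    ts = config.static_window_s
    walk_end = max(schedule.hc["L"][-1], schedule.hc["R"][-1])
    env = _ramp(t, ts, 0.2, rising=True) * _ramp(t, walk_end, 0.3, rising=False)
    env[t < ts] = 0.0

    theta: dict = {}
    omega: dict = {}
    a_vert: dict = {}
    ay_dyn: dict = {}
    az_dyn: dict = {}

    # feet: event-marking waveforms, tilt from the gyro lobes
    for side in ("L", "R"):
        seg = f"foot_{side}"
        r3x = _r3x_waveform(t, schedule, side, config)
        th = config.theta0_foot + cumulative_trapezoid(r3x, t, initial=0.0)
        e = _a3z_waveform(t, schedule, side, config)
        sy = config.lateral_acc_amp * env * np.sin(
            2.0 * np.pi * (t - ts) / T + (0.0 if side == "L" else np.pi)
        )
        theta[seg], omega[seg] = th, r3x
        az_dyn[seg], ay_dyn[seg] = e, sy
        a_vert[seg] = e * np.cos(th) - sy * np.sin(th)

    # thighs and shanks: small prescribed vertical motion
    for i, name in enumerate(("thigh_L", "thigh_R", "shank_L", "shank_R")):
        phase = np.pi * (i % 2) + 0.3 * (i // 2)
        th_raw = config.long_tilt_amp * env * np.sin(2.0 * np.pi * (t - ts) / T + phase)
        om = np.gradient(th_raw, t)
        th = config.theta0_long + cumulative_trapezoid(om, t, initial=0.0)
        av = config.leg_acc_amp * env * np.sin(4.0 * np.pi * (t - ts) / T + phase)
        sy = 0.5 * config.lateral_acc_amp * env * np.cos(2.0 * np.pi * (t - ts) / T)
        theta[name], omega[name] = th, om
        a_vert[name] = av
        ay_dyn[name] = sy
        az_dyn[name] = (av + sy * np.cos(th)) / np.sin(th)

    if config.foot_dominated:
        # Shift the load variation into the foot accelerations: each foot
        # carries its own load deviation from the quasi-static weight share,
        # so the trunk term (solved below) stays nearly constant and the
        # foot-only estimate tracks the prescribed load.  The stance-phase
        # deviation is zero outside the hump supports, so a swing lobe
        # ending exactly at each HC (with a small dip after it) recreates
        # the detector's sign-change structure (the trunk term, solved from
        # the whole-body equation, absorbs the small lobe contribution).
        ds = (config.stance_fraction - 0.5) * T
        c = {
            s: _contact(t, schedule.hc[s], schedule.to[s], ds) for s in ("L", "R")
        }
        total = c["L"] + c["R"]
        total[total < 1e-12] = 1.0
        stance_len = config.stance_fraction * T
        lobes = {}
        for side in ("L", "R"):
            hcs = schedule.hc[side]
            lobe = np.zeros_like(t)
            for k, h in enumerate(hcs):
                start = hcs[k - 1] + 0.85 * stance_len if k else schedule.to[side][0]
                lobe += 3.0 * _sin2_bump(t, start, h - start)
                lobe -= 3.0 * _sin2_bump(t, h, 0.05 * stance_len)
            lobes[side] = lobe
        for side in ("L", "R"):
            seg = f"foot_{side}"
            share = config.body_mass * c[side] / total
            a_vert[seg] = g * (loads[side] - share) / masses.m_foot + lobes[side]
            th = theta[seg]
            ay_dyn[seg] = np.zeros_like(t)  # keep a3z zeros at the load zeros
            az_dyn[seg] = a_vert[seg] / np.cos(th)

    # trunk: solve the whole-body equation so the total equals N*(t)
    leg_sum = np.zeros_like(t)
    for name, m in (("thigh", masses.m_thigh), ("shank", masses.m_shank),
                    ("foot", masses.m_foot)):
        leg_sum += m * (a_vert[f"{name}_L"] + a_vert[f"{name}_R"] + 2.0 * g)
    a_b = (n_star_newton - leg_sum) / masses.m_upper - g
    th_raw = 0.5 * config.long_tilt_amp * env * np.sin(2.0 * np.pi * (t - ts) / T)
    om = np.gradient(th_raw, t)
    th = config.theta0_long + cumulative_trapezoid(om, t, initial=0.0)
    sy = 0.3 * config.lateral_acc_amp * env * np.sin(2.0 * np.pi * (t - ts) / T + 0.7)
    theta["sacrum"], omega["sacrum"] = th, om
    a_vert["sacrum"] = a_b
    ay_dyn["sacrum"] = sy
    az_dyn["sacrum"] = (a_b + sy * np.cos(th)) / np.sin(th)

    # sensor-frame streams: constant gravity projection at theta0 + dynamics
    recordings: dict = {}
    for seg in theta:
        if seg.startswith("foot"):
            th0 = config.theta0_foot
            grav_y, grav_z = -g * math.sin(th0), g * math.cos(th0)
        else:
            th0 = config.theta0_long
            grav_y, grav_z = -g * math.cos(th0), g * math.sin(th0)
        acc = np.column_stack(
            [np.zeros_like(t), ay_dyn[seg] + grav_y, az_dyn[seg] + grav_z]
        )
        gyr = np.column_stack([omega[seg], np.zeros_like(t), np.zeros_like(t)])
        if config.accel_noise_sd > 0:
            acc = acc + rng.normal(0.0, config.accel_noise_sd, acc.shape)
        if config.gyro_noise_sd > 0:
            gyr = gyr + rng.normal(0.0, config.gyro_noise_sd, gyr.shape)
        recordings[seg] = ImuRecording(
            segment_id=seg, t=t.copy(), acc=acc, gyro=gyr, fs=config.fs
        )

    windows = [s.forefoot_window for s in schedule.steps]
    force = simulate_force_sensors(t, n_star_newton, windows, config, rng)

    max_fl = np.array(
        [
            float(np.max(n_star_kgf[(t >= w0) & (t <= w1)]))
            for (w0, w1) in windows
        ]
    )
    events = {
        side: {"HC": schedule.hc[side].copy(), "TO": schedule.to[side].copy()}
        for side in ("L", "R")
    }
    return SimulatedTrial(
        config=config,
        t=t,
        recordings=recordings,
        force=force,
        n_star_kgf=n_star_kgf,
        a_vert=a_vert,
        theta=theta,
        events=events,
        steps=schedule.steps,
        max_fl_per_step=max_fl,
    )


def simulate_daily_walk(
    config: GaitSimConfig,
    bouts: list,
    idle_gap_s: float = 5.0,
) -> tuple:
    """Concatenate several walking bouts separated by standing idle periods.

    ``bouts`` is a list of dicts overriding config fields per bout (typically
    ``n_steps`` and ``excessive_steps``).  Returns ``(recordings, trials)``
    where ``recordings`` maps segment ids to stitched streams and ``trials``
    holds the per-bout ground truth with times shifted into the global base.
    """
    if not bouts:
        raise ParameterError("need at least one bout")
    dt = 1.0 / config.fs
    idle_gap_s = round(idle_gap_s * config.fs) * dt  # keep the grid uniform
    trials = []
    offset = 0.0
    for i, over in enumerate(bouts):
        sub = replace(config, seed=config.seed + i, **over)
        trial = simulate_trial(sub)
        trial.t += offset
        for rec in trial.recordings.values():
            rec.t += offset
        trial.force.t += offset
        for side in ("L", "R"):
            trial.events[side]["HC"] += offset
            trial.events[side]["TO"] += offset
        for s in trial.steps:
            s.hc += offset
            s.to += offset
            s.forefoot_start += offset
            s.forefoot_end += offset
        trials.append(trial)
        offset = trial.t[-1] + idle_gap_s

    g = config.g
    rng = np.random.default_rng(config.seed + 10_000)
    recordings = {}
    for seg in trials[0].recordings:
        if seg.startswith("foot"):
            grav = (0.0, -g * math.sin(config.theta0_foot), g * math.cos(config.theta0_foot))
        else:
            grav = (0.0, -g * math.cos(config.theta0_long), g * math.sin(config.theta0_long))
        t_parts, acc_parts, gyr_parts = [], [], []
        for i, trial in enumerate(trials):
            rec = trial.recordings[seg]
            t_parts.append(rec.t)
            acc_parts.append(rec.acc)
            gyr_parts.append(rec.gyro)
            if i + 1 < len(trials):
                # standing idle between bouts: gravity-only samples
                n_gap = int(round((trials[i + 1].t[0] - rec.t[-1]) / dt)) - 1
                t_gap = rec.t[-1] + dt * np.arange(1, n_gap + 1)
                acc_gap = np.tile(np.array(grav), (len(t_gap), 1))
                gyr_gap = np.zeros((len(t_gap), 3))
                if config.accel_noise_sd > 0:
                    acc_gap = acc_gap + rng.normal(0, config.accel_noise_sd, acc_gap.shape)
                if config.gyro_noise_sd > 0:
                    gyr_gap = gyr_gap + rng.normal(0, config.gyro_noise_sd, gyr_gap.shape)
                t_parts.append(t_gap)
                acc_parts.append(acc_gap)
                gyr_parts.append(gyr_gap)
        recordings[seg] = ImuRecording(
            segment_id=seg,
            t=np.concatenate(t_parts),
            acc=np.vstack(acc_parts),
            gyro=np.vstack(gyr_parts),
            fs=config.fs,
        )
    return recordings, trials


def inject_sampling_gaps(
    rec: ImuRecording, gap_indices: list, gap_extra_s: float = 0.03
) -> ImuRecording:
    """Return a copy whose time base jumps by ``gap_extra_s`` at each index."""
    t = rec.t.copy()
    for i in sorted(gap_indices):
        if not 0 < i < len(t):
            raise ParameterError(f"gap index {i} out of range")
        t[i:] += gap_extra_s
    return ImuRecording(rec.segment_id, t, rec.acc.copy(), rec.gyro.copy(), rec.fs)
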