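"""Gait-event detection, step segmentation, and walking-bout detection.

Heel contact (HC) is marked by a sign change of the offset-free, low-pass
filtered foot z-acceleration, accepted only if at least ``min_hc_gap_s``
(default 0.2 s) has elapsed since the most recent toe off (TO) of the
*contralateral* foot.  TO is marked by a sign change of the foot pitch
angular velocity, accepted only if at least ``min_stance_s`` (default 0.6 s)
has elapsed since the most recent HC of the *ipsilateral* foot, keeping at
most one TO per HC.

Sign-change conventions: the event timestamp is the later sample of the
sign-change pair; a run of exact zeros entered from a nonzero sample yields a
single event at its first zero, and a run starting at the edge of the
searched range yields none (no transition was observed there).

:func:`detect_gait_events` applies both rules jointly in chronological order
over the two feet, additionally enforcing the per-foot alternation invariant
(between consecutive HCs of one foot there is exactly one TO of that foot).

A step is an HC paired with the following TO of the same foot; its
forefoot-contact window runs from the most recent contralateral TO (the
start of midstance) to the ipsilateral TO, which for level walking is the
midstance-plus-push-off period of roughly 0.6 s.  Steps with implausible
phase durations or stance fractions are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnalysisConfig, ParameterError

__all__ = [
    "FootEvents",
    "GaitEventSet",
    "Step",
    "WalkingBout",
    "zero_crossings",
    "detect_heel_contacts",
    "detect_toe_offs",
    "detect_gait_events",
    "segment_steps",
    "detect_bouts",
    "gait_cycle_stats",
]


@dataclass
class FootEvents:
    """Detected event times (s) for one foot, strictly increasing."""

    hc_times: np.ndarray
    to_times: np.ndarray
    hc_indices: np.ndarray
    to_indices: np.ndarray


@dataclass
class GaitEventSet:
    left: FootEvents
    right: FootEvents

    def foot(self, side: str) -> FootEvents:
        return self.left if side == "L" else self.right


@dataclass
class Step:
    """One gait step: stance from ``hc`` to ``to`` with its forefoot window.

    ``cycle_duration`` is the interval to the next HC of the same foot (or,
    for a foot's final step, the preceding cycle used as a proxy).
    """

    foot: str                      # "L" or "R"
    hc: float
    to: float
    forefoot_start: float
    forefoot_end: float
    cycle_duration: float | None = None

    @property
    def stance_duration(self) -> float:
        return self.to - self.hc

    @property
    def forefoot_window(self) -> tuple:
        return (self.forefoot_start, self.forefoot_end)


@dataclass
class WalkingBout:
    """A run of consecutive steps in a free-living recording."""

    start: float
    end: float
    steps: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_steps(self) -> int:
        return len(self.steps)


# ---------------------------------------------------------------------------
# Zero-crossing candidates


def zero_crossings(x: np.ndarray, atol: float = 0.0) -> np.ndarray:
    """Indices of sign-change events: ``x[i]*x[i+1] <= 0`` with ``x[i] != 0``.

    The event index is ``i+1`` (the first sample at/after the change).
    Requiring the left sample to be nonzero collapses a run of exact zeros to
    one event at its first sample and emits nothing for a run that begins at
    the array edge.  Values with magnitude at or below ``atol`` count as
    exact zeros, which keeps filter residue in silent stretches from
    masquerading as sign changes.
    """
    x = np.asarray(x, dtype=float)
    if atol > 0.0:
        x = np.where(np.abs(x) <= atol, 0.0, x)
    left, right = x[:-1], x[1:]
    hits = (left * right <= 0) & (left != 0)
    return np.nonzero(hits)[0] + 1


def _last_before(times: np.ndarray, t: float) -> float | None:
    """Latest element of a sorted array strictly before t, else None."""
    i = np.searchsorted(times, t)
    return float(times[i - 1]) if i > 0 else None


# ---------------------------------------------------------------------------
# Single-foot detectors (reference event lists given)


def detect_heel_contacts(
    a3z_dyn: np.ndarray,
    t: np.ndarray,
    contralateral_to: np.ndarray,
    min_gap: float = 0.2,
) -> np.ndarray:
    """HC times: z-acceleration sign changes gated by the contralateral TO.

    A candidate is kept iff no contralateral TO precedes it, or at least
    ``min_gap`` seconds have elapsed since the most recent one.
    """
    t = np.asarray(t, dtype=float)
    contralateral_to = np.sort(np.asarray(contralateral_to, dtype=float))
    out = []
    for i in zero_crossings(a3z_dyn):
        u = t[i]
        last_to = _last_before(contralateral_to, u)
        if last_to is None or u - last_to >= min_gap:
            out.append(u)
    return np.asarray(out)


def detect_toe_offs(
    r3x: np.ndarray,
    t: np.ndarray,
    ipsilateral_hc: np.ndarray,
    min_stance: float = 0.6,
) -> np.ndarray:
    """TO times: pitch angular-velocity sign changes gated by the own HC.

    A candidate is kept iff it falls at least ``min_stance`` seconds after
    the most recent ipsilateral HC, retaining only the first qualifying
    candidate per HC.
    """
    t = np.asarray(t, dtype=float)
    ipsilateral_hc = np.sort(np.asarray(ipsilateral_hc, dtype=float))
    out = []
    taken_hc: set = set()
    for i in zero_crossings(r3x):
        u = t[i]
        last_hc = _last_before(ipsilateral_hc, u)
        if last_hc is None:
            continue
        if u - last_hc >= min_stance and last_hc not in taken_hc:
            out.append(u)
            taken_hc.add(last_hc)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Joint chronological detection over both feet


def detect_gait_events(
    t: np.ndarray,
    a3z_dyn: dict,
    r3x: dict,
    config: AnalysisConfig | None = None,
    search_start_s: float | None = None,
) -> GaitEventSet:
    """Detect HC and TO for both feet jointly.

    ``a3z_dyn`` and ``r3x`` map side ("L"/"R") to the offset-free filtered
    foot z-acceleration and the filtered foot pitch angular velocity.
    Candidates from both feet are processed in time order so that every
    gating rule refers only to already-accepted events:

    * HC(foot): rejected within ``min_hc_gap_s`` of the most recent
      contralateral TO, and rejected while the foot awaits its TO
      (alternation); the rules are vacuous before the first relevant event.
    * TO(foot): rejected within ``min_stance_s`` of the foot's most recent
      HC; at most one TO is retained per HC.  A foot standing at trial start
      may emit its first TO without a preceding HC.

    ``search_start_s`` (default: the static initialization window) excludes
    the stationary lead-in, where offset-free signals hover at zero.
    """
    config = config or AnalysisConfig()
    if search_start_s is None:
        search_start_s = config.static_window_s
    t = np.asarray(t, dtype=float)
    # lead by two samples so a transition exactly at the window edge (e.g. a
    # liftoff at the end of the static interval) still shows its sign-change pair
    start = max(int(np.searchsorted(t, search_start_s, side="right")) - 2, 0)

    candidates = []  # (time, kind_order, kind, side, index)
    for side in ("L", "R"):
        acc = np.asarray(a3z_dyn[side], dtype=float)[start:]
        gyr = np.asarray(r3x[side], dtype=float)[start:]
        for i in zero_crossings(acc, atol=1e-9 * np.max(np.abs(acc), initial=0.0)):
            candidates.append((t[start + i], 1, "HC", side, start + i))
        for i in zero_crossings(gyr, atol=1e-9 * np.max(np.abs(gyr), initial=0.0)):
            # TO candidates sort before HC at equal timestamps so that a
            # stance completes before the next contact is considered.
            candidates.append((t[start + i], 0, "TO", side, start + i))
    candidates.sort()

    last_hc = {"L": None, "R": None}
    last_to = {"L": None, "R": None}
    events: dict = {s: {"HC": [], "TO": []} for s in ("L", "R")}

    for u, _, kind, side, idx in candidates:
        contra = "R" if side == "L" else "L"
        if kind == "HC":
            if last_hc[side] is not None and (
                last_to[side] is None or last_to[side] < last_hc[side]
            ):
                continue  # alternation: awaiting this foot's TO
            if last_to[contra] is not None and u - last_to[contra] < config.min_hc_gap_s:
                continue
            last_hc[side] = u
            events[side]["HC"].append((u, idx))
        else:  # TO
            if last_to[side] is not None and (
                last_hc[side] is None or last_hc[side] < last_to[side]
            ):
                continue  # one TO per HC
            if last_hc[side] is not None and u - last_hc[side] < config.min_stance_s:
                continue
            last_to[side] = u
            events[side]["TO"].append((u, idx))

    def _foot(side: str) -> FootEvents:
        hc = events[side]["HC"]
        to = events[side]["TO"]
        return FootEvents(
            hc_times=np.array([u for u, _ in hc]),
            to_times=np.array([u for u, _ in to]),
            hc_indices=np.array([i for _, i in hc], dtype=int),
            to_indices=np.array([i for _, i in to], dtype=int),
        )

    return GaitEventSet(left=_foot("L"), right=_foot("R"))


# ---------------------------------------------------------------------------
# Step segmentation


def segment_steps(
    events: GaitEventSet,
    config: AnalysisConfig | None = None,
) -> tuple[list, int]:
    """Pair each HC with its following TO and screen for plausibility.

    Returns ``(steps, n_discarded)``.  A step is discarded when its stance or
    swing duration is below the configured minimum, when its stance fraction
    of the gait cycle falls outside the plausibility band, or when no
    contralateral TO falls inside the stance to anchor the forefoot window.
    Unpaired events at the stream edges are dropped and counted.
    """
    config = config or AnalysisConfig()
    lo, hi = config.stance_fraction_band
    steps: list = []
    n_discarded = 0

    for side in ("L", "R"):
        foot = events.foot(side)
        contra = events.foot("R" if side == "L" else "L")
        hcs = foot.hc_times
        tos = foot.to_times
        for k, hc in enumerate(hcs):
            nxt = tos[np.searchsorted(tos, hc, side="right"):]
            if len(nxt) == 0:
                n_discarded += 1  # trailing HC without TO
                continue
            to = float(nxt[0])
            if k + 1 < len(hcs) and hcs[k + 1] < to:
                n_discarded += 1  # next HC before this stance ended
                continue
            # gait cycle: to the next HC of the same foot, else the
            # preceding cycle as a proxy for the foot's final step
            if k + 1 < len(hcs):
                cycle = float(hcs[k + 1] - hc)
                swing = float(hcs[k + 1] - to)
            elif k > 0:
                cycle = float(hc - hcs[k - 1])
                swing = None
            else:
                n_discarded += 1
                continue
            stance = to - hc
            if stance < config.min_stance_duration_s:
                n_discarded += 1
                continue
            if swing is not None and swing < config.min_swing_duration_s:
                n_discarded += 1
                continue
            if not lo <= stance / cycle <= hi:
                n_discarded += 1
                continue
            in_stance = contra.to_times[
                (contra.to_times > hc) & (contra.to_times < to)
            ]
            if len(in_stance) == 0:
                n_discarded += 1  # cannot anchor the forefoot window
                continue
            steps.append(
                Step(
                    foot=side,
                    hc=float(hc),
                    to=to,
                    forefoot_start=float(in_stance[-1]),
                    forefoot_end=to,
                    cycle_duration=cycle,
                )
            )
    steps.sort(key=lambda s: s.hc)
    return steps, n_discarded


# ---------------------------------------------------------------------------
# Bouts and summary statistics


def detect_bouts(
    steps: list,
    gap_s: float = 1.5,
    min_duration_s: float = 30.0,
) -> list:
    """Group steps into walking bouts.

    Consecutive steps (either foot) whose HCs are no more than ``gap_s``
    apart belong to the same run; runs lasting at least ``min_duration_s``
    (first HC to last TO) are kept as bouts.
    """
    if gap_s <= 0 or min_duration_s <= 0:
        raise ParameterError("gap_s and min_duration_s must be positive")
    if not steps:
        return []
    steps = sorted(steps, key=lambda s: s.hc)
    runs = [[steps[0]]]
    for prev, cur in zip(steps[:-1], steps[1:]):
        if cur.hc - prev.hc > gap_s:
            runs.append([])
        runs[-1].append(cur)
    bouts = []
    for run in runs:
        start = run[0].hc
        end = max(s.to for s in run)
        if end - start >= min_duration_s:
            bouts.append(WalkingBout(start=start, end=end, steps=run))
    return bouts


def gait_cycle_stats(steps: list) -> tuple[float | None, int]:
    """Mean gait-cycle duration (successive same-foot HCs) and step count."""
    cycles = []
    for side in ("L", "R"):
        hcs = sorted(s.hc for s in steps if s.foot == side)
        cycles.extend(np.diff(hcs))
    mean_cycle = float(np.mean(cycles)) if cycles else None
    return mean_cycle, len(steps)
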