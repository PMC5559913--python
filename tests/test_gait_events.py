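"""Event detection rules, step segmentation, bouts and cycle statistics."""

import numpy as np
import pytest

from footload.gait_events import (
    FootEvents,
    GaitEventSet,
    Step,
    detect_bouts,
    detect_heel_contacts,
    detect_toe_offs,
    gait_cycle_stats,
    segment_steps,
    zero_crossings,
)
from footload.io_formats import AnalysisConfig
from footload.pipeline import estimate_trial
from footload.synthetic import GaitSimConfig, simulate_trial

FS = 100.0


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1.0, 0.5, -0.5], [2]),            # plain sign change at i+1
            ([1.0, 1.0, 2.0], []),              # no change
            ([1.0, 0.0, 0.0, -1.0], [1]),       # zeros-run: first zero only
            ([0.0, 0.0, 1.0, -1.0], [3]),       # edge run emits nothing
            ([-1.0, 0.0, -1.0], [1]),           # touch counts once
            ([1.0, -1.0, 1.0], [1, 2]),         # genuine double crossing
        ],
    )
    def test_semantics(self, x, expected):
        assert list(zero_crossings(np.array(x))) == expected

    def test_numerical_floor_suppresses_dust(self):
        x = np.array([0.0, 1e-15, -1e-15, 1.0, -1.0])
        assert list(zero_crossings(x, atol=1e-9)) == [4]


class TestHeelContactRule:
    def test_single_sign_change_passing_constraint(self):
        t = np.arange(3) / FS
        hc = detect_heel_contacts(
            np.array([0.5, 0.2, -0.1]), t, contralateral_to=[t[2] - 0.3], min_gap=0.2
        )
        np.testing.assert_allclose(hc, [t[2]])

    def test_strictly_positive_series_yields_none(self):
        t = np.arange(5) / FS
        assert len(detect_heel_contacts(np.ones(5), t, [], 0.2)) == 0

    def test_candidate_too_close_to_contralateral_to_discarded(self):
        t = np.arange(40) / FS
        x = np.ones(40)
        x[10] = -1.0  # crossings at 0.10 and 0.11 s
        x[25] = -1.0  # crossings at 0.25 and 0.26 s
        hc = detect_heel_contacts(x, t, contralateral_to=[0.0], min_gap=0.2)
        np.testing.assert_allclose(hc, [0.25, 0.26])


class TestToeOffRule:
    def test_accept_after_min_stance(self):
        t = np.arange(80) / FS
        x = np.ones(80)
        x[66:] = -1.0  # sign change at 0.66 s
        to = detect_toe_offs(x, t, ipsilateral_hc=[0.0], min_stance=0.6)
        np.testing.assert_allclose(to, [0.66])

    def test_reject_before_min_stance(self):
        t = np.arange(80) / FS
        x = np.ones(80)
        x[30:] = -1.0
        assert len(detect_toe_offs(x, t, [0.0], 0.6)) == 0

    def test_one_toe_off_per_heel_contact(self):
        t = np.arange(120) / FS
        x = np.ones(120)
        x[66:80] = -1.0   # qualifying crossing at 0.66, return at 0.80
        x[90:95] = -1.0   # later crossings for the same stance
        to = detect_toe_offs(x, t, [0.0], 0.6)
        np.testing.assert_allclose(to, [0.66])


@pytest.mark.parametrize(
    "cadence, stance_fraction", [(0.9, 0.70), (1.1, 0.60), (1.5, 0.55)]
)
def test_joint_detection_recovers_all_events(cadence, stance_fraction, subject):
    """Across cadences, every prescribed HC/TO is found within 2 samples
    with no spurious events (perfect recall and precision, noise-free)."""
    cfg = GaitSimConfig(
        n_steps=16, cadence=cadence, stance_fraction=stance_fraction, seed=3
    )
    trial = simulate_trial(cfg)
    est = estimate_trial(trial.recordings, subject, mode="full")
    for side in ("L", "R"):
        det = est.events.foot(side)
        for truth, found in (
            (trial.events[side]["HC"], det.hc_times),
            (trial.events[side]["TO"], det.to_times),
        ):
            assert len(found) == len(truth)
            for u in truth:
                assert np.min(np.abs(found - u)) <= 2.0 / cfg.fs + 1e-9


def test_event_alternation_invariant(clean_estimate):
    """Per foot, HC and TO strictly alternate in the detected sequence."""
    for side in ("L", "R"):
        foot = clean_estimate.events.foot(side)
        merged = sorted(
            [(t, "HC") for t in foot.hc_times] + [(t, "TO") for t in foot.to_times]
        )
        kinds = [k for _, k in merged]
        for a, b in zip(kinds[:-1], kinds[1:]):
            assert a != b


def test_raising_constraints_never_adds_events(clean_trial, subject):
    """Detection counts are non-increasing in min_gap and min_stance."""
    def count(min_gap, min_stance):
        cfg = AnalysisConfig(min_hc_gap_s=min_gap, min_stance_s=min_stance)
        est = estimate_trial(clean_trial.recordings, subject, cfg, mode="full")
        return sum(
            len(est.events.foot(s).hc_times) + len(est.events.foot(s).to_times)
            for s in ("L", "R")
        )

    base = count(0.2, 0.6)
    assert count(0.3, 0.6) <= base
    assert count(0.2, 0.65) <= base
    assert count(0.3, 0.7) <= base


class TestSegmentSteps:
    @staticmethod
    def _events(hc_l, to_l, hc_r, to_r):
        def foot(hc, to):
            return FootEvents(
                hc_times=np.array(hc, dtype=float),
                to_times=np.array(to, dtype=float),
                hc_indices=np.zeros(len(hc), dtype=int),
                to_indices=np.zeros(len(to), dtype=int),
            )

        return GaitEventSet(left=foot(hc_l, to_l), right=foot(hc_r, to_r))

    def test_alternating_gait_all_retained(self):
        # 1.0 s cycles, 0.6/0.4 stance/swing; windows span contra TO -> own TO
        hc_l = [0.0, 1.0, 2.0]
        to_l = [0.6, 1.6, 2.6]
        hc_r = [0.5, 1.5, 2.5]
        to_r = [0.1, 1.1, 2.1]
        steps, dropped = segment_steps(self._events(hc_l, to_l, hc_r, to_r))
        l_steps = [s for s in steps if s.foot == "L"]
        assert len(l_steps) == 3
        assert l_steps[0].forefoot_window == (0.1, 0.6)

    def test_implausibly_short_stance_rejected(self):
        # L "stance" of 0.1 s inside an ordinary cycle
        steps, dropped = segment_steps(
            self._events([0.0, 1.0], [0.1, 1.6], [0.5], [0.05])
        )
        assert all(s.stance_duration >= 0.4 for s in steps)
        assert dropped >= 1

    def test_windows_match_simulator(self, clean_trial, clean_estimate):
        cfg = clean_trial.config
        det = clean_estimate.steps
        truth = clean_trial.steps
        assert len(det) == len(truth)
        for d, g in zip(det, truth):
            assert d.foot == g.foot
            assert abs(d.forefoot_start - g.forefoot_start) <= 2.0 / cfg.fs + 1e-9
            assert abs(d.forefoot_end - g.forefoot_end) <= 2.0 / cfg.fs + 1e-9


def _step_run(start, n, cycle=1.0):
    steps = []
    for i in range(n):
        hc = start + i * cycle / 2
        steps.append(
            Step(
                foot="L" if i % 2 == 0 else "R",
                hc=hc,
                to=hc + 0.6 * cycle,
                forefoot_start=hc + 0.1 * cycle,
                forefoot_end=hc + 0.6 * cycle,
                cycle_duration=cycle,
            )
        )
    return steps


class TestBouts:
    def test_forty_seconds_is_one_bout(self):
        bouts = detect_bouts(_step_run(0.0, 80))
        assert len(bouts) == 1
        assert bouts[0].n_steps == 80

    def test_twentynine_seconds_is_no_bout(self):
        steps = _step_run(0.0, 57)   # first hc 0.0, last to 28.6 s
        assert detect_bouts(steps) == []

    def test_standstill_splits_runs(self):
        steps = _step_run(0.0, 40) + _step_run(25.0, 72)
        bouts = detect_bouts(steps)
        assert len(bouts) == 1
        assert bouts[0].start == 25.0

    def test_boundary_duration_kept(self):
        steps = _step_run(0.0, 60)  # first hc 0.0, last to 29.5+0.6 = 30.1
        assert len(detect_bouts(steps)) == 1


class TestCycleStats:
    def test_mean_cycle_from_heel_contacts(self):
        steps = [
            Step("L", hc, hc + 0.7, hc + 0.1, hc + 0.7, 1.2)
            for hc in (0.0, 1.2, 2.4)
        ]
        mean_cycle, n = gait_cycle_stats(steps)
        assert mean_cycle == pytest.approx(1.2)
        assert n == 3

    def test_single_step_has_no_cycle(self):
        mean_cycle, n = gait_cycle_stats([Step("L", 0.0, 0.7, 0.1, 0.7, None)])
        assert mean_cycle is None and n == 1

    def test_simulator_cadence_recovered(self, clean_trial, clean_estimate):
        mean_cycle, _ = gait_cycle_stats(clean_estimate.steps)
        assert mean_cycle == pytest.approx(clean_trial.config.cadence, abs=0.01)
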