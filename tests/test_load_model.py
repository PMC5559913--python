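"""Segment masses, GRF estimation (both modes), forefoot-load extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from footload.gait_events import Step
from footload.io_formats import AnalysisConfig, ParameterError
from footload.load_model import (
    GrfSeries,
    estimate_grf_foot_only,
    estimate_grf_full,
    extract_forefoot_load,
    segment_masses,
)

G = 9.8
ALL_SEGMENTS = ("sacrum", "thigh_L", "thigh_R", "shank_L", "shank_R", "foot_L", "foot_R")


def _zero_accels(n=50):
    return {seg: np.zeros(n) for seg in ALL_SEGMENTS}


class TestSegmentMasses:
    @pytest.mark.parametrize(
        "body_mass, foot_exact, foot_reported",
        [(105.0, 1.155, 1.2), (55.0, 0.605, 0.6)],
    )
    def test_foot_mass(self, body_mass, foot_exact, foot_reported):
        masses = segment_masses(body_mass)
        assert masses.m_foot == pytest.approx(foot_exact)
        assert masses.foot_mass_reported() == foot_reported

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=30.0, max_value=200.0))
    def test_mass_closure(self, body_mass):
        masses = segment_masses(body_mass)
        assert masses.body_mass == pytest.approx(body_mass, abs=1e-9)

    def test_invalid_fraction_table_rejected(self):
        with pytest.raises(ParameterError):
            segment_masses(70.0, AnalysisConfig(fraction_thigh=0.5))


class TestGrfEstimation:
    def test_static_closure_full(self):
        masses = segment_masses(61.0)
        grf = estimate_grf_full(np.arange(50) / 100, _zero_accels(), masses)
        np.testing.assert_allclose(grf.newton, 61.0 * G, atol=1e-9)
        np.testing.assert_allclose(grf.kgf, 61.0, atol=1e-9)

    def test_static_closure_foot_only(self):
        masses = segment_masses(61.0)
        grf = estimate_grf_foot_only(
            np.arange(50) / 100, {"foot_L": np.zeros(50), "foot_R": np.zeros(50)},
            masses,
        )
        np.testing.assert_allclose(grf.newton, 61.0 * G, atol=1e-9)

    def test_trunk_acceleration_linearity(self):
        masses = segment_masses(61.0)
        a = _zero_accels()
        a["sacrum"] = np.ones(50)
        grf = estimate_grf_full(np.arange(50) / 100, a, masses)
        np.testing.assert_allclose(
            grf.newton, 61.0 * G + masses.m_upper * 1.0, atol=1e-9
        )

    def test_foot_only_matches_full_when_other_segments_static(self):
        masses = segment_masses(61.0)
        t = np.arange(60) / 100
        a = _zero_accels(60)
        a["foot_L"] = np.sin(t * 10)
        a["foot_R"] = np.cos(t * 10)
        full = estimate_grf_full(t, a, masses)
        feet = estimate_grf_foot_only(
            t, {k: a[k] for k in ("foot_L", "foot_R")}, masses
        )
        np.testing.assert_allclose(full.newton, feet.newton, atol=1e-9)

    def test_unit_coherence(self):
        grf = GrfSeries(np.arange(3.0), np.array([98.0, 49.0, 9.8]), mode="full")
        np.testing.assert_allclose(grf.kgf * G, grf.newton)

    def test_length_mismatch_rejected(self):
        masses = segment_masses(61.0)
        a = _zero_accels()
        a["foot_L"] = np.zeros(10)
        with pytest.raises(ParameterError):
            estimate_grf_full(np.arange(50) / 100, a, masses)

    def test_full_mode_round_trip_under_one_percent(self, clean_trial, clean_estimate):
        """The pipeline's GRF reproduces the prescribed load within 1%."""
        n_star = clean_trial.n_star_newton
        err = np.abs(clean_estimate.grf.newton - n_star)
        assert np.max(err) / np.max(n_star) < 0.01

    def test_foot_only_tracks_foot_dominated_load(self, foot_dominated_trial):
        """When the load variation is routed through the feet, the foot-only
        estimate correlates with the true load at r >= 0.9 per step."""
        trial = foot_dominated_trial
        masses = segment_masses(trial.config.body_mass)
        grf = estimate_grf_foot_only(
            trial.t, {k: trial.a_vert[k] for k in ("foot_L", "foot_R")}, masses
        )
        for step in trial.steps:
            m = (trial.t >= step.forefoot_start) & (trial.t <= step.forefoot_end)
            r = stats.pearsonr(grf.newton[m], trial.n_star_newton[m]).statistic
            assert r >= 0.9


class TestForefootExtraction:
    def _grf(self, n=200, value=61.0):
        t = np.arange(n) / 100
        return GrfSeries(t, np.full(n, value * G), mode="full")

    def test_constant_window(self):
        grf = self._grf()
        step = Step("L", 0.5, 1.19, 0.6, 1.19, 1.1)
        fl = extract_forefoot_load(grf, [step])
        assert len(fl.steps) == 1
        assert len(fl.steps[0].fl_kgf) == 60
        assert fl.steps[0].max_fl == pytest.approx(61.0)

    def test_single_sample_window(self):
        grf = self._grf()
        step = Step("L", 0.5, 1.0, 0.995, 1.0, 1.1)
        fl = extract_forefoot_load(grf, [step])
        assert fl.steps[0].max_fl == pytest.approx(61.0)

    def test_window_outside_series_skipped(self):
        grf = self._grf(n=100)
        step = Step("L", 0.5, 1.6, 0.9, 1.6, 1.1)
        fl = extract_forefoot_load(grf, [step])
        assert len(fl.steps) == 0
        assert fl.n_skipped == 1

    def test_per_step_peak_matches_simulator(self, clean_trial, clean_estimate):
        """Estimated per-step peak forefoot load is within 2% of the truth."""
        est = clean_estimate.fl.max_fl_per_step
        truth = clean_trial.max_fl_per_step
        assert len(est) == len(truth)
        np.testing.assert_allclose(est, truth, rtol=0.02)
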