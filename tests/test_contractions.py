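"""Baseline envelope, event detection, propagation fit and classification."""

import numpy as np
import pytest

from gutmotion import (
    DiameterMatrix,
    DetectionConfig,
    estimate_baseline,
    detect_events,
    fit_propagation,
    classify_event,
    measure_events,
)
from gutmotion.contractions import RawEvent

DT = 6.0 / 7.0  # motility-rate frame interval


def flat_matrix(n_pos=240, n_frames=240, rest=5.0):
    return np.full((n_pos, n_frames), rest)


def add_dip(values, x_mm, t0_frame, t1_frame, depth_frac, sigma=0.8,
            spacing=0.25, velocity_mm_s=0.0, dt=DT):
    pos = (np.arange(values.shape[0]) + 0.5) * spacing
    for f in range(t0_frame, t1_frame):
        centre = x_mm + velocity_mm_s * (f - t0_frame) * dt
        g = np.exp(-0.5 * ((pos - centre) / sigma) ** 2)
        values[:, f] *= 1.0 - depth_frac * g
    return values


def as_dm(values, interval=DT):
    return DiameterMatrix(values, 0.25, interval)


class TestBaseline:
    def test_constant_matrix(self):
        dm = as_dm(flat_matrix())
        base = estimate_baseline(dm)
        assert np.allclose(base, 5.0)

    def test_transient_dip_leaves_envelope_at_rest(self):
        vals = add_dip(flat_matrix(), 30.0, 100, 112, 0.2)
        dm = as_dm(vals)
        base = estimate_baseline(dm)
        row = int(30.0 / 0.25)
        assert np.all(np.abs(base[row] - 5.0) < 0.05)

    def test_envelope_tracks_slow_drift(self):
        n = 2400  # ~34 min so the rolling window actually rolls
        drift = 0.0002 * np.arange(n) * DT
        vals = 5.0 + np.tile(drift, (60, 1))
        dm = as_dm(vals)
        base = estimate_baseline(dm)
        # within one half-window of drift everywhere
        tol = 0.0002 * 900 + 1e-6
        assert np.all(np.abs(base - vals) <= tol)

    def test_window_must_cover_three_frames(self):
        dm = as_dm(flat_matrix(60, 10), interval=1000.0)
        with pytest.raises(ValueError):
            estimate_baseline(dm, DetectionConfig())


class TestDetectEvents:
    def test_single_stationary_dip(self):
        vals = add_dip(flat_matrix(), 30.0, 100, 112, 0.2)
        events = detect_events(as_dm(vals))
        assert len(events) == 1
        ev = events[0]
        assert ev.n_frames == 12
        assert ev.path_mm.max() - ev.path_mm.min() < 1.0
        assert ev.max_depth == pytest.approx(0.2, abs=0.01)

    def test_below_threshold_constrictions_ignored(self):
        vals = add_dip(flat_matrix(), 30.0, 100, 112, 0.05)
        assert detect_events(as_dm(vals)) == []

    def test_two_simultaneous_dips_far_apart(self):
        vals = add_dip(flat_matrix(), 15.0, 100, 112, 0.2)
        vals = add_dip(vals, 35.0, 100, 112, 0.25)
        events = detect_events(as_dm(vals))
        assert len(events) == 2

    def test_short_events_discarded(self):
        vals = add_dip(flat_matrix(), 30.0, 100, 101, 0.2)  # one frame
        assert detect_events(as_dm(vals)) == []

    def test_path_tie_breaks_to_smaller_index(self):
        vals = flat_matrix()
        # two equally deep pixels 0.75 mm apart within one component
        for f in range(100, 110):
            vals[120, f] = 4.0
            vals[121, f] = 4.3
            vals[122, f] = 4.3
            vals[123, f] = 4.0
        events = detect_events(as_dm(vals))
        assert len(events) == 1
        # argmin picks row 120; refinement stays within half a pixel
        assert np.all(np.abs(events[0].path_mm - (120.5 * 0.25)) <= 0.25 / 2 + 1e-9)


class TestFitPropagation:
    def test_exact_positive_line(self):
        frames = np.arange(10)
        ev = RawEvent(frames, 10.0 + 0.2 * frames * 1.0, 0.3)
        slope, r2 = fit_propagation(ev, 1.0)
        assert slope == pytest.approx(0.2)
        assert r2 == pytest.approx(1.0)

    def test_exact_negative_line(self):
        frames = np.arange(6)
        ev = RawEvent(frames, 20.0 - 0.05 * frames, 0.3)
        slope, r2 = fit_propagation(ev, 1.0)
        assert slope == pytest.approx(-0.05)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        path = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 3.0])
        ev = RawEvent(np.arange(6), path, 0.3)
        slope, r2 = fit_propagation(ev, 1.0)
        t = np.arange(6.0)
        X = np.vstack([np.ones(6), t]).T
        beta = np.linalg.solve(X.T @ X, X.T @ path)
        resid = path - X @ beta
        r2_oracle = 1 - (resid @ resid) / ((path - path.mean()) @ (path - path.mean()))
        assert slope == pytest.approx(beta[1], abs=1e-12)
        assert r2 == pytest.approx(r2_oracle, abs=1e-12)

    def test_degenerate_single_time(self):
        ev = RawEvent(np.array([4]), np.array([10.0]), 0.3)
        slope, r2 = fit_propagation(ev, 1.0)
        assert np.isnan(slope) and np.isnan(r2)


class TestClassifyEvent:
    @pytest.mark.parametrize("distance,slope,r2,kind,direction", [
        (0.9, float("nan"), float("nan"), "standing", "none"),
        (1.0, float("nan"), float("nan"), "standing", "none"),
        (3.0, 0.2, 0.95, "ripple", "anterograde"),
        (3.0, -0.01, 0.5, "slow_propulsive", "retrograde"),
        (3.0, -0.3, 0.80, "ripple", "retrograde"),
        (3.0, 0.0, 0.0, "slow_propulsive", "none"),
        (1.1, float("nan"), float("nan"), "standing", "none"),  # degenerate fit
    ])
    def test_rules(self, distance, slope, r2, kind, direction):
        assert classify_event(distance, slope, r2) == (kind, direction)

    def test_partition_property_on_detected_events(self):
        vals = add_dip(flat_matrix(260, 400), 20.0, 30, 42, 0.3)
        vals = add_dip(vals, 45.0, 100, 130, 0.4, velocity_mm_s=0.2)
        dm = as_dm(vals)
        events = measure_events(dm, detect_events(dm))
        assert len(events) == 2
        assert all(e.kind in ("standing", "ripple", "slow_propulsive")
                   for e in events)
        kinds = {e.kind for e in events}
        assert "standing" in kinds and "ripple" in kinds
        rip = next(e for e in events if e.kind == "ripple")
        assert rip.velocity_mm_s == pytest.approx(0.2, rel=0.1)
        assert rip.direction == "anterograde"


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(min_amplitude_frac=0.0),
        dict(min_amplitude_frac=1.5),
        dict(min_duration_s=-1),
        dict(split_prominence_ratio=0.9),
    ])
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            DetectionConfig(**kw)
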