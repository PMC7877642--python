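"""Calibration, determinism and closure of the scenario generator."""

import dataclasses

import numpy as np
import pytest

from gutmotion import (
    DetectionConfig,
    default_params,
    detect_events,
    generate_isolated_events,
    generate_scenario,
    match_events,
    measure_events,
    read_ground_truth,
    write_ground_truth,
)
from gutmotion.synthetic_data import (
    TruncLogNormal,
    _calibrated_trunc_normal_mean,
    _measured_slope_median,
    draw_preparation,
    render_preparation,
)

HOUR = 3600.0


class TestCalibration:
    @pytest.mark.parametrize("triple", [
        (7.7, 47.4, 77.9), (12.7, 55.3, 79.0), (12.4, 56.9, 81.3),
        (1.7, 1.8, 23.4), (1.72, 15.3, 506.6), (0.04, 0.22, 0.67),
    ])
    def test_truncated_median_hits_target_within_1pct(self, triple):
        dist = TruncLogNormal.from_triple(*triple)
        x = dist.rvs(np.random.default_rng(99), 100000)
        assert np.median(x) == pytest.approx(triple[1], rel=0.01)
        assert x.min() >= triple[0] and x.max() <= triple[2]

    def test_ripple_joint_medians(self, cellulose_params):
        joint = cellulose_params.kinds["ripple"].joint
        v, t = joint.rvs(np.random.default_rng(7), 100000)
        assert np.median(v) == pytest.approx(0.22, rel=0.025)
        # the observable-distance floor makes the duration target only
        # approximately attainable (the target pair sits on the constraint
        # boundary); the ~8 % residual disappears in the frame-quantized
        # measured median and stays inside the recovery tolerance
        assert np.median(t) == pytest.approx(7.2, rel=0.10)
        assert np.all(v * np.maximum(t - 6 / 7, 0) >= 1.25 - 1e-9)

    def test_slow_velocity_measured_median(self, cellulose_params):
        kp = cellulose_params.kinds["slow_propulsive"]
        m = _measured_slope_median(kp.velocity, kp.duration_s, n=20000, seed=5)
        assert m == pytest.approx(0.04, rel=0.05)

    def test_evacuation_mean_and_published_range(self, cellulose_params):
        rng = np.random.default_rng(1)
        draws = np.array([cellulose_params.draw_evacuation_s(rng)
                          for _ in range(4000)]) / HOUR
        # cellulose boluses emptied between 0.6 and 2.5 h, mean 1.1 h
        assert draws.min() >= 0.6 and draws.max() <= 2.5
        assert draws.mean() == pytest.approx(1.1, abs=0.05)

    def test_trunc_normal_mean_solver(self):
        mu = _calibrated_trunc_normal_mean(1.1, 0.7, 0.6, 2.5)
        assert mu < 1.1  # the asymmetric range pushes the mean up


class TestDefaults:
    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError):
            default_params("granite")

    def test_published_rates_and_means(self, cellulose_params):
        assert cellulose_params.rate("standing", 1, "I") == 1.5
        assert cellulose_params.rate("slow_propulsive", 1, "I") == 0.26
        assert cellulose_params.rate("ripple", 1, "I") == 0.08
        assert cellulose_params.kinds["slow_propulsive"].anterograde_p == 0.626
        assert default_params("lipid").evacuation_mean_h == 3.4
        assert default_params("protein").evacuation_mean_h == 3.9

    def test_period_II_rates_decline(self, cellulose_params):
        for kind in ("standing", "ripple", "slow_propulsive"):
            for seg in range(1, 5):
                assert (cellulose_params.rate(kind, seg, "II")
                        < cellulose_params.rate(kind, seg, "I"))


class TestDeterminism:
    def test_same_seed_same_matrices(self, cellulose_params):
        a, _ = generate_scenario(cellulose_params, 1, seed=31,
                                 horizon_s=900.0)
        b, _ = generate_scenario(cellulose_params, 1, seed=31,
                                 horizon_s=900.0)
        assert np.array_equal(a[0].values, b[0].values)

    def test_rerendering_a_window_is_stable(self, cellulose_params):
        truth = draw_preparation(cellulose_params, "d",
                                 np.random.SeedSequence(8), horizon_s=1800.0)
        w1 = render_preparation(truth, 7 / 6, 300.0, 900.0)
        w2 = render_preparation(truth, 7 / 6, 300.0, 900.0)
        assert np.array_equal(w1.values, w2.values)


class TestGroundTruthIO:
    def test_round_trip(self, cellulose_params, tmp_path):
        truth = draw_preparation(cellulose_params, "io",
                                 np.random.SeedSequence(9), horizon_s=1200.0)
        path = tmp_path / "gt.tsv"
        write_ground_truth(truth, path)
        df = read_ground_truth(path)
        assert len(df) == len(truth.events)
        for col, attr in [("onset_s", "onset_s"), ("duration_s", "duration_s"),
                          ("position_mm", "position_mm"),
                          ("amplitude_pct", "amplitude_pct")]:
            got = df[col].to_numpy()
            want = np.array([getattr(e, attr) for e in truth.events])
            assert np.allclose(got, want, rtol=1e-9, atol=1e-9)
        assert list(df["kind"]) == [e.kind for e in truth.events]

    def test_zero_event_scenario_writes_header_only(self, cellulose_params,
                                                    tmp_path):
        quiet = dataclasses.replace(
            cellulose_params,
            rates_cpm_mm={k: 0.0 for k in cellulose_params.rates_cpm_mm})
        truth = draw_preparation(quiet, "z", np.random.SeedSequence(2),
                                 horizon_s=900.0)
        assert truth.events == []
        path = tmp_path / "gt.tsv"
        write_ground_truth(truth, path)
        assert len(read_ground_truth(path)) == 0


class TestEventCounts:
    def test_poisson_count_within_3_sigma(self, cellulose_params):
        # slow propulsive counts are plain Poisson draws
        rng_counts = []
        for seed in range(3):
            truth = draw_preparation(cellulose_params, "n",
                                     np.random.SeedSequence([40 + seed]),
                                     horizon_s=2 * HOUR, length_mm=70.0)
            rng_counts.append(sum(1 for e in truth.events
                                  if e.kind == "slow_propulsive"))
        # expected: sum over segments/periods of rate*len*span
        evs = []
        n = np.mean(rng_counts)
        lo_rate = cellulose_params.rate("slow_propulsive", 4, "II")
        assert lo_rate > 0
        # crude expectation bracket: between all-period-II and all-period-I rates
        area = 70.0 * 120.0  # mm * min
        lo = 0.6 * 0.26 * 0.5 * area * 0.5
        hi = 1.1 * 0.26 * area
        assert lo < n < hi


class TestClosure:
    def test_noiseless_recovery_of_kinds_velocity_amplitude(self, cellulose_params):
        cfg = DetectionConfig()
        for kind in ("standing", "ripple", "slow_propulsive"):
            dm, truth = generate_isolated_events(kind, 130, seed=21, noise=False)
            events = measure_events(dm, detect_events(dm, cfg), cfg)
            pairs, recall, precision = match_events(truth.events, events)
            assert recall >= 0.95 and precision >= 0.95
            acc = np.mean([events[j].kind == truth.events[i].kind
                           for i, j in pairs])
            assert acc >= 0.95
            amp_err = [abs(events[j].amplitude_pct - truth.events[i].amplitude_pct)
                       for i, j in pairs]
            assert np.max(amp_err) <= 2.0
            if kind == "ripple":
                vel = [(events[j].velocity_mm_s, truth.events[i].velocity_mm_s)
                       for i, j in pairs if events[j].kind == "ripple"]
                rel = [abs(a - b) / b for a, b in vel]
                assert np.median(rel) <= 0.10
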