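"""Latency estimators: thresholds, loop-area minimisation, cue regression."""

import numpy as np
import pytest

import echokin as ek

from conftest import train_from_ici


class TestIciThreshold:
    def test_step_crossing_recovered(self):
        # 2 ms ICIs, stepping to 6 ms at event + 0.08 s
        pre = np.full(540, 0.002)  # t = 0 .. 1.08
        post = np.full(100, 0.006)
        train = train_from_ici(np.concatenate([pre, post]))
        est = ek.threshold_latency_ici(train, event=1.0, thresh=0.005)
        assert est is not None
        assert est.method == "ici_threshold"
        assert est.value == pytest.approx(0.08, abs=0.003)

    def test_never_crossing_returns_none(self):
        train = train_from_ici(np.full(500, 0.003))
        assert ek.threshold_latency_ici(train, event=0.5) is None

    def test_precrossing_ignored_post_rule_applies(self):
        # ICI > 5 ms throughout: latency is the first post-event click
        train = train_from_ici(np.full(300, 0.008))
        est = ek.threshold_latency_ici(train, event=1.0)
        first_post = train.times[train.times >= 1.0][0]
        assert est.value == pytest.approx(first_post - 1.0)

    def test_event_outside_record_rejected(self):
        train = train_from_ici(np.full(10, 0.005))
        with pytest.raises(ek.ParameterError):
            ek.threshold_latency_ici(train, event=99.0)


class TestJerkThreshold:
    def test_simulator_burst_latency(self):
        cfg = ek.SimConfig(seed=21, response_latency_jerk=0.1, jerk_peak=500.0)
        bundle = ek.simulate_trial(cfg)
        est = ek.threshold_latency_jerk(bundle.body_motion, event=cfg.event_time)
        assert est is not None
        assert est.value == pytest.approx(0.10, abs=0.01)

    def test_quiescent_motion_returns_none(self, null_trial):
        assert ek.threshold_latency_jerk(null_trial.body_motion, event=2.0) is None

    def test_weak_burst_below_threshold_returns_none(self):
        cfg = ek.SimConfig(seed=22, jerk_peak=200.0)
        bundle = ek.simulate_trial(cfg)
        assert ek.threshold_latency_jerk(bundle.body_motion, event=2.0) is None


class TestLoopArea:
    @staticmethod
    def wiggly_pair(delay, g=lambda r: 1.3 * r, fs=200.0, dur=4.0):
        t = np.arange(0.0, dur, 1.0 / fs)
        r = 2.5 + 0.5 * np.sin(2 * np.pi * 0.8 * t)
        dof = g(2.5 + 0.5 * np.sin(2 * np.pi * 0.8 * (t - delay)))
        return t, r, t, dof

    def test_known_delay_recovered(self):
        est = ek.loop_area_latency(*self.wiggly_pair(0.09))
        assert est.method == "loop_area"
        assert est.value == pytest.approx(0.09, abs=1e-12)

    def test_zero_delay_gives_zero(self):
        est = ek.loop_area_latency(*self.wiggly_pair(0.0))
        assert est.value == 0.0

    def test_off_grid_delay_quantised_to_neighbour(self):
        est = ek.loop_area_latency(*self.wiggly_pair(0.092))
        assert est.value in (0.090, 0.095)

    def test_nonlinear_monotone_mapping_ok(self):
        est = ek.loop_area_latency(*self.wiggly_pair(0.06, g=lambda r: r**1.5))
        assert est.value == pytest.approx(0.06, abs=0.005)

    def test_area_at_true_advance_below_zero_advance(self):
        rt, r, dt, dof = self.wiggly_pair(0.1)
        t0 = max(rt[0], dt[0])
        t1 = min(rt[-1], dt[-1] - 0.3)
        tg = np.arange(t0, t1, 1 / 200.0)
        x = np.interp(tg, rt, r)

        def area(a):
            y = np.interp(tg + a, dt, dof)
            return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

        assert area(0.1) < area(0.0)

    def test_time_origin_shift_invariance(self):
        rt, r, dt, dof = self.wiggly_pair(0.05)
        a = ek.loop_area_latency(rt, r, dt, dof)
        b = ek.loop_area_latency(rt + 7.0, r, dt + 7.0, dof)
        assert a.value == b.value

    def test_degenerate_range_rejected(self):
        t = np.arange(0, 4, 0.005)
        with pytest.raises(ek.EstimationError):
            ek.loop_area_latency(t, np.full(t.size, 2.0), t, np.full(t.size, 3.0))


class TestTargetCue:
    def test_static_stream_no_cue(self):
        rng = np.random.default_rng(0)
        accel = rng.normal(0, 0.02, (2, 1500)) + np.array([[0.3], [-0.2]])
        target = ek.TargetMotion(accel=accel, fs=500.0)
        assert ek.rms_target_acceleration(target) is None

    def test_single_axis_sinusoid_rms(self):
        fs, amp = 500.0, 6.0
        t = np.arange(int(3.0 * fs)) / fs
        ax = np.where(t >= 1.5, amp * np.sin(2 * np.pi * 8 * (t - 1.5)), 0.0)
        ax += 1e-4 * np.random.default_rng(1).standard_normal(t.size)
        target = ek.TargetMotion(accel=np.vstack([ax, 1e-4 * np.ones_like(ax)]), fs=fs)
        cue = ek.rms_target_acceleration(target)
        assert cue is not None
        assert cue.onset_time == pytest.approx(1.5, abs=0.01)
        assert cue.rms_accel == pytest.approx(amp / np.sqrt(2), rel=0.02)

    def test_quadrature_pair_rms_equals_amplitude(self):
        fs, amp = 500.0, 4.0
        t = np.arange(int(3.0 * fs)) / fs
        on = t >= 1.5
        ax = np.where(on, amp * np.sin(2 * np.pi * 8 * (t - 1.5)), 0.0)
        ay = np.where(on, amp * np.cos(2 * np.pi * 8 * (t - 1.5)), 0.0)
        noise = 1e-4 * np.random.default_rng(2).standard_normal((2, t.size))
        target = ek.TargetMotion(accel=np.vstack([ax, ay]) + noise, fs=fs)
        cue = ek.rms_target_acceleration(target)
        assert cue.rms_accel == pytest.approx(amp, rel=0.02)

    def test_simulator_pull_produces_cue(self, default_trial):
        cue = ek.rms_target_acceleration(default_trial.target_motion)
        assert cue is not None
        assert cue.onset_time == pytest.approx(2.0, abs=0.01)
        assert cue.rms_accel > 1.0


class TestInverseLatencyRegression:
    def test_exact_linear_relation(self):
        x = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
        tau = 1.0 / (2 * x + 1)
        slope, intercept, r2, p = ek.inverse_latency_regression(tau, x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 0.01

    def test_constant_latency_flat(self):
        tau = np.full(6, 0.1)
        cues = np.arange(6, dtype=float)
        slope, _, r2, p = ek.inverse_latency_regression(tau, cues)
        assert slope == 0.0
        assert r2 == 0.0
        assert p == 1.0

    def test_too_few_pairs(self):
        with pytest.raises(ek.InsufficientDataError):
            ek.inverse_latency_regression([0.1, 0.2], [1.0, 2.0])

    def test_noisy_cohort_slope_positive(self):
        """Cue-dependent latencies with noise: slope sign is stable."""
        rng = np.random.default_rng(3)
        signs = []
        for _ in range(40):
            cues = rng.uniform(1.0, 8.0, 20)
            tau = 1.0 / (2.0 + 1.5 * cues) * np.exp(0.15 * rng.standard_normal(20))
            slope, *_ = ek.inverse_latency_regression(tau, cues)
            signs.append(slope > 0)
        assert np.mean(signs) >= 0.95


class TestThresholdLatencyVsCue:
    def test_latency_nonincreasing_in_cue(self):
        """Faster target movements give faster strong ICI responses."""
        lats = []
        for pull, lat in [(4.0, 0.16), (10.0, 0.10), (22.0, 0.05)]:
            cfg = ek.SimConfig(
                seed=31, response_latency=lat, saccade_enabled=True,
                target_pull_accel=pull,
            )
            times, _ = ek.simulate_click_train(cfg)
            est = ek.threshold_latency_ici(
                ek.ClickTrain(times=times), event=cfg.event_time
            )
            assert est is not None
            lats.append(est.value)
        assert lats[0] >= lats[1] >= lats[2]
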