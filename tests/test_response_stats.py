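"""Event-locked statistics, bootstrap behaviour, and analytic helpers."""

import numpy as np
import pytest

import echokin as ek
from echokin.click_buzz import ClickTrain

from conftest import train_from_ici


def jittered_train(rng, n=600, base=0.004, jitter=1e-4):
    """Exchangeable-noise train: iid jitter about a constant ICI."""
    ici = base + jitter * rng.standard_normal(n)
    return train_from_ici(np.clip(ici, base / 2, None))


class TestDeltaIciProportions:
    def test_accelerating_train_all_zero(self):
        # ICI monotonically decreasing -> every deltaICI negative
        ici = np.linspace(0.012, 0.002, 400)
        train = train_from_ici(ici)
        props = ek.delta_ici_proportions(train, event=1.2, bin_width=0.05)
        filled = props[~np.isnan(props)]
        assert filled.size > 10
        assert np.all(filled == 0.0)

    def test_decelerating_train_all_one(self):
        ici = np.linspace(0.002, 0.012, 400)
        train = train_from_ici(ici)
        props = ek.delta_ici_proportions(train, event=1.2, bin_width=0.05)
        filled = props[~np.isnan(props)]
        assert np.all(filled == 1.0)

    def test_exchangeable_jitter_near_half(self):
        rng = np.random.default_rng(0)
        props = []
        for _ in range(40):
            train = jittered_train(rng)
            p = ek.delta_ici_proportions(train, event=1.2, bin_width=0.05)
            props.append(p)
        mean = np.nanmean(np.vstack(props))
        # ~40 trials x 20 bins x ~12 intervals: binomial SE ~ 0.006
        assert mean == pytest.approx(0.5, abs=0.02)

    def test_bin_accounting(self):
        """Per bin, positives + non-positives equal the deltaICI count."""
        rng = np.random.default_rng(1)
        train = jittered_train(rng)
        edges = ek.event_bins(0.05)
        props = ek.delta_ici_proportions(train, event=1.2, bin_width=0.05)
        dici = np.diff(train.ici)
        t_d = train.times[1:-1] - 1.2
        for b in range(edges.size - 1):
            sel = dici[(t_d >= edges[b]) & (t_d < edges[b + 1])]
            if sel.size == 0:
                assert np.isnan(props[b])
            else:
                pos = np.count_nonzero(sel > 0)
                assert props[b] == pytest.approx(pos / sel.size)

    def test_no_overlap_is_error(self):
        train = train_from_ici([0.005] * 10)
        with pytest.raises(ek.InsufficientDataError):
            ek.delta_ici_proportions(train, event=50.0, bin_width=0.05)


class TestJerk:
    def test_constant_acceleration_zero_jerk(self):
        motion = ek.SensorStream(accel=np.ones((3, 400)) * 2.5, fs=200.0)
        bins = ek.jerk_rms_bins(motion, event=1.0, bin_width=0.05)
        assert np.nanmax(bins) == 0.0

    def test_single_axis_ramp_gives_slope(self):
        fs, s = 200.0, 120.0  # ramp slope in m/s^3
        t = np.arange(800) / fs
        accel = np.vstack([s * t, np.zeros_like(t), np.zeros_like(t)])
        motion = ek.SensorStream(accel=accel, fs=fs)
        bins = ek.jerk_rms_bins(motion, event=2.0, bin_width=0.05)
        np.testing.assert_allclose(bins[~np.isnan(bins)], s, rtol=1e-9)

    def test_simulator_burst_lands_in_expected_bin(self):
        cfg = ek.SimConfig(seed=12, response_latency_jerk=0.08, jerk_peak=500.0)
        bundle = ek.simulate_trial(cfg)
        bins = ek.jerk_rms_bins(bundle.body_motion, cfg.event_time, 0.05)
        edges = ek.event_bins(0.05)
        first = np.argmax(np.nan_to_num(bins) > 300.0)
        assert edges[first] == pytest.approx(0.05)
        assert edges[first + 1] == pytest.approx(0.10)

    def test_jerk_subadditive_and_collinear_equality(self):
        rng = np.random.default_rng(2)
        a1 = rng.standard_normal((3, 300))
        a2 = rng.standard_normal((3, 300))
        fs = 200.0
        _, j1 = ek.norm_jerk(ek.SensorStream(accel=a1, fs=fs))
        _, j2 = ek.norm_jerk(ek.SensorStream(accel=a2, fs=fs))
        _, j12 = ek.norm_jerk(ek.SensorStream(accel=a1 + a2, fs=fs))
        assert np.all(j12 <= j1 + j2 + 1e-9)
        _, jc = ek.norm_jerk(ek.SensorStream(accel=3 * a1, fs=fs))
        np.testing.assert_allclose(jc, 3 * j1, rtol=1e-9)


class TestBootstrap:
    @staticmethod
    def cohort(rng, n=12, null=True, latency=0.075):
        trials = []
        for _ in range(n):
            ev = float(rng.uniform(1.0, 2.0))
            cfg = ek.SimConfig(
                seed=int(rng.integers(2**31)),
                event_time=ev,
                response_latency=latency,
                saccade_enabled=not null,
            )
            times, _ = ek.simulate_click_train(cfg, null=null)
            trials.append((ClickTrain(times=times), ev))
        return trials

    def test_parameter_errors(self):
        rng = np.random.default_rng(3)
        trials = self.cohort(rng, n=2)
        with pytest.raises(ek.ParameterError):
            ek.bootstrap_null(trials, bin_width=0.05, n_rep=0)
        with pytest.raises(ek.ParameterError):
            ek.bootstrap_null(trials[:1], bin_width=0.05, n_rep=10)

    def test_self_transplant_reproduces_observed(self):
        """Replicates built from each trial's own event offset equal the
        observed statistic (bootstrap self-consistency)."""
        rng = np.random.default_rng(4)
        trials = self.cohort(rng, n=6)
        resp = ek.binned_response(trials, bin_width=0.05)
        observed = np.nanmedian(resp.values, axis=0)
        starts = [t.times[0] for t, _ in trials]
        redone = np.vstack(
            [
                ek.delta_ici_proportions(t, s + (ev - s), 0.05)
                for (t, ev), s in zip(trials, starts)
            ]
        )
        np.testing.assert_allclose(np.nanmedian(redone, axis=0), observed)

    def test_strong_response_detected_null_not(self):
        rng = np.random.default_rng(5)
        null_res = ek.bootstrap_null(
            self.cohort(rng, n=12, null=True), bin_width=0.05, n_rep=100, rng_seed=1
        )
        strong_res = ek.bootstrap_null(
            self.cohort(rng, n=12, null=False), bin_width=0.05, n_rep=100, rng_seed=1
        )
        post = null_res.bin_edges[:-1] >= 0.05
        assert strong_res.significant[post].sum() >= 2
        assert null_res.significant.sum() <= 2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        trials = self.cohort(rng, n=6)
        a = ek.bootstrap_null(trials, bin_width=0.05, n_rep=50, rng_seed=9)
        b = ek.bootstrap_null(trials, bin_width=0.05, n_rep=50, rng_seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        np.testing.assert_array_equal(a.significant, b.significant)


class TestAnalyticHelpers:
    def test_depth_of_field_identity(self):
        assert ek.ici_to_dof(0.005, 1500.0) == pytest.approx(3.75)
        assert ek.ici_to_dof(0.0, 1500.0) == 0.0
        x = 0.0037
        assert ek.dof_to_ici(ek.ici_to_dof(x)) == pytest.approx(x)

    def test_bandwidth_ratio(self):
        assert ek.bandwidth_ratio(0.0025, 0.05) == pytest.approx(40.0)
        assert ek.bandwidth_ratio(0.004, 0.002) == pytest.approx(1.0)
        assert ek.bandwidth_ratio(0.0035, 0.175) == pytest.approx(100.0)

    def test_clicks_per_latency(self):
        assert ek.clicks_per_latency(0.05, 0.0025) == 20
        assert ek.clicks_per_latency(0.0, 0.0025) == 0
        assert ek.clicks_per_latency(0.2, 0.0035) == 57

    @pytest.mark.parametrize(
        "fn,args",
        [
            (ek.ici_to_dof, (-0.001,)),
            (ek.dof_to_ici, (-1.0,)),
            (ek.bandwidth_ratio, (0.0, 0.05)),
            (ek.bandwidth_ratio, (0.002, 0.0)),
            (ek.clicks_per_latency, (0.05, 0.0)),
        ],
    )
    def test_domain_errors(self, fn, args):
        with pytest.raises(ek.ParameterError):
            fn(*args)
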