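"""APD measurement, pacing driver and calcium metrics."""

import numpy as np
import pytest

from cardioinflam import (APTrace, PacingProtocol, apd, calcium_metrics,
                          default_parameters, delta_apd, pace)


def square_pulse_trace(rest=-85.0, plateau=15.0, up_ms=50.0, down_ms=250.0,
                       total=900.0, dt=0.1):
    t = np.arange(0.0, total, dt)
    vm = np.full_like(t, rest)
    vm[(t >= up_ms) & (t < down_ms)] = plateau
    return APTrace(time=t, vm=vm, ca_i=np.full_like(t, 1e-4),
                   ca_sr=np.full_like(t, 1.3), period=total,
                   beat_starts=np.array([0.0]))


def smooth_ap(t, rest, amp, apd_ms, t_up):
    """Synthetic smooth action potential with a tanh repolarization ramp."""
    up = 0.5 * (1 + np.tanh((t - t_up) / 0.4))
    down = 0.5 * (1 - np.tanh((t - t_up - apd_ms) / 8.0))
    return rest + amp * up * down


class TestAPD:
    def test_square_pulse_apd_equals_plateau_duration(self):
        tr = square_pulse_trace()
        m = apd(tr)
        assert m.apd90 == pytest.approx(200.0, abs=0.2)
        assert m.resting_vm == pytest.approx(-85.0)
        assert m.peak_vm == pytest.approx(15.0)

    def test_square_geometry_invariant_to_fraction(self):
        tr = square_pulse_trace()
        assert apd(tr, fraction=0.5).apd90 == pytest.approx(200.0, abs=0.2)

    def test_matches_dense_resampling_oracle_on_smooth_aps(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rest = -90 + 5 * rng.random()
            amp = 100 + 30 * rng.random()
            apd_true = 150 + 250 * rng.random()
            t_up = 5 + 10 * rng.random()
            t = np.arange(0.0, 900.0, 0.1)
            vm = smooth_ap(t, rest, amp, apd_true, t_up)
            tr = APTrace(time=t, vm=vm, ca_i=np.ones_like(t) * 1e-4,
                         ca_sr=np.ones_like(t), period=900.0,
                         beat_starts=np.array([0.0]))
            m = apd(tr)
            # oracle: brute-force scan on a 100x denser resampling
            td = np.arange(0.0, 900.0, 0.001)
            vd = smooth_ap(td, rest, amp, apd_true, t_up)
            i_up = np.argmax(np.diff(vd))
            thr = vd[0] + 0.1 * (vd.max() - vd[0])
            after_peak = np.argmax(vd)
            below = np.nonzero(vd[after_peak:] < thr)[0]
            oracle = td[after_peak + below[0]] - td[i_up]
            assert m.apd90 == pytest.approx(oracle, abs=0.2)

    def test_time_shift_and_sampling_invariance(self):
        t = np.arange(0.0, 900.0, 0.05)
        vm = smooth_ap(t, -86.0, 120.0, 300.0, 10.0)
        tr_fine = APTrace(time=t, vm=vm, ca_i=np.ones_like(t), ca_sr=np.ones_like(t),
                          period=900.0, beat_starts=np.array([0.0]))
        tr_coarse = APTrace(time=t[::2], vm=vm[::2], ca_i=np.ones_like(t[::2]),
                            ca_sr=np.ones_like(t[::2]), period=900.0,
                            beat_starts=np.array([0.0]))
        shift = 37.0
        tr_shift = APTrace(time=t + shift, vm=vm, ca_i=np.ones_like(t),
                           ca_sr=np.ones_like(t), period=900.0,
                           beat_starts=np.array([shift]))
        a = apd(tr_fine).apd90
        assert apd(tr_coarse).apd90 == pytest.approx(a, abs=0.2)
        assert apd(tr_shift).apd90 == pytest.approx(a, abs=0.1)

    def test_repolarization_failure_flagged(self):
        t = np.arange(0.0, 400.0, 0.1)
        vm = np.where(t < 10, -85.0, 10.0)  # never repolarizes
        tr = APTrace(time=t, vm=vm, ca_i=np.ones_like(t), ca_sr=np.ones_like(t),
                     period=400.0, beat_starts=np.array([0.0]))
        m = apd(tr)
        assert m.repolarization_failure
        assert np.isnan(m.apd90)


class TestPace:
    def test_single_beat_window(self):
        tr = pace(default_parameters("EPI"), PacingProtocol(count=1), n_keep=1)
        assert len(tr.beat_starts) == 1
        assert tr.time[-1] - tr.time[0] <= 1000.0

    def test_steady_state_criterion_reported(self):
        tr = pace(default_parameters("EPI"), PacingProtocol(count=200))
        assert tr.steady_state
        assert tr.apd_delta_last < 1.0

    def test_rate_adaptation_shortens_apd(self):
        p = default_parameters("EPI")
        slow = apd(pace(p, PacingProtocol(period=1000.0, count=200))).apd90
        fast = apd(pace(p, PacingProtocol(period=500.0, count=200))).apd90
        assert fast < slow

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(count=0)
        with pytest.raises(ValueError):
            PacingProtocol(duration=1200.0, period=1000.0)


class TestDeltaAPD:
    def test_definitions_coincide_for_equal_flanks(self):
        d = delta_apd(297.0, 200.0, 200.0)
        assert d.mid_minus_mean == pytest.approx(97.0)
        assert d.mid_minus_max == pytest.approx(97.0)

    def test_mean_vs_max_definitions(self):
        d = delta_apd(300.0, 190.0, 210.0)
        assert d.mid_minus_mean == pytest.approx(100.0)
        assert d.mid_minus_max == pytest.approx(90.0)
        assert d.value("mean") == d.mid_minus_mean
        with pytest.raises(ValueError):
            d.value("median")

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            delta_apd(0.0, 200.0, 200.0)


class TestCalciumMetrics:
    def test_equals_brute_force_min_max(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 1000.0, 0.1)
        ca = 1e-4 + 1e-3 * np.abs(np.sin(t / 100.0)) + 1e-5 * rng.random(len(t))
        sr = 3.0 + np.cos(t / 200.0)
        tr = APTrace(time=t, vm=np.full_like(t, -85.0), ca_i=ca, ca_sr=sr,
                     period=1000.0, beat_starts=np.array([0.0]))
        m = calcium_metrics(tr)
        assert m["diastolic_ca_i"] == pytest.approx(ca.min())
        assert m["systolic_ca_i"] == pytest.approx(ca.max())
        assert m["ca_sr_content"] == pytest.approx(sr.min())

    def test_constant_trace_has_equal_systole_and_diastole(self):
        t = np.arange(0.0, 100.0, 0.1)
        tr = APTrace(time=t, vm=np.full_like(t, -85.0),
                     ca_i=np.full_like(t, 2e-4), ca_sr=np.full_like(t, 3.0),
                     period=100.0, beat_starts=np.array([0.0]))
        m = calcium_metrics(tr)
        assert m["diastolic_ca_i"] == m["systolic_ca_i"]

    def test_inflammation_calcium_sign_pattern(self):
        from cardioinflam.inflammation import (apply_perturbation,
                                               severity_preset)
        protocol = PacingProtocol(count=200)
        base = calcium_metrics(pace(default_parameters("EPI"), protocol))
        inflamed_params = apply_perturbation(default_parameters("EPI"),
                                             severity_preset(1.0))
        infl = calcium_metrics(pace(inflamed_params, protocol))
        assert infl["systolic_ca_i"] < base["systolic_ca_i"]
        assert infl["diastolic_ca_i"] > base["diastolic_ca_i"]
        assert infl["ca_sr_content"] < base["ca_sr_content"]
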