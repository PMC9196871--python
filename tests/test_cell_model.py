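"""Ionic-model unit and property tests: fixed points, gates, convergence."""

import numpy as np
import pytest

from cardioinflam import (CellState, PacingProtocol, SolverInstabilityError,
                          Variant, default_parameters, derivatives, pace,
                          resting_state, step)
from cardioinflam.cell_model import perturbed, resting_drift


class TestDefaults:
    def test_variant_round_trip_and_zero_shifts(self):
        for v in ("ENDO", "MID", "EPI"):
            p = default_parameters(v)
            assert p.variant == Variant(v)
            assert p.shift_ikr_act == 0.0
            assert p.shift_ito_inact == 0.0

    def test_transmural_conductance_scheme(self):
        # MID: reduced slow delayed rectifier; ENDO: reduced transient outward
        mid, epi, endo = (default_parameters(v) for v in ("MID", "EPI", "ENDO"))
        assert mid.g_ks < epi.g_ks
        assert mid.g_ks < endo.g_ks
        assert endo.g_to < epi.g_to
        assert mid.g_to == epi.g_to

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            default_parameters("APEX")

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            perturbed(default_parameters("EPI"), g_kr=-0.1)


class TestDerivatives:
    def test_rest_is_a_fixed_point(self):
        params = default_parameters("EPI")
        rest = resting_state(params)
        d, cur = derivatives(rest, params)
        assert abs(d.vm) < 0.01

    def test_current_sum_identity(self):
        params = default_parameters("MID")
        _, cur = derivatives(CellState(), params)
        total = (cur.i_na + cur.i_cal + cur.i_to + cur.i_kr + cur.i_ks
                 + cur.i_k1 + cur.i_naca + cur.i_nak + cur.i_pca + cur.i_pk
                 + cur.i_bna + cur.i_bca)
        assert cur.i_ion == pytest.approx(total)

    def test_zero_uptake_rate_gives_zero_jup(self):
        params = perturbed(default_parameters("EPI"), v_max_up=0.0)
        _, cur = derivatives(CellState(), params)
        assert cur.j_up == 0.0

    def test_leak_linear_in_rate_constant(self):
        params = default_parameters("EPI")
        doubled = perturbed(params, v_leak=2 * params.v_leak)
        state = CellState(ca_sr=2.0, ca_i=0.0002)
        _, c1 = derivatives(state, params)
        _, c2 = derivatives(state, doubled)
        assert c2.j_leak == pytest.approx(2 * c1.j_leak, rel=1e-12)

    def test_nonfinite_state_rejected(self):
        params = default_parameters("EPI")
        bad = CellState(vm=float("nan"))
        with pytest.raises(SolverInstabilityError):
            derivatives(bad, params)


class TestStep:
    def test_rest_step_is_identity(self):
        params = default_parameters("EPI")
        rest = resting_state(params)
        out = step(rest, params, dt=0.02)
        assert abs(out.vm - rest.vm) < 1e-3

    def test_stimulus_elicits_upstroke(self):
        # an 80 pA/pF, 0.5 ms pulse from rest crosses 0 mV
        params = default_parameters("EPI")
        s = resting_state(params)
        vmax = s.vm
        for i in range(int(5.0 / 0.02)):
            t = i * 0.02
            s = step(s, params, dt=0.02, i_stim=80.0 if t < 0.5 else 0.0)
            vmax = max(vmax, s.vm)
        assert vmax > 0.0

    def test_two_half_steps_match_one_step(self):
        params = default_parameters("EPI")
        s = resting_state(params)
        a = step(step(s, params, dt=0.01, i_stim=80.0), params, dt=0.01,
                 i_stim=80.0)
        b = step(s, params, dt=0.02, i_stim=80.0)
        assert abs(a.vm - b.vm) < 0.05  # O(dt) local agreement

    def test_instability_error_names_variable(self):
        params = default_parameters("EPI")
        with pytest.raises(SolverInstabilityError, match="vm|non-finite"):
            step(CellState(vm=float("inf")), params)


class TestLongRunStability:
    def test_resting_drift_below_1mV_over_60s(self):
        assert resting_drift(default_parameters("EPI")) < 1.0

    def test_gates_bounded_and_concentrations_positive_under_pacing(self):
        # 10 s of 1 Hz pacing keeps the state in its admissible box
        tr = pace(default_parameters("MID"), PacingProtocol(count=10))
        tr.final_state.validate()
        assert np.all(tr.ca_i > 0)
        assert np.all(tr.ca_sr > 0)

    def test_step_halving_changes_steady_apd_below_1ms(self):
        from cardioinflam import apd
        protocol = PacingProtocol(count=200)
        params = default_parameters("EPI")
        a = apd(pace(params, protocol, dt=0.02)).apd90
        b = apd(pace(params, protocol, dt=0.01)).apd90
        assert abs(a - b) < 1.0

    def test_trace_vm_agreement_under_step_halving(self):
        # a small dt-dependent phase shift of the stimulus-locked upstroke
        # produces large pointwise differences on the steep flank, so the
        # first 5 ms of each beat are excluded from the comparison
        protocol = PacingProtocol(count=2)
        params = default_parameters("EPI")
        a = pace(params, protocol, dt=0.02)
        b = pace(params, protocol, dt=0.01)
        off_upstroke = (a.time % protocol.period) > 5.0
        assert np.max(np.abs(a.vm - b.vm)[off_upstroke]) < 1.0


class TestSerialization:
    def test_parameter_config_round_trip(self):
        p = default_parameters("MID")
        q = type(p).from_config(p.to_config())
        assert p == q

    def test_state_csv_header_names_every_variable(self, tmp_path):
        import csv
        path = tmp_path / "state.csv"
        with open(path, "w", newline="") as fp:
            CellState.write_csv([CellState()], fp)
        with open(path) as fp:
            header = next(csv.reader(fp))
        assert len(header) == len(CellState().to_array())
        assert "vm" in header and "ca_sr" in header
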