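"""Strand geometry, monodomain propagation, CV and the vulnerable window."""

import numpy as np
import pytest

from cardioinflam import (S2Class, SpaceTimeRecording, Stimulus, Variant,
                          build_strand, classify_s2, measure_cv, measure_vw,
                          s1_train, solve_strand)
from cardioinflam.tissue_1d import (VWScan, s1_snapshot, s1_trajectory,
                                    s2_response, variant_layout)


class TestGeometry:
    def test_default_layout_proportions_and_length(self):
        g = build_strand()
        assert g.n_nodes == 100
        assert g.length_mm == pytest.approx(15.0)
        counts = {v: g.variants.count(v) for v in Variant}
        assert counts[Variant.ENDO] == 25
        assert counts[Variant.MID] == 35
        assert counts[Variant.EPI] == 40
        assert g.variants[0] == Variant.ENDO

    def test_layout_rounding_off_default_size(self):
        layout = variant_layout(61)
        counts = {v: layout.count(v) for v in Variant}
        assert abs(counts[Variant.ENDO] - 0.25 * 61) <= 1
        assert abs(counts[Variant.MID] - 0.35 * 61) <= 1

    def test_inflamed_coupling_override(self):
        g = build_strand(severity=1.0)
        assert np.allclose(g.D, 0.1)
        mild = build_strand(severity=0.5)
        assert np.all(mild.D < 0.154) and np.all(mild.D > 0.1)

    def test_control_strand_is_unperturbed(self):
        g = build_strand()
        assert np.allclose(g.D, 0.154)
        assert not g.inflamed.any()


class TestSolveStrand:
    def test_no_stimulus_stays_at_rest(self):
        g = build_strand()
        rec = solve_strand(g, [], duration=100.0)
        assert np.max(np.abs(rec.vm - rec.vm[0])) < 1.0

    def test_uniform_resting_strand_has_no_diffusive_drift(self):
        # on a spatially uniform (all-EPI) resting strand the conservative
        # flux form must contribute nothing: every node drifts exactly like
        # an isolated cell
        g = build_strand(proportions=(0.0, 0.0, 1.0))
        rec = solve_strand(g, [], duration=100.0)
        per_node = rec.vm[-1] - rec.vm[0]
        assert np.ptp(per_node) < 1e-9
        single = build_strand(n_nodes=1, proportions=(0.0, 0.0, 1.0))
        ref = solve_strand(single, [], duration=100.0)
        reaction = ref.vm[-1, 0] - ref.vm[0, 0]
        assert np.sum(np.abs(per_node - reaction)) < 0.1

    def test_stimulus_outside_duration_rejected(self):
        g = build_strand()
        with pytest.raises(ValueError):
            solve_strand(g, [Stimulus(start=500.0)], duration=100.0)

    def test_plane_wave_activation_times_monotone(self, control_recording):
        at = control_recording.activation_times()
        assert np.all(np.isfinite(at))
        assert np.all(np.diff(at[3:]) > 0)


class TestCV:
    def test_synthetic_recording_known_velocity(self):
        # activation at t = x / v with v = 0.5 m/s
        dx = 0.15
        n = 100
        t = np.arange(0.0, 80.0, 0.5)
        at = np.arange(n) * dx / 0.5
        vm = np.where(t[:, None] >= at[None, :], 20.0, -85.0)
        rec = SpaceTimeRecording(time=t, vm=vm, dx=dx)
        assert measure_cv(rec) == pytest.approx(0.5, rel=0.01)

    def test_default_strand_cv(self, control_recording):
        assert measure_cv(control_recording) == pytest.approx(0.74, abs=0.05)

    def test_reduced_coupling_cv(self):
        g = build_strand(severity=1.0)  # D = 0.1 mm^2/ms everywhere
        rec = solve_strand(g, s1_train(1), duration=120.0)
        assert measure_cv(rec) == pytest.approx(0.6, abs=0.05)

    def test_cv_scales_with_sqrt_of_diffusion(self):
        g = build_strand()
        ref = measure_cv(solve_strand(g, s1_train(1), duration=120.0))
        half = build_strand(D=0.154 / 2)
        cv_half = measure_cv(solve_strand(half, s1_train(1), duration=160.0))
        assert cv_half == pytest.approx(ref / np.sqrt(2), rel=0.10)

    def test_boundary_nodes_rejected(self, control_recording):
        with pytest.raises(ValueError):
            measure_cv(control_recording, node_a=2, node_b=80)


def synthetic_s2_recording(left_conducts, right_conducts, site=50, s2=300.0):
    """Step-activation recording with prescribed S2 outcomes."""
    n = 100
    dx = 0.15
    t = np.arange(0.0, s2 + 120.0, 0.5)
    vm = np.full((len(t), n), -85.0)
    # S1 plane wave
    for i in range(n):
        vm[t >= i * dx / 0.7, i] = 20.0
    # repolarize well before S2
    vm[(t[:, None] >= 250.0) & np.ones((1, n), bool)] = -85.0
    for i in range(n):
        arrival = None
        if site - 1 <= i <= site + 1:
            arrival = s2 + 1.0
        elif i < site - 1 and left_conducts:
            arrival = s2 + 1.0 + (site - i) * dx / 0.7
        elif i > site + 1 and right_conducts:
            arrival = s2 + 1.0 + (i - site) * dx / 0.7
        if arrival is not None:
            vm[t >= arrival, i] = 20.0
    return SpaceTimeRecording(time=t, vm=vm, dx=dx)


class TestClassifyS2:
    @pytest.mark.parametrize("left,right,expected", [
        (True, True, S2Class.BIDIRECTIONAL),
        (True, False, S2Class.UNIDIRECTIONAL_BLOCK),
        (False, True, S2Class.UNIDIRECTIONAL_BLOCK),
        (False, False, S2Class.BIDIRECTIONAL_BLOCK),
    ])
    def test_synthetic_patterns(self, left, right, expected):
        rec = synthetic_s2_recording(left, right)
        assert classify_s2(rec, 50, 300.0) == expected

    def test_matches_node_scan_oracle_on_random_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            left, right = bool(rng.integers(2)), bool(rng.integers(2))
            site = int(rng.integers(20, 80))
            rec = synthetic_s2_recording(left, right, site=site)
            got = classify_s2(rec, site, 300.0)
            # oracle: explicit upward-crossing scan at the probe nodes
            sides = []
            for node in (site - 10, site + 10):
                sel = (rec.time >= 300.0) & (rec.time < 400.0)
                v = rec.vm[sel, node]
                sides.append(bool(np.any((v[1:] >= -20) & (v[:-1] < -20))))
            expected = {2: S2Class.BIDIRECTIONAL,
                        1: S2Class.UNIDIRECTIONAL_BLOCK,
                        0: S2Class.BIDIRECTIONAL_BLOCK}[sum(sides)]
            assert got == expected

    def test_boundary_site_rejected(self):
        rec = synthetic_s2_recording(True, True)
        with pytest.raises(ValueError):
            classify_s2(rec, 5, 300.0)


class TestVulnerableWindow:
    def test_refractory_and_recovered_limits(self, control_strand):
        base = s1_snapshot(control_strand)
        traj = s1_trajectory(control_strand, base, Stimulus(0.0), 900.0)
        early = s2_response(control_strand, 70, 150.0, trajectory=traj)
        late = s2_response(control_strand, 70, 850.0, trajectory=traj)
        assert early == S2Class.BIDIRECTIONAL_BLOCK
        assert late == S2Class.BIDIRECTIONAL

    def test_edges_match_dense_quarter_ms_scan(self, control_strand):
        base = s1_snapshot(control_strand)
        traj = s1_trajectory(control_strand, base, Stimulus(0.0), 650.0)
        res = measure_vw(control_strand, 70, trajectory=traj)
        assert res.found
        grid = np.round(np.arange(res.open - 3.0, res.close + 3.0 + 1e-9, 0.25), 6)
        dense = [s2_response(control_strand, 70, float(c), trajectory=traj)
                 for c in grid]
        uni = [i for i, k in enumerate(dense)
               if k == S2Class.UNIDIRECTIONAL_BLOCK]
        assert grid[uni[0]] == pytest.approx(res.open, abs=0.25)
        assert grid[uni[-1]] == pytest.approx(res.close, abs=0.25)

    def test_no_window_when_scanning_recovered_tissue(self, control_strand):
        base = s1_snapshot(control_strand)
        scan = VWScan(dt_min=800.0, dt_max=900.0)
        res = measure_vw(control_strand, 70, scan=scan, base_state=base)
        assert res.width == 0.0
        assert np.isnan(res.open) and np.isnan(res.close)

    def test_widths_nonnegative_and_ordered_by_severity(self, vw_results):
        for res in vw_results.values():
            assert all(w >= 0.0 for w in res.per_site.values())
        assert (vw_results[1.0].mean_width > vw_results[0.5].mean_width
                > vw_results[0.0].mean_width)

    def test_inflammation_delays_window_onset(self, vw_results):
        # per-site window opening shifts later as severity grows
        def mean_open(res):
            opens = [r.open for r in res.results if r.found]
            return np.mean(opens)
        assert mean_open(vw_results[1.0]) > mean_open(vw_results[0.0])


class TestRecordingExport:
    def test_csv_and_hdf5_round_trip(self, control_recording, tmp_path):
        import io
        buf = io.StringIO()
        control_recording.write_csv(buf)
        header = buf.getvalue().splitlines()[0].split(",")
        assert header[0] == "time_ms"
        assert len(header) == control_recording.n_nodes + 1
        path = tmp_path / "rec.h5"
        control_recording.write_hdf5(path)
        back = SpaceTimeRecording.read_hdf5(path)
        assert np.allclose(back.vm, control_recording.vm)
        assert back.dx == control_recording.dx
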