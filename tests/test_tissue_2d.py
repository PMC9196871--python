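"""Sheet scenarios, 2-D propagation, reentry machinery and critical PCL."""

import numpy as np
import pytest

from cardioinflam import (ConductionClass, SheetStimulus, build_sheet,
                          build_strand, critical_pcl, endo_pacing,
                          induce_reentry, solve_sheet)
from cardioinflam.tissue_2d import winding_circulation


class TestBuildSheet:
    def test_control_has_no_lesion(self):
        g = build_sheet("control", nx=40, ny=40)
        assert not g.lesion.any()
        assert np.allclose(g.D[g.mask], 0.154)

    def test_global_scenario_reduces_coupling_everywhere(self):
        g = build_sheet("global", nx=40, ny=40)
        assert g.lesion[g.mask].all()
        assert np.allclose(g.D[g.mask], 0.154 * 0.65)
        assert np.allclose(g.D[g.mask], 0.1001)

    def test_layer_bands_match_proportions_within_one_column(self):
        g = build_sheet("control", nx=60, ny=20)
        n_endo = sum(1 for v in g.variants if v == "ENDO")
        n_mid = sum(1 for v in g.variants if v == "MID")
        assert abs(n_endo - 0.25 * 60) <= 1
        assert abs(n_mid - 0.35 * 60) <= 1

    def test_local_lesion_inside_tissue_away_from_pacing(self):
        g = build_sheet("local", nx=60, ny=60)
        assert g.lesion.any()
        assert not g.lesion[:, :3].any()
        assert (g.lesion & ~g.mask).sum() == 0
        frac = g.lesion.sum() / (60 * 60)
        assert 0.05 < frac < 0.2  # ~ (1/3)^2 of the sheet

    def test_obstacle_disjoint_from_tissue(self):
        g = build_sheet("control", nx=40, ny=40, obstacle=True)
        assert g.obstacle.any()
        assert not (g.obstacle & g.mask).any()

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            build_sheet("focal")

    def test_lesion_jitter_is_reproducible(self):
        a = build_sheet("local", nx=60, ny=60, rng=np.random.default_rng(5))
        b = build_sheet("local", nx=60, ny=60, rng=np.random.default_rng(5))
        assert (a.lesion == b.lesion).all()


class TestSolveSheet:
    def test_point_stimulus_wavefront_is_isotropic(self):
        g = build_sheet("control", nx=50, ny=50)
        stim = [SheetStimulus(start=0.0, amplitude=160.0,
                              x0=24, x1=27, y0=24, y1=27)]
        rec = solve_sheet(g, stim, 40.0, record_dt=1.0)
        at = rec.activation_times()
        d = 15
        arms = [at[25, 25 + d], at[25, 25 - d], at[25 + d, 25], at[25 - d, 25]]
        assert np.all(np.isfinite(arms))
        assert max(arms) / min(arms) < 1.05

    def test_row_cv_matches_strand_value(self):
        g = build_sheet("control", nx=80, ny=30)
        rec = solve_sheet(g, endo_pacing(1), 120.0, record_dt=0.5)
        at = rec.activation_times()
        cv = (60 - 20) * 0.15 / (at[15, 60] - at[15, 20])
        assert cv == pytest.approx(0.74, abs=0.05)

    def test_obstacle_blocks_conduction_inside_void(self):
        g = build_sheet("control", nx=50, ny=50, obstacle=True)
        rec = solve_sheet(g, endo_pacing(1), 120.0, record_dt=1.0)
        at = rec.activation_times()
        assert np.isnan(at[g.obstacle]).all()
        assert np.isfinite(at[g.mask]).all()  # wave goes around the hole


class TestWindingClassifier:
    def _ring(self, n=40):
        ang = np.linspace(-np.pi, np.pi, n, endpoint=False)
        return ang

    def test_detects_circulating_activation(self):
        ang = self._ring()
        period = 180.0
        act = 500.0 + (ang + np.pi) / (2 * np.pi) * period
        assert winding_circulation(act, ang)

    def test_rejects_plane_wave_invasion(self):
        ang = self._ring()
        # symmetric arrival from one side: time depends on |angle|
        act = 500.0 + 50.0 * np.abs(ang) / np.pi
        assert not winding_circulation(act, ang)

    def test_rejects_simultaneous_activation(self):
        ang = self._ring()
        assert not winding_circulation(np.full_like(ang, 400.0), ang)


class TestReentry:
    def test_s2_far_above_window_not_inducible(self):
        g = build_sheet("control", nx=40, ny=40)
        res = induce_reentry(g, scan=(900.0, 940.0, 2.0), follow_ms=400.0)
        assert not res.induced
        assert res.reentry_type == "none"
        assert res.lifetime_ms == 0.0

    def test_unidirectional_block_found_at_lesion_border(self):
        g = build_sheet("local", nx=50, ny=50)
        res = induce_reentry(g, follow_ms=600.0)
        # the premature wave escapes on one side of the border; in a sheet
        # far smaller than the excitation wavelength it cannot re-enter
        assert res.s2_coupling is None or res.s2_coupling >= 250.0
        assert res.lifetime_ms < 600.0


class TestCriticalPCL:
    def test_inflamed_critical_pcl_exceeds_control(self, pcl_results):
        assert pcl_results[1.0].critical_pcl > pcl_results[0.0].critical_pcl

    def test_two_to_one_below_critical(self, pcl_results):
        for res in pcl_results.values():
            assert res.class_below == ConductionClass.TWO_TO_ONE

    def test_no_one_to_one_recorded_below_critical(self, pcl_results):
        for res in pcl_results.values():
            for pcl, cls in res.classes.items():
                if pcl < res.critical_pcl:
                    assert cls != ConductionClass.ONE_TO_ONE

    def test_heart_rate_conversion(self, pcl_results):
        res = pcl_results[1.0]
        assert res.heart_rate_bpm == pytest.approx(60000.0 / res.critical_pcl)

    def test_one_row_sheet_matches_strand(self, pcl_results):
        sheet = build_sheet("control", nx=100, ny=1)
        r = critical_pcl(sheet)
        assert abs(r.critical_pcl - pcl_results[0.0].critical_pcl) <= 2.0

    def test_range_without_transition_raises(self):
        g = build_strand()
        with pytest.raises(RuntimeError, match="1:1"):
            critical_pcl(g, pcl_range=(180.0, 220.0))


class TestSheetExport:
    def test_snapshot_text_and_hdf5(self, tmp_path):
        g = build_sheet("control", nx=20, ny=20)
        rec = solve_sheet(g, endo_pacing(1), 10.0, record_dt=2.0)
        txt = tmp_path / "frame.txt"
        with open(txt, "w") as fp:
            rec.write_snapshot_txt(fp, time_index=0)
        frame = np.loadtxt(txt)
        assert frame.shape == (20, 20)
        rec.write_hdf5(tmp_path / "rec.h5")
        import h5py
        with h5py.File(tmp_path / "rec.h5") as f:
            assert f["vm"].shape == rec.vm.shape
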