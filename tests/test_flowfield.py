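"""Unit-cell solver: rasterization, conservation, shear, critical diameter."""

import numpy as np
import pytest

from clusterdld import flowfield as F
from clusterdld import geometry as G

from conftest import STAGE1_PER_GAP, STAGE2_PER_GAP


class TestRasterize:
    def test_cylinder_area_matches_disk(self, stage1_cell):
        area = stage1_cell.mask.sum() * stage1_cell.resolution ** 2
        assert area == pytest.approx(np.pi * 25.0 ** 2, rel=0.02)

    def test_hybrid_area_matches_analytic_footprint(self, stage2_cell):
        area = stage2_cell.mask.sum() * stage2_cell.resolution ** 2
        assert area == pytest.approx(
            stage2_cell.shape.footprint_area(), rel=0.02)

    def test_hybrid_mask_is_fore_aft_asymmetric(self, stage2_cell):
        m = stage2_cell.mask
        assert (m ^ m[::-1, :]).sum() > 0

    def test_degenerate_grooves_still_valid(self):
        shape = G.PillarShape.asymmetric_hybrid(
            77.0, 60.0, groove_width_fraction=0.4,
            groove_depth_fraction=0.01)
        with pytest.raises(ValueError, match="too coarse"):
            # groove depth 0.77 µm is below what a 1 µm grid resolves
            F.rasterize_pillar(shape, 1.0, 140.0, 140.0, 30.0, 20.0)
        shape2 = G.PillarShape.asymmetric_hybrid(
            77.0, 60.0, groove_width_fraction=0.5,
            groove_depth_fraction=0.3)
        cell = F.rasterize_pillar(shape2, 1.0, 140.0, 140.0, 30.0, 20.0)
        assert cell.mask.any()


class TestSolver:
    def test_empty_cell_recovers_uniform_plane_flow(self):
        mask = np.zeros((56, 56), dtype=bool)
        cell = F.UnitCell(mask=mask, resolution=2.0, length_x=112.0,
                          length_y=112.0, depth=90.0, row_shift=16.0,
                          pillar_center=(56.0, 56.0))
        fld = F.solve_unit_cell(cell, 5.0)
        U = fld.mean_velocity
        assert np.allclose(fld.u, U, rtol=0.01)
        assert np.abs(fld.v).max() < 0.01 * U

    def test_flux_achieved_exactly(self, stage1_field):
        assert stage1_field.achieved_per_gap_flux_ul_min == \
            pytest.approx(STAGE1_PER_GAP, rel=1e-9)

    def test_flux_constant_across_all_cross_sections(self, stage1_field):
        u = stage1_field._u_raw
        col_flux = u.sum(axis=1)
        assert np.allclose(col_flux, col_flux[0], rtol=1e-9)

    def test_discrete_divergence_vanishes(self, stage1_field, stage2_field):
        assert stage1_field.max_divergence() < 1e-6
        assert stage2_field.max_divergence() < 1e-6

    def test_no_slip_on_pillar(self, stage1_field):
        import scipy.ndimage as ndi
        mask = stage1_field.cell.mask
        boundary = mask & ~ndi.binary_erosion(mask)
        speed = np.hypot(stage1_field._u_raw, stage1_field._v_raw)
        assert speed[boundary].max() < 0.02 * abs(stage1_field.mean_velocity)

    def test_stokes_linearity_exact(self, stage2_cell):
        f1 = F.solve_unit_cell(stage2_cell, STAGE2_PER_GAP)
        f2 = F.solve_unit_cell(stage2_cell, 2.0 * STAGE2_PER_GAP)
        scale = np.abs(f1.u).max()
        assert np.abs(f2.u - 2.0 * f1.u).max() < 1e-6 * scale

    def test_untilted_cylinder_speed_mirror_symmetric(self, device):
        st = device.stage1
        cell = F.rasterize_pillar(st.pillar, 1.0, st.pitch, st.pitch,
                                  st.ceiling_height, row_shift=0.0)
        fld = F.solve_unit_cell(cell, STAGE1_PER_GAP)
        s = fld.speed
        fluid = ~cell.mask
        sym = fluid & fluid[:, ::-1]
        rel = np.linalg.norm((s - s[:, ::-1])[sym]) / np.linalg.norm(s[sym])
        assert rel < 0.02

    def test_coarse_3d_mode_not_available(self, stage1_cell):
        with pytest.raises(NotImplementedError):
            F.solve_unit_cell(stage1_cell, 5.0, model="coarse_3d")


class TestCriticalDiameterFromField:
    def test_cylinder_agrees_with_parabolic_analytic(self, stage1_field):
        dc = F.critical_diameter_from_field(stage1_field, 1 / 7)
        analytic = G.critical_diameter(63.0, 1 / 7, "parabolic").d_c
        assert dc.d_c == pytest.approx(analytic, rel=0.10)
        assert dc.method == "cfd"

    def test_plug_field_beta_is_gap_times_epsilon(self, stage1_plug):
        dc = F.critical_diameter_from_field(stage1_plug, 1 / 7)
        assert dc.first_stream_width == pytest.approx(63.0 / 7.0, abs=0.02)
        # flux proportional to width under a plug profile
        dc2 = F.critical_diameter_from_field(stage1_plug, 2 / 7)
        assert dc2.first_stream_width == \
            pytest.approx(2 * dc.first_stream_width, abs=0.05)

    def test_full_flux_fraction_spans_gap(self, stage1_plug):
        dc = F.critical_diameter_from_field(stage1_plug, 1.0)
        assert dc.first_stream_width == pytest.approx(63.0, abs=0.05)


class TestWallShear:
    def test_zero_flow_zero_shear(self, stage1_cell):
        zero = F.FlowField(cell=stage1_cell,
                           u=np.zeros(stage1_cell.mask.shape),
                           v=np.zeros(stage1_cell.mask.shape),
                           psi=np.zeros(stage1_cell.mask.shape),
                           mean_velocity=0.0, per_gap_flux_ul_min=0.0,
                           viscosity_mpas=1.0)
        rep = F.wall_shear_map(zero)
        assert rep.peak_pa == 0.0

    def test_stage1_peak_within_30pct_of_reference(self, stage1_field):
        rep = F.wall_shear_map(stage1_field)
        assert rep.peak_pa == pytest.approx(2.9, rel=0.30)

    def test_stage2_peak_within_30pct_of_reference(self, stage2_field):
        rep = F.wall_shear_map(stage2_field)
        assert rep.peak_pa == pytest.approx(4.8, rel=0.30)

    def test_peak_sits_at_the_gap_throat(self, stage1_field):
        rep = F.wall_shear_map(stage1_field)
        cx, cy = stage1_field.cell.pillar_center
        x, y = rep.peak_location_um
        assert abs(x - cx) <= 10.0          # narrowest section is at x = cx
        # and on the pillar surface, not in the open stream
        r = np.hypot(x - cx, ((y - cy + 56.5) % 113.0) - 56.5)
        assert abs(r - 25.0) <= 3.0

    def test_shear_scales_linearly_with_flow(self, stage1_cell, stage1_field):
        doubled = F.solve_unit_cell(stage1_cell, 2.0 * STAGE1_PER_GAP)
        r1 = F.wall_shear_map(stage1_field)
        r2 = F.wall_shear_map(doubled)
        assert r2.peak_pa == pytest.approx(2.0 * r1.peak_pa, rel=1e-6)


class TestGridConvergence:
    def test_peak_shear_and_dc_stable_under_refinement(self, device,
                                                       stage1_field):
        st = device.stage1
        fine_cell = F.rasterize_pillar(st.pillar, 0.5, st.pitch, st.pitch,
                                       st.ceiling_height, st.row_shift)
        fine = F.solve_unit_cell(fine_cell, STAGE1_PER_GAP)
        tau_c = F.wall_shear_map(stage1_field).peak_pa
        tau_f = F.wall_shear_map(fine).peak_pa
        assert abs(tau_c - tau_f) / tau_f < 0.05
        dc_c = F.critical_diameter_from_field(stage1_field, 1 / 7).d_c
        dc_f = F.critical_diameter_from_field(fine, 1 / 7).d_c
        assert abs(dc_c - dc_f) / dc_f < 0.05


class TestAsymmetry:
    def test_mirror_symmetric_field_scores_zero(self, stage1_cell):
        shape = stage1_cell.mask.shape
        u = np.ones(shape)
        sym = F.FlowField(cell=stage1_cell, u=u, v=np.zeros(shape),
                          psi=np.zeros(shape), mean_velocity=1.0,
                          per_gap_flux_ul_min=1.0, viscosity_mpas=1.0)
        assert F.asymmetry_metric(sym) == pytest.approx(0.0, abs=1e-12)

    def test_untilted_cylinder_below_threshold(self, device):
        st = device.stage1
        cell = F.rasterize_pillar(st.pillar, 1.0, st.pitch, st.pitch,
                                  st.ceiling_height, row_shift=0.0)
        fld = F.solve_unit_cell(cell, STAGE1_PER_GAP)
        assert F.asymmetry_metric(fld) < 0.05

    def test_hybrid_scores_above_cylinder(self, stage1_field, stage2_field):
        assert F.asymmetry_metric(stage2_field) > \
            F.asymmetry_metric(stage1_field)


class TestStreamline:
    def test_streamline_exits_and_is_tangent(self, stage1_field):
        sl = F.trace_streamline(stage1_field, (0.5, 20.0))
        assert sl.terminal == "exit"
        pts = sl.points
        # verify tangency at a few interior points
        cell = stage1_field.cell
        for k in range(5, len(pts) - 5, max(len(pts) // 6, 1)):
            seg = pts[k + 1] - pts[k - 1]
            seg = seg / np.linalg.norm(seg)
            p = np.array([[pts[k][0] % cell.length_x,
                           pts[k][1] % cell.length_y]])
            vel = stage1_field.velocity_at(p)[0]
            vel = vel / np.linalg.norm(vel)
            assert float(seg @ vel) > 0.95
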