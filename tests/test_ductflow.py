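"""Rectangular-duct flow model: operating point, series/FD cross-checks."""

import numpy as np
import pytest

from ecshear import units
from ecshear.ductflow import (DEVICE_GEOMETRY, WATERLIKE_MEDIUM, ChannelGeometry,
                              FluidProps, InvalidGeometryError, duct_flowrate,
                              duct_shape_factor, duct_velocity_series, is_laminar,
                              mean_velocity, operating_point_summary, plate_wall_shear,
                              pressure_drop, pressure_gradient_for_flowrate,
                              reynolds_number, shear_to_flowrate,
                              solve_crosssection_fd, wall_shear_profile)

Q_OP = units.m3_per_s(14.0)  # the device operating point


class TestOperatingPoint:
    def test_plate_shear_at_operating_point(self):
        # 14 mL/min in a 6.0 x 0.5 mm channel with 0.75 mPa.s medium
        assert plate_wall_shear(Q_OP) == pytest.approx(0.70, abs=1e-12)
        assert units.dyn_per_cm2(plate_wall_shear(Q_OP)) == pytest.approx(7.0)

    def test_shear_linearity_in_q_and_viscosity(self, rng):
        for _ in range(5):
            scale = rng.uniform(0.2, 5.0)
            assert plate_wall_shear(Q_OP * scale) == pytest.approx(
                scale * plate_wall_shear(Q_OP))
            fluid = FluidProps(viscosity=WATERLIKE_MEDIUM.viscosity * scale)
            assert plate_wall_shear(Q_OP, fluid=fluid) == pytest.approx(
                scale * plate_wall_shear(Q_OP))

    def test_zero_flow_zero_shear(self):
        assert plate_wall_shear(0.0) == 0.0

    def test_shear_to_flowrate_inverts(self, rng):
        assert units.ml_per_min(shear_to_flowrate(0.70)) == pytest.approx(14.0)
        assert shear_to_flowrate(0.0) == 0.0
        for tau in rng.uniform(0.01, 10.0, size=20):
            assert plate_wall_shear(shear_to_flowrate(tau)) == pytest.approx(tau)

    def test_mean_velocity(self):
        u = mean_velocity(Q_OP)
        assert u == pytest.approx(0.0778, abs=5e-5)
        assert round(u, 2) == 0.08
        assert mean_velocity(0.0) == 0.0
        assert mean_velocity(2 * Q_OP) == pytest.approx(2 * u)

    def test_reynolds_number_laminar(self):
        re = reynolds_number(Q_OP)
        # rho U D_h / mu with D_h = 0.923 mm, U = 0.0778 m/s
        assert re == pytest.approx(95.7, rel=0.01)
        assert is_laminar(re)
        assert reynolds_number(0.0) == 0.0
        assert reynolds_number(2 * Q_OP) == pytest.approx(2 * re)

    def test_pressure_drop(self):
        assert pressure_drop(0.0) == 0.0
        # plate approximation: G = 12 mu Q / (w h^3), L = 125.77 mm
        assert pressure_drop(Q_OP, model="plate") == pytest.approx(352.2, rel=0.001)
        # the duct model carries less flow per gradient -> larger drop
        assert pressure_drop(Q_OP) > pressure_drop(Q_OP, model="plate")
        qs = np.linspace(0, 2 * Q_OP, 5)
        drops = [pressure_drop(q) for q in qs]
        assert np.all(np.diff(drops) > 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ChannelGeometry(width=-1e-3, height=0.5e-3, length=0.1)
        with pytest.raises(InvalidGeometryError):
            FluidProps(viscosity=0.0)
        with pytest.raises(ValueError):
            plate_wall_shear(-1e-9)

    def test_summary_reports_device_numbers(self):
        s = operating_point_summary(Q_OP)
        assert s["wall_shear_plate_pa"] == pytest.approx(0.70)
        assert s["laminar"] is True
        assert s["wall_shear_center_pa"] > s["wall_shear_plate_pa"]


class TestSeriesSolution:
    def test_no_slip_walls(self):
        g = 2000.0
        geom = DEVICE_GEOMETRY
        y = np.linspace(0, geom.width, 7)
        for z in (0.0, geom.height):
            u = duct_velocity_series(geom, g, WATERLIKE_MEDIUM, y, z)
            assert np.allclose(u, 0.0, atol=1e-12)
        for yv in (0.0, geom.width):
            u = duct_velocity_series(geom, g, WATERLIKE_MEDIUM, yv,
                                     np.linspace(0, geom.height, 7))
            assert np.allclose(u, 0.0, atol=1e-9)

    def test_wide_channel_center_velocity_is_plane_poiseuille(self):
        # w/h = 1000: centre velocity -> G h^2 / (8 mu)
        geom = ChannelGeometry(width=0.5, height=0.5e-3, length=0.1)
        g, mu = 1000.0, WATERLIKE_MEDIUM.viscosity
        u_c = duct_velocity_series(geom, g, WATERLIKE_MEDIUM,
                                   geom.width / 2, geom.height / 2)
        assert u_c == pytest.approx(g * geom.height ** 2 / (8 * mu), rel=1e-3)

    def test_series_truncation_converged(self):
        g = pressure_gradient_for_flowrate(Q_OP, DEVICE_GEOMETRY, WATERLIKE_MEDIUM)
        y = np.linspace(0, DEVICE_GEOMETRY.width, 41)[:, None]
        z = np.linspace(0, DEVICE_GEOMETRY.height, 11)[None, :]
        u51 = duct_velocity_series(DEVICE_GEOMETRY, g, WATERLIKE_MEDIUM, y, z, n_terms=51)
        u201 = duct_velocity_series(DEVICE_GEOMETRY, g, WATERLIKE_MEDIUM, y, z, n_terms=201)
        assert np.max(np.abs(u51 - u201)) <= 1e-8 * np.max(u201)

    def test_shape_factor_limits(self):
        assert duct_shape_factor(1e4) == pytest.approx(1.0, abs=1e-2)
        # classical tabulated value for the square duct
        assert duct_shape_factor(1.0) == pytest.approx(0.4217, abs=5e-4)
        for aspect in (1.0, 4.0, 12.0):
            assert 0.0 < duct_shape_factor(aspect) < 1.0

    def test_wide_channel_flowrate_limit(self):
        geom = ChannelGeometry(width=1.0, height=0.5e-3, length=0.1)
        g, mu = 500.0, WATERLIKE_MEDIUM.viscosity
        q = duct_flowrate(geom, g, WATERLIKE_MEDIUM)
        assert q == pytest.approx(g * geom.width * geom.height ** 3 / (12 * mu), rel=2e-3)


class TestShearProfile:
    def test_symmetry_and_side_wall_zero(self):
        g = 2000.0
        prof = wall_shear_profile(DEVICE_GEOMETRY, g, WATERLIKE_MEDIUM)
        assert np.allclose(prof.tau, prof.tau[::-1], rtol=1e-9)
        assert prof.tau[0] == pytest.approx(0.0, abs=1e-9)
        assert prof.tau[-1] == pytest.approx(0.0, abs=1e-9)

    def test_wide_channel_center_shear_is_plane_poiseuille(self):
        geom = ChannelGeometry(width=0.5, height=0.5e-3, length=0.1)
        g = 1000.0
        prof = wall_shear_profile(geom, g, WATERLIKE_MEDIUM,
                                  y_grid=np.array([geom.width / 2]))
        assert prof.tau[0] == pytest.approx(g * geom.height / 2, rel=1e-2)

    def test_center_plateau_flat_at_device_aspect(self):
        g = 2000.0
        prof = wall_shear_profile(DEVICE_GEOMETRY, g, WATERLIKE_MEDIUM)
        central = prof.tau[(prof.y > 0.1 * DEVICE_GEOMETRY.width)
                           & (prof.y < 0.9 * DEVICE_GEOMETRY.width)]
        assert np.ptp(central) / central.max() < 0.02

    def test_center_shear_exceeds_plate_formula_slightly(self):
        # side walls steal flow, so at fixed Q the centre shear runs a few
        # percent above 6 mu Q/(w h^2)
        g = pressure_gradient_for_flowrate(Q_OP, DEVICE_GEOMETRY, WATERLIKE_MEDIUM)
        prof = wall_shear_profile(DEVICE_GEOMETRY, g, WATERLIKE_MEDIUM,
                                  y_grid=np.array([DEVICE_GEOMETRY.width / 2]))
        ratio = prof.tau[0] / plate_wall_shear(Q_OP)
        assert 1.0 < ratio < 1.10

    def test_z_eval_must_be_inside_channel(self):
        with pytest.raises(ValueError):
            wall_shear_profile(DEVICE_GEOMETRY, 1.0, WATERLIKE_MEDIUM,
                               z_eval=2 * DEVICE_GEOMETRY.height)


class TestFiniteDifferenceOracle:
    def test_zero_gradient_zero_field(self):
        f = solve_crosssection_fd(DEVICE_GEOMETRY, 0.0, WATERLIKE_MEDIUM, ny=31, nz=11)
        assert np.all(f.u == 0)

    def test_mirror_symmetry(self):
        f = solve_crosssection_fd(DEVICE_GEOMETRY, 1500.0, WATERLIKE_MEDIUM, ny=61, nz=15)
        assert np.allclose(f.u, f.u[::-1, :], atol=1e-12 * f.u.max())
        assert np.allclose(f.u, f.u[:, ::-1], atol=1e-12 * f.u.max())

    def test_boundary_exactly_zero(self):
        f = solve_crosssection_fd(DEVICE_GEOMETRY, 1500.0, WATERLIKE_MEDIUM, ny=31, nz=11)
        assert np.all(f.u[0, :] == 0) and np.all(f.u[-1, :] == 0)
        assert np.all(f.u[:, 0] == 0) and np.all(f.u[:, -1] == 0)

    @pytest.mark.parametrize("aspect,ny,nz", [(1.0, 81, 81), (4.0, 161, 41), (12.0, 241, 21)])
    def test_series_agrees_with_fd(self, aspect, ny, nz):
        geom = ChannelGeometry(width=aspect * 0.5e-3, height=0.5e-3, length=0.1)
        g = 2000.0
        fd = solve_crosssection_fd(geom, g, WATERLIKE_MEDIUM, ny=ny, nz=nz)
        series = duct_velocity_series(geom, g, WATERLIKE_MEDIUM,
                                      fd.y[:, None], fd.z[None, :])
        err = np.max(np.abs(series - fd.u)) / np.max(series)
        assert err < 0.005

    def test_flowrate_conservation(self):
        g = pressure_gradient_for_flowrate(Q_OP, DEVICE_GEOMETRY, WATERLIKE_MEDIUM)
        fd = solve_crosssection_fd(DEVICE_GEOMETRY, g, WATERLIKE_MEDIUM, ny=241, nz=21)
        assert fd.flow_rate() == pytest.approx(Q_OP, rel=0.01)

    def test_square_duct_shape_factor_vs_fd_integration(self):
        geom = ChannelGeometry(width=1e-3, height=1e-3, length=0.1)
        g = 1000.0
        fd = solve_crosssection_fd(geom, g, WATERLIKE_MEDIUM, ny=121, nz=121)
        f_fd = fd.flow_rate() / (g * geom.width * geom.height ** 3
                                 / (12 * WATERLIKE_MEDIUM.viscosity))
        assert duct_shape_factor(1.0) == pytest.approx(f_fd, rel=0.005)

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            solve_crosssection_fd(DEVICE_GEOMETRY, 1.0, WATERLIKE_MEDIUM, ny=4, nz=4)
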