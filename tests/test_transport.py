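"""Darcy-flow and transport solver: closed forms, conservation, stability."""

import numpy as np
import pytest

from conftest import slab_series_formation_time, slab_series_profile
from morphflow import transport as tr


@pytest.fixture(scope="module")
def props():
    return tr.PorousMediumProps()  # collagen: 0.99, 2e-13 m^2, 1 cP, 1000 kg/m^3


@pytest.fixture(scope="module")
def slab_geom():
    # flow path (width) 1 mm, transparent interface: the 1-D slab limit
    return tr.DeviceGeometry(chamber_length=0.2e-3, chamber_width=1e-3,
                             grid_spacing=1e-3 / 50, pore_conductance=np.inf)


class TestHeadConversion:
    def test_zero_head(self, props):
        assert tr.head_to_pressure(0.0, props) == 0.0

    @pytest.mark.parametrize("head_mm,expected_pa", [(2.0, 19.6133), (20.0, 196.133)])
    def test_rho_g_h(self, props, head_mm, expected_pa):
        assert tr.head_to_pressure(head_mm, props) == pytest.approx(expected_pa, rel=1e-9)

    def test_linear_in_head(self, props):
        assert tr.head_to_pressure(7.0, props) == pytest.approx(
            7 * tr.head_to_pressure(1.0, props))

    def test_negative_head_names_line(self, props):
        with pytest.raises(ValueError, match="inlet"):
            tr.PressureBoundary(inlet_head=-1.0, outlet_head=0.0)
        with pytest.raises(ValueError, match="outlet"):
            tr.PressureBoundary(inlet_head=1.0, outlet_head=-2.0)


class TestDarcy:
    def test_slab_matches_analytic_velocity(self, slab_geom, props):
        # v = k dP / (mu L): dP = 9.80665 Pa over L = 1 mm -> 1.961 um/s
        bc = tr.PressureBoundary(inlet_head=1.0, outlet_head=0.0)
        flow = tr.solve_darcy(slab_geom, props, bc)
        v_exact = props.permeability * 9.80665 / (props.viscosity * 1e-3)
        assert np.abs(np.abs(flow.velocity_y) - v_exact).max() / v_exact < 1e-6
        assert np.abs(flow.velocity_x).max() / v_exact < 1e-9

    def test_equal_heads_give_zero_velocity(self, slab_geom, props):
        flow = tr.solve_darcy(slab_geom, props, tr.PressureBoundary(3.0, 3.0))
        assert flow.speed.max() < 1e-15

    def test_doubling_pressure_doubles_velocity_exactly(self, props):
        geom = tr.aligned_preset(grid_spacing=25e-6, pore_conductance=1e-6)
        f1 = tr.solve_darcy(geom, props, tr.PressureBoundary(2.0, 0.0))
        f2 = tr.solve_darcy(geom, props, tr.PressureBoundary(4.0, 0.0))
        assert np.array_equal(f2.face_flux_y, 2 * f1.face_flux_y)
        assert np.array_equal(f2.face_flux_x, 2 * f1.face_flux_x)

    def test_linearity_across_head_range(self, props):
        geom = tr.aligned_preset(grid_spacing=25e-6, pore_conductance=1e-6)
        heads = [2.0, 5.0, 10.0, 20.0]
        vmax = [tr.solve_darcy(geom, props, tr.PressureBoundary(h, 0.0)).speed.max()
                for h in heads]
        slope = [v / h for v, h in zip(vmax, heads)]
        assert np.ptp(slope) / slope[0] < 1e-9

    def test_mass_conservation(self, props):
        geom = tr.aligned_preset(grid_spacing=12.5e-6, pore_conductance=1e-6)
        flow = tr.solve_darcy(geom, props, tr.PressureBoundary(10.0, 0.0))
        assert flow.max_relative_divergence() < 1e-6

    def test_under_constrained_boundary_reported(self, props):
        geom = tr.aligned_preset(pore_conductance=1e-300)
        with pytest.raises(ValueError, match="under-constrained"):
            tr.solve_darcy(geom, props, tr.PressureBoundary(1.0, 0.0))

    def test_calibration_hits_target(self, props):
        geom = tr.aligned_preset(grid_spacing=25e-6)
        target = 10e-6  # 10 um/s at 10 mm H2O
        g = tr.calibrate_pore_conductance(geom, props, target, 10.0)
        flow = tr.solve_darcy(
            tr.DeviceGeometry(**{**geom.__dict__, "pore_conductance": g}),
            props, tr.PressureBoundary(10.0, 0.0))
        assert flow.speed.max() == pytest.approx(target, rel=1e-6)


class TestReynoldsPeclet:
    def test_zero_flow(self, props):
        geom = tr.aligned_preset(grid_spacing=25e-6)
        rp = tr.reynolds_peclet(tr.zero_flow(geom), geom, props, 7e-11)
        assert rp["Re_max"] == 0.0 and rp["Pe"] == 0.0

    def test_closed_forms(self, props):
        # |v| = 10 um/s, W = 250 um: Re = 2.5e-3, Pe ~ 35.7
        geom = tr.aligned_preset(grid_spacing=25e-6)
        flow = tr.zero_flow(geom)
        flow.velocity_x[:] = 10e-6
        rp = tr.reynolds_peclet(flow, geom, props, 7e-11)
        assert rp["Re_max"] == pytest.approx(2.5e-3, rel=1e-9)
        assert rp["Pe"] == pytest.approx(10e-6 * 250e-6 / 7e-11, rel=1e-9)


@pytest.fixture(scope="module")
def chamber():
    return tr.DeviceGeometry(chamber_length=100e-6, chamber_width=250e-6,
                             grid_spacing=250e-6 / 50)


class TestTransport:
    L = 250e-6
    D = 7e-11

    def test_zero_boundaries_stay_zero(self, chamber):
        params = tr.TransportParams(diffusivity=self.D, time_step=50.0,
                                    total_time=1000.0, source_concentration=0.0)
        conc = tr.solve_transport(tr.zero_flow(chamber), chamber, params)
        assert np.abs(conc.concentration).max() == 0.0

    def test_long_time_linear_profile(self, chamber):
        params = tr.TransportParams(diffusivity=self.D, time_step=10.0,
                                    total_time=5 * self.L**2 / self.D)
        conc = tr.solve_transport(tr.zero_flow(chamber), chamber, params,
                                  output_times=[5 * self.L**2 / self.D])
        ny = chamber.shape[0]
        y = (np.arange(ny) + 0.5) * chamber.grid_spacing
        prof = conc.profile()[-1]
        assert np.abs(prof - y / self.L).max() < 1e-3
        mid = 0.5 * (prof[ny // 2 - 1] + prof[ny // 2])
        assert mid == pytest.approx(0.5, abs=1e-3)

    def test_transient_matches_series_oracle(self, chamber):
        total = 3 * self.L**2 / self.D
        params = tr.TransportParams(diffusivity=self.D, time_step=2.0, total_time=total)
        times = np.linspace(0, total, 25)[1:]
        conc = tr.solve_transport(tr.zero_flow(chamber), chamber, params,
                                  output_times=times)
        y = (np.arange(chamber.shape[0]) + 0.5) * chamber.grid_spacing
        steady_rms = 1 / np.sqrt(3)
        for k, t in enumerate(conc.times):
            exact = slab_series_profile(y, t, self.L, self.D)
            err = np.sqrt(np.mean((conc.profile()[k] - exact) ** 2)) / steady_rms
            assert err < 0.01, f"L2 error {err:.4f} at t={t:.0f}s"

    def test_maximum_principle(self, chamber, props):
        geom = tr.DeviceGeometry(chamber_length=500e-6, chamber_width=250e-6,
                                 grid_spacing=25e-6, pore_conductance=1e-6)
        flow = tr.solve_darcy(geom, props, tr.PressureBoundary(10.0, 0.0))
        params = tr.TransportParams(time_step=30.0, total_time=2 * 3600.0)
        conc = tr.solve_transport(flow, geom, params, porosity=props.porosity)
        assert conc.concentration.min() >= -1e-9
        assert conc.concentration.max() <= 1.0 + 1e-9

    def test_unstable_step_refused_with_bound(self, props):
        geom = tr.DeviceGeometry(chamber_length=500e-6, chamber_width=250e-6,
                                 grid_spacing=25e-6, pore_conductance=1e-5)
        flow = tr.solve_darcy(geom, props, tr.PressureBoundary(20.0, 0.0))
        params = tr.TransportParams(time_step=1e4, total_time=2e4)
        with pytest.raises(ValueError, match="stability bound"):
            tr.solve_transport(flow, geom, params, auto_substep=False)
        # with auto-substepping the same request succeeds and stays bounded
        conc = tr.solve_transport(flow, geom, params)
        assert conc.concentration.max() <= 1.0 + 1e-9

    def test_boundary_rescaling_invariance(self, chamber):
        params1 = tr.TransportParams(diffusivity=self.D, time_step=20.0,
                                     total_time=500.0, source_concentration=1.0)
        params2 = tr.TransportParams(diffusivity=self.D, time_step=20.0,
                                     total_time=500.0, source_concentration=0.25)
        flow = tr.zero_flow(chamber)
        c1 = tr.solve_transport(flow, chamber, params1, output_times=[500.0])
        c2 = tr.solve_transport(flow, chamber, params2, output_times=[500.0])
        assert np.allclose(c2.concentration * 4.0, c1.concentration, atol=1e-12)


class TestGradientMetrics:
    L = 250e-6
    D = 7e-11

    def test_steady_initial_condition_formed_at_zero(self, chamber):
        ny = chamber.shape[0]
        y = (np.arange(ny) + 0.5) * chamber.grid_spacing
        steady = np.tile(y / self.L, (chamber.shape[1], 1)).T
        params = tr.TransportParams(diffusivity=self.D, time_step=20.0,
                                    total_time=200.0)
        conc = tr.solve_transport(tr.zero_flow(chamber), chamber, params,
                                  initial=steady, output_times=[0.0, 100.0, 200.0])
        gm = tr.gradient_metrics(conc, steady.mean(axis=1),
                                 maintenance_window=200.0)
        assert gm.formation_time == 0.0
        assert gm.maintained_24h

    def test_degenerate_zero_gradient_flagged(self, chamber):
        params = tr.TransportParams(diffusivity=self.D, time_step=50.0,
                                    total_time=500.0, source_concentration=0.0)
        conc = tr.solve_transport(tr.zero_flow(chamber), chamber, params)
        gm = tr.gradient_metrics(conc, np.zeros(chamber.shape[0]),
                                 maintenance_window=500.0)
        assert gm.degenerate
        assert gm.formation_time == 0.0
        assert gm.maintained_24h

    def test_formation_time_matches_series_oracle(self, chamber):
        total = 3 * self.L**2 / self.D
        times = np.linspace(0, total, 49)
        params = tr.TransportParams(diffusivity=self.D, time_step=5.0,
                                    total_time=total)
        conc = tr.solve_transport(tr.zero_flow(chamber), chamber, params,
                                  output_times=times)
        steady = tr.solve_steady_transport(tr.zero_flow(chamber), chamber, params)
        gm = tr.gradient_metrics(conc, steady.mean(axis=1), tolerance=0.05,
                                 maintenance_window=total)
        y = (np.arange(chamber.shape[0]) + 0.5) * chamber.grid_spacing
        oracle = slab_series_formation_time(times, y, self.L, self.D, 0.05)
        interval = times[1] - times[0]
        assert abs(gm.formation_time - oracle) <= interval + 1e-9

    def test_grid_convergence_of_formation_time(self):
        total = 3 * self.L**2 / self.D
        times = np.linspace(0, total, 97)
        result = {}
        for ns in (40, 80):
            geom = tr.DeviceGeometry(chamber_length=100e-6, chamber_width=self.L,
                                     grid_spacing=self.L / ns)
            params = tr.TransportParams(diffusivity=self.D, time_step=2.0,
                                        total_time=total)
            conc = tr.solve_transport(tr.zero_flow(geom), geom, params,
                                      output_times=times)
            steady = tr.solve_steady_transport(tr.zero_flow(geom), geom, params)
            gm = tr.gradient_metrics(conc, steady.mean(axis=1), tolerance=0.1,
                                     maintenance_window=total)
            result[ns] = gm.formation_time
        assert abs(result[80] - result[40]) / result[40] < 0.02


class TestGeometryValidation:
    def test_presets_have_stated_aspect_ratios(self):
        a = tr.aligned_preset()
        assert a.chamber_length / a.chamber_width == pytest.approx(20.0)
        r = tr.random_preset()
        assert r.chamber_length / r.chamber_width == pytest.approx(1.0)

    def test_grid_spacing_must_resolve_width(self):
        with pytest.raises(ValueError, match="grid_spacing"):
            tr.DeviceGeometry(chamber_length=1e-3, chamber_width=250e-6,
                              grid_spacing=50e-6)

    def test_positive_lengths_required(self):
        with pytest.raises(ValueError):
            tr.DeviceGeometry(chamber_length=-1e-3, chamber_width=250e-6)
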