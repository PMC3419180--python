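"""SIMPLE finite-volume solver: oracles, symmetries, conservation, transient."""

import dataclasses

import numpy as np
import pytest

import tortuflow as tf


def straight_setup(L=40.0, interval=1.0):
    geom = tf.VesselGeometry(L=L, n=0)
    path = tf.build_centerline(geom)
    mesh = tf.sweep_mesh(tf.offset_lumen(path, geom.d), path, interval)
    return geom, path, mesh


class TestSteady:
    def test_rest_state(self):
        _, _, mesh = straight_setup()
        f = tf.solve_steady(mesh, tf.FluidProperties(),
                            tf.BoundaryConditionSet(inlet_velocity=0.0,
                                                    outlet_pressure=250.0))
        assert np.abs(f.u).max() == 0.0 and np.abs(f.v).max() == 0.0
        assert np.allclose(f.p, 250.0)

    def test_fully_developed_profile_matches_discrete_oracle(self, coarse_straight):
        # 3 cells across: discrete parabola u = (3/4, 5/4, 3/4) * beta
        _, path, mesh, f = coarse_straight
        ni, nj = mesh.shape
        u = f.u.reshape(ni, nj)
        mid = u[ni // 2]
        assert mid[1] / mid[0] == pytest.approx(5.0 / 3.0, rel=2e-2)
        assert mid.mean() == pytest.approx(0.156, rel=5e-3)

    def test_fully_developed_gradient_matches_discrete_oracle(self, coarse_straight):
        _, path, mesh, f = coarse_straight
        ni, nj = mesh.shape
        p = f.p.reshape(ni, nj).mean(axis=1)
        x = mesh.cell_centroid[:, 0].reshape(ni, nj).mean(axis=1)
        i0, i1 = ni // 4, 3 * ni // 4
        grad = (p[i0] - p[i1]) / (x[i1] - x[i0])
        oracle = tf.coarse_channel_drop(0.0035, 0.156, 0.130, 0.003, 3) / 0.130
        assert grad == pytest.approx(oracle, rel=0.05)

    def test_midline_symmetry(self, coarse_straight):
        _, _, mesh, f = coarse_straight
        ni, nj = mesh.shape
        u = f.u.reshape(ni, nj)
        v = f.v.reshape(ni, nj)
        peak = np.abs(u).max()
        assert np.abs(u[:, 0] - u[:, 2]).max() <= 1e-6 * peak
        assert np.abs(v[:, 0] + v[:, 2]).max() <= 1e-6 * peak
        assert np.abs(v[:, 1]).max() <= 1e-6 * peak

    def test_mass_conservation(self, coarse_straight):
        *_, f = coarse_straight
        assert f.mass_imbalance <= 10.0 * 1e-3

    def test_gauge_invariance(self):
        _, _, mesh = straight_setup()
        fluid = tf.FluidProperties()
        f0 = tf.solve_steady(mesh, fluid, tf.BoundaryConditionSet(outlet_pressure=0.0))
        f1 = tf.solve_steady(mesh, fluid, tf.BoundaryConditionSet(outlet_pressure=500.0))
        assert np.allclose(f1.u, f0.u, atol=1e-10)
        assert np.allclose(f1.p - f0.p, 500.0, atol=1e-8)

    def test_grid_convergence_toward_poiseuille(self):
        # parabolic inlet: no development length; drop must approach
        # 12 mu U L / h^2 monotonically at observed order >= 1
        fluid = tf.FluidProperties()
        bc = tf.BoundaryConditionSet(inlet_profile="parabolic")
        exact = tf.poiseuille_drop(0.0035, 0.156, 0.040, 0.003)
        errs = []
        for h in (1.0, 0.5, 0.25):
            _, _, mesh = straight_setup(L=40.0, interval=h)
            f = tf.solve_steady(mesh, fluid, bc)
            dp = tf.pressure_drop(f, mesh).dp
            errs.append(abs(dp - exact) / exact)
        assert errs[0] > errs[1] > errs[2]
        order = np.log2(errs[0] / errs[1])
        assert order >= 1.0

    def test_nonconvergence_raises_with_history(self):
        _, _, mesh = straight_setup()
        cfg = tf.SolverConfig(max_iterations=5)
        with pytest.raises(tf.NonConvergenceError) as exc:
            tf.solve_steady(mesh, tf.FluidProperties(), tf.BoundaryConditionSet(), cfg)
        assert exc.value.history is not None and len(exc.value.history) == 5

    def test_laminar_guard_warns(self):
        # supercritical inlet speed triggers the laminar-regime warning;
        # the steady laminar solve itself may legitimately fail to converge
        _, _, mesh = straight_setup()
        with pytest.warns(UserWarning, match="Reynolds"):
            try:
                tf.solve_steady(mesh, tf.FluidProperties(),
                                tf.BoundaryConditionSet(inlet_velocity=10.0),
                                tf.SolverConfig(max_iterations=200))
            except tf.NonConvergenceError:
                pass


class TestResiduals:
    def test_converged_run_meets_tolerance(self, coarse_straight):
        *_, f = coarse_straight
        assert max(f.residuals.values()) <= 1e-3
        hist = f.history
        assert hist.shape[1] == 4
        # scaled residuals end well below their early peak
        assert hist[-1, 1:].max() < 0.1 * hist[:5, 1:].max()


class TestUnsteady:
    def test_constant_waveform_recovers_steady(self):
        geom = tf.VesselGeometry(theta_deg=120.0, n=1)
        path = tf.build_centerline(geom)
        mesh = tf.sweep_mesh(tf.offset_lumen(path, geom.d), path, 1.0)
        fluid = tf.FluidProperties()
        steady = tf.solve_steady(mesh, fluid, tf.BoundaryConditionSet())
        series = tf.solve_unsteady(mesh, fluid, tf.constant_waveform(0.156, 0.0),
                                   tf.SolverConfig(n_cycles=1), snapshot_times=[1.0])
        snap = series.at_time(1.0)
        peak = np.abs(steady.u).max()
        assert np.abs(snap.u - steady.u).max() <= 0.025 * peak
        dp_s = tf.pressure_drop(steady, mesh).dp
        dp_t = tf.pressure_drop(snap, mesh).dp
        assert dp_t == pytest.approx(dp_s, rel=0.01)

    def test_anchor_inlet_flux(self):
        # at the first cardiac landmark the imposed inlet mass flux is
        # rho * v(t1) * d per unit depth
        geom = tf.VesselGeometry(L=40.0, n=0)
        path = tf.build_centerline(geom)
        mesh = tf.sweep_mesh(tf.offset_lumen(path, geom.d), path, 1.0)
        wf = tf.build_waveform()
        series = tf.solve_unsteady(mesh, tf.FluidProperties(), wf,
                                   tf.SolverConfig(n_cycles=1),
                                   snapshot_times=[0.26])
        snap = series.at_time(0.26)
        influx = -snap.face_flux[mesh.patches["inlet"]].sum()
        assert influx == pytest.approx(1050.0 * 0.51 * 0.003, rel=1e-9)

    def test_time_step_must_divide_period(self):
        _, _, mesh = straight_setup()
        with pytest.raises(tf.SolverError, match="divide"):
            tf.solve_unsteady(mesh, tf.FluidProperties(), tf.build_waveform(),
                              tf.SolverConfig(time_step=0.03))

    def test_missing_snapshot_reports_stored_times(self):
        _, _, mesh = straight_setup()
        series = tf.solve_unsteady(mesh, tf.FluidProperties(),
                                   tf.constant_waveform(0.1, 0.0),
                                   tf.SolverConfig(n_cycles=1), snapshot_times=[0.5])
        with pytest.raises(KeyError, match="stored times"):
            series.at_time(0.75)


class TestValidation:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            tf.SolverConfig(tolerance=2.0)
        with pytest.raises(ValueError):
            tf.SolverConfig(relax_velocity=0.0)
        with pytest.raises(ValueError):
            tf.SolverConfig(time_step=-0.01)
        with pytest.raises(ValueError):
            tf.FluidProperties(mu=-1.0)
        with pytest.raises(ValueError):
            tf.BoundaryConditionSet(inlet_velocity=-0.1)
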