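"""Diagnostics: stabilization criterion, coercivity eigenvalues, dual norms,
a-priori constants and the executable energy/contraction estimates."""

import numpy as np
import pytest
import scipy.linalg

from oxytrans import diagnostics as dg
from oxytrans import transport
from oxytrans.config import GeometryConfig, NumericsConfig, RunConfiguration
from oxytrans.geometry import build_domain, triangulate
from oxytrans.transport import BoundaryData, StateFields, assemble


@pytest.fixture(scope="module")
def small_cfg():
    return RunConfiguration(
        geometry=GeometryConfig(side=0.9, n_inlets=8, n_outlets=8),
        numerics=NumericsConfig(n_edge_segments=24, t_final=3.0))


@pytest.fixture(scope="module")
def small_run(small_cfg):
    return transport.simulate(small_cfg)


@pytest.fixture(scope="module")
def small_constants(small_cfg, small_run):
    return dg.apriori_constants(
        small_run.params, small_run.bc, small_run.ops, small_run.velocity,
        small_cfg.initial.phi0, small_cfg.initial.theta0,
        small_run.times[-1])


def _fake_result(mesh, ops, params, times, phis, thetas):
    states = [StateFields(t, p, th) for t, p, th in zip(times, phis, thetas)]
    records = [dict(time=t, picard_residual=0.0) for t in times]
    return dg.SimulationResult(mesh=mesh, times=times, states=states,
                               records=records, ops=ops, params=params)


class TestStabilizationTime:
    def test_constant_series_is_zero(self, unit_square_mesh, params, table,
                                     closed_bc):
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        times = np.arange(5) * 0.5
        u = [np.full(n, 3.0)] * 5
        r = _fake_result(unit_square_mesh, ops, params, times, u, u)
        assert dg.stabilization_time(r, "phi", 0.01) == 0.0

    def test_synthetic_series_against_brute_force(self, unit_square_mesh,
                                                  params, table, closed_bc):
        """Ten-point decaying series: compare with a literal scan of the
        defining condition."""
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        dt = 0.5
        times = np.arange(10) * dt
        vals = np.exp(-times)  # u(t) = e^-t, spatially uniform
        phis = [np.full(n, v) for v in vals]
        r = _fake_result(unit_square_mesh, ops, params, times, phis, phis)
        eps = 0.3
        # independent brute force on the uniform field: rates are
        # |u(t+dt)-u(t)| / (dt*|u(T)|), the L2 factors cancel
        rates = np.abs(np.diff(vals)) / (dt * vals[-1])
        ok = [i for i in range(len(rates))
              if all(rt <= eps for rt in rates[i:])]
        expected = times[ok[0]] if ok else float("inf")
        assert dg.stabilization_time(r, "phi", eps) == expected

    def test_monotone_in_eps(self, small_run):
        ts = [dg.stabilization_time(small_run, "theta", e)
              for e in (0.003, 0.01, 0.03, 0.1)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_never_settling_series(self, unit_square_mesh, params, table,
                                   closed_bc):
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        times = np.arange(6) * 1.0
        phis = [np.full(n, float(i % 2)) for i in range(6)]
        r = _fake_result(unit_square_mesh, ops, params, times, phis, phis)
        assert dg.stabilization_time(r, "phi", 0.01) == float("inf")


class TestCoercivity:
    def test_two_triangle_mesh_vs_dense_eigensolver(self, params, table):
        mesh = triangulate(build_domain(1.0, 0, 0), 1, 8)
        bc = BoundaryData(gamma={c: 2.0 for c in transport.CLASSES},
                          delta={c: 3.0 for c in transport.CLASSES},
                          phi_b={c: 0.0 for c in transport.CLASSES})
        ops = assemble(mesh, params, bc, None, table)
        k1, k2 = dg.coercivity_constants(ops, mesh)
        for A, k in ((ops.A1, k1), (ops.A2, k2)):
            dense = scipy.linalg.eigh(A.toarray(), ops.Mv.toarray(),
                                      eigvals_only=True)
            assert k == pytest.approx(dense[0], abs=1e-10)

    def test_positive_on_perforated_mesh(self, small_run):
        k1, k2 = dg.coercivity_constants(small_run.ops, small_run.mesh)
        assert k1 > 0 and k2 > 0

    def test_doubling_gamma_does_not_decrease_k1(self, coarse_mesh, params,
                                                 table):
        ks = []
        for g in (1.0, 2.0):
            bc = BoundaryData(
                gamma={c: g * params.alpha * 100 for c in transport.CLASSES},
                delta={c: 1.0 for c in transport.CLASSES},
                phi_b={c: 0.0 for c in transport.CLASSES})
            ops = assemble(coarse_mesh, params, bc, None, table)
            ks.append(dg.coercivity_constants(ops, coarse_mesh)[0])
        assert ks[1] >= ks[0] - 1e-12


class TestDualNorm:
    def test_zero_functional(self, small_run):
        z = np.zeros(small_run.mesh.n_vertices)
        assert dg.dual_norm(z, small_run.ops) == 0.0

    def test_riesz_of_constant(self, unit_square_mesh, params, table,
                               closed_bc):
        # the functional (1, .)_V has dual norm ||1||_V = sqrt(area)
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        one = np.ones(unit_square_mesh.n_vertices)
        f = ops.Mv @ one
        assert dg.dual_norm(f, ops) == pytest.approx(1.0, rel=1e-10)

    def test_homogeneity(self, small_run, rng):
        f = rng.standard_normal(small_run.mesh.n_vertices)
        assert dg.dual_norm(3 * f, small_run.ops) == pytest.approx(
            3 * dg.dual_norm(f, small_run.ops), rel=1e-10)


class TestAprioriConstants:
    def test_no_flow_growth_rate(self, unit_square_mesh, params, table,
                                 closed_bc):
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        c = dg.apriori_constants(params, closed_bc, ops, None, 0.0, 0.0, 1.0)
        assert c.C2 == pytest.approx(params.a * (1 + params.kappa), rel=1e-9)
        assert c.C3 == pytest.approx(params.a / 2.0, rel=1e-12)
        assert c.C1 == pytest.approx(0.0, abs=1e-20)

    def test_all_positive_under_robin_condition(self, small_constants):
        c = small_constants
        assert min(c.k1, c.k2, c.C1, c.C2, c.C3) > 0


class TestEnergyBound:
    def test_margins_nonpositive_on_run(self, small_run, small_constants):
        margins = dg.energy_bound_check(small_run, small_constants)
        assert margins.max() <= 0.0

    def test_zero_data_gives_zero_margins(self, unit_square_mesh, params,
                                          table, closed_bc):
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        times = np.arange(4) * 0.25
        zero = [np.zeros(n)] * 4
        r = _fake_result(unit_square_mesh, ops, params, times, zero, zero)
        for rec, st in zip(r.records, r.states):
            rec.update(l2_phi=0.0, l2_theta=0.0, v_phi=0.0, v_theta=0.0)
        c = dg.apriori_constants(params, closed_bc, ops, None, 0.0, 0.0, 0.75)
        assert np.abs(dg.energy_bound_check(r, c)).max() == 0.0

    def test_check_is_not_vacuous(self, unit_square_mesh, params, table,
                                  closed_bc):
        """Closed run with nonzero initial data: C1 equals the initial energy
        exactly, so halving it must break the inequality at t = 0."""
        import dataclasses
        from oxytrans.config import RunConfiguration, GeometryConfig, \
            NumericsConfig, BoundaryConfig
        cfg = RunConfiguration(
            geometry=GeometryConfig(side=1.0, n_inlets=0, n_outlets=0),
            numerics=NumericsConfig(n_edge_segments=8, t_final=1.0),
            boundary=BoundaryConfig(gamma_multiplier=0.0,
                                    delta_multiplier=0.0,
                                    phi_b={"inlet": 0.0, "outlet": 0.0,
                                           "edge": 0.0}))
        res = transport.simulate(cfg)
        c = dg.apriori_constants(res.params, res.bc, res.ops, res.velocity,
                                 4.0, 0.01, 1.0)
        # here C1 equals the t=0 energy, so the margin touches 0 there
        assert dg.energy_bound_check(res, c).max() <= 1e-9
        c_half = dataclasses.replace(c, C1=c.C1 / 2)
        assert dg.energy_bound_check(res, c_half).max() > 1.0


class TestGronwallContraction:
    def test_identical_runs_give_zero_difference(self, small_run,
                                                 small_constants):
        m = dg.gronwall_difference_check(small_run, small_run,
                                         small_constants)
        assert np.abs(m).max() == 0.0

    def test_perturbed_initial_data_bound_holds(self, small_cfg, small_run,
                                                small_constants):
        import dataclasses
        cfg = RunConfiguration(
            geometry=small_cfg.geometry, numerics=small_cfg.numerics)
        cfg.initial = dataclasses.replace(cfg.initial, theta0=0.02)
        res2 = transport.simulate(cfg)
        m = dg.gronwall_difference_check(small_run, res2, small_constants)
        assert m.max() <= 0.0

    def test_unit_factor_bound_fails_for_growing_difference(
            self, unit_square_mesh, params, table, closed_bc):
        """A pair whose difference grows must violate the bound once the
        exponential factor is stripped (the check is non-vacuous)."""
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        times = np.arange(4) * 0.25
        growing = [np.full(n, 0.1 * 2.0 ** k) for k in range(4)]
        zero = [np.zeros(n)] * 4
        rA = _fake_result(unit_square_mesh, ops, params, times, growing, zero)
        rB = _fake_result(unit_square_mesh, ops, params, times, zero, zero)
        c = dg.apriori_constants(params, closed_bc, ops, None, 0.0, 0.0, 1.0)
        assert dg.gronwall_difference_check(rA, rB, c).max() <= 0.0
        import dataclasses
        c_flat = dataclasses.replace(c, C3=-params.kappa * params.a / 2.0)
        assert dg.gronwall_difference_check(rA, rB, c_flat).max() > 0.0


class TestPhysiologicalEstimates:
    @pytest.mark.parametrize("N, m, rho, expected, tol", [
        (76.8e6, 1200.0, 1.04, 0.25, 0.005),  # adult-brain estimate
        (1, 1.0, 1.0, 10.0, 1e-12),           # 1 cm cube
        (8, 1.0, 1.0, 5.0, 1e-12),            # 8x the count halves the side
    ])
    def test_mean_inlet_separation(self, N, m, rho, expected, tol):
        assert dg.mean_inlet_separation(N, m, rho) == pytest.approx(
            expected, abs=tol)

    def test_separation_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dg.mean_inlet_separation(0, 1.0, 1.0)

    def test_diffusion_time_scaling(self):
        assert dg.diffusion_time(0.02, 0.0024) == pytest.approx(1 / 6, rel=1e-9)
        assert dg.diffusion_time(0.02, 0.0024, c=2.0) == pytest.approx(
            1 / 12, rel=1e-9)


class TestTotalOxygen:
    def test_zero_state(self, unit_square_mesh):
        n = unit_square_mesh.n_vertices
        s = StateFields(0.0, np.zeros(n), np.zeros(n))
        assert dg.total_oxygen(s, unit_square_mesh, 0.03) == 0.0

    def test_unit_fields_integrate_to_area(self, unit_square_mesh):
        n = unit_square_mesh.n_vertices
        s = StateFields(0.0, np.ones(n), np.ones(n))
        assert dg.total_oxygen(s, unit_square_mesh, 0.3) == pytest.approx(1.0)

    def test_hypoxic_initial_content(self, small_run):
        s0 = small_run.states[0]
        sigma = small_run.params.sigma
        expected = (sigma * 4.0 + (1 - sigma) * 0.01) * small_run.mesh.area()
        assert dg.total_oxygen(s0, small_run.ops, sigma) == pytest.approx(
            expected, rel=1e-12)
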