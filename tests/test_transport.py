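"""Transport assembly and time stepping: operator identities, nonlinear-sweep
convergence, conservation, and agreement with the well-mixed ODE limit."""

import numpy as np
import pytest

from oxytrans import transport
from oxytrans.config import GeometryConfig, NumericsConfig, RunConfiguration
from oxytrans.kinetics import ModelParameters, build_inverse_hill
from oxytrans.oracles import ode_reduction
from oxytrans.transport import BoundaryData, StateFields, advance, assemble


@pytest.fixture(scope="module")
def small_cfg():
    return RunConfiguration(
        geometry=GeometryConfig(side=0.9, n_inlets=8, n_outlets=8),
        numerics=NumericsConfig(n_edge_segments=24, t_final=3.0))


@pytest.fixture(scope="module")
def small_run(small_cfg):
    return transport.simulate(small_cfg)


class TestAssemble:
    def test_zero_ambient_gives_zero_load(self, coarse_mesh, params, table):
        bc = BoundaryData(gamma={c: 1.0 for c in transport.CLASSES},
                          delta={c: 1.0 for c in transport.CLASSES},
                          phi_b={c: 0.0 for c in transport.CLASSES})
        ops = assemble(coarse_mesh, params, bc, None, table)
        assert np.abs(ops.f1).max() == 0.0
        assert np.abs(ops.f2).max() == 0.0

    def test_a1_symmetric_positive(self, coarse_mesh, params, table, rng):
        bc = BoundaryData.from_parameters(params)
        ops = assemble(coarse_mesh, params, bc, None, table)
        asym = np.abs((ops.A1 - ops.A1.T).toarray()).max()
        assert asym < 1e-14
        for _ in range(3):
            u = rng.standard_normal(coarse_mesh.n_vertices)
            assert u @ (ops.A1 @ u) > 0
            assert u @ (ops.A2 @ u) > 0

    def test_a1_constant_energy_is_boundary_measure(self, coarse_mesh,
                                                    params, table):
        # (A1 1, 1) = alpha*0 + int_Gamma gamma dGamma
        gamma = 0.7
        bc = BoundaryData(gamma={c: gamma for c in transport.CLASSES},
                          delta={c: 1.0 for c in transport.CLASSES},
                          phi_b={c: 0.0 for c in transport.CLASSES})
        ops = assemble(coarse_mesh, params, bc, None, table)
        one = np.ones(coarse_mesh.n_vertices)
        expected = gamma * coarse_mesh.boundary_lengths().sum()
        assert one @ (ops.A1 @ one) == pytest.approx(expected, rel=1e-12)

    def test_derived_theta_b_is_inverse_hill_of_phi_b(self, params, table):
        bc = BoundaryData.from_parameters(params)
        tb = bc.derived_theta_b(table)
        assert tb["inlet"] == pytest.approx(0.1584, abs=5e-4)
        assert tb["outlet"] == pytest.approx(0.0755, abs=5e-4)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            BoundaryData(gamma={c: -1.0 for c in transport.CLASSES},
                         delta={c: 1.0 for c in transport.CLASSES},
                         phi_b={c: 0.0 for c in transport.CLASSES})


class TestAdvance:
    def test_uniform_closed_step_matches_ode(self, unit_square_mesh, params,
                                             table, closed_bc):
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        dt = 0.01
        st = StateFields(0.0, np.full(n, 4.0), np.full(n, 0.01), table)
        out = advance(st, ops, table, params, dt, 20)
        ode = ode_reduction(params, 4.0, 0.01, dt, n_out=2)
        # backward-Euler local error is O(dt^2)
        assert abs(out.phi[0] - ode.phi[1]) < 5 * dt ** 2
        assert abs(out.theta[0] - ode.theta[1]) < 5 * dt ** 2
        assert np.ptp(out.phi) < 1e-10  # stays spatially uniform

    def test_monotone_relaxation_toward_ambient(self, unit_square_mesh):
        # negligible exchange/consumption: phi obeys the Robin heat equation
        # and relaxes monotonically toward the ambient value
        p = ModelParameters(a=1e-12, mu0=1e-12)
        tbl = build_inverse_hill(p)
        bc = BoundaryData(gamma={c: p.alpha * 100 for c in transport.CLASSES},
                          delta={c: p.beta * 100 for c in transport.CLASSES},
                          phi_b={c: 8.0 for c in transport.CLASSES})
        ops = assemble(unit_square_mesh, p, bc, None, tbl)
        n = unit_square_mesh.n_vertices
        M = ops.M
        st = StateFields(0.0, np.full(n, 4.0), np.full(n, 0.01), tbl)

        def dist(u):  # L2 distance to the ambient steady state
            e = u - 8.0
            return float(np.sqrt(e @ (M @ e)))

        prev = dist(st.phi)
        for _ in range(30):
            st = advance(st, ops, tbl, p, 0.5, 5)
            d = dist(st.phi)
            assert d <= prev + 1e-12  # backward Euler contracts in L2
            prev = d
        # slow diffusive relaxation, but clearly under way after 15 s
        assert prev < 0.6 * dist(np.full(n, 4.0))
        assert st.phi.min() > 3.9

    def test_twenty_sweeps_reach_tight_increment(self, small_run):
        assert all(r["picard_residual"] < 1e-8
                   for r in small_run.records[1:])

    def test_invalid_arguments(self, unit_square_mesh, params, table,
                               closed_bc):
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        st = StateFields(0.0, np.full(n, 4.0), np.full(n, 0.01), table)
        with pytest.raises(ValueError):
            advance(st, ops, table, params, -0.1)
        with pytest.raises(ValueError):
            advance(st, ops, table, params, 0.1, n_picard=0)


class TestConservation:
    def test_closed_system_budget(self, unit_square_mesh, params, table,
                                  closed_bc):
        """With no flux and no flow, the weighted total sigma*phi+(1-sigma)*theta
        changes only by the consumed amount each step."""
        from oxytrans.kinetics import mm_rate
        ops = assemble(unit_square_mesh, params, closed_bc, None, table)
        n = unit_square_mesh.n_vertices
        M = ops.M
        one = np.ones(n)
        dt = 0.05  # resolves the fast initial depletion of the closed system
        st = StateFields(0.0, np.full(n, 4.0), np.full(n, 0.01), table)
        for _ in range(10):
            new = advance(st, ops, table, params, dt, 40)
            tot0 = one @ (M @ (params.sigma * st.phi
                               + (1 - params.sigma) * st.theta))
            tot1 = one @ (M @ (params.sigma * new.phi
                               + (1 - params.sigma) * new.theta))
            consumed = (1 - params.sigma) * (one @ (M @ mm_rate(new.theta,
                                                                params))) * dt
            assert abs(tot1 - tot0 + consumed) / abs(tot0) <= 1e-4
            assert tot1 < tot0  # total oxygen non-increasing
            st = new


class TestSimulate:
    def test_zero_horizon_keeps_initial_state(self, small_cfg):
        import dataclasses
        cfg = RunConfiguration(
            geometry=small_cfg.geometry,
            numerics=dataclasses.replace(small_cfg.numerics, t_final=0.0))
        res = transport.simulate(cfg)
        assert len(res.states) == 1
        assert res.states[0].phi[0] == 4.0

    def test_deterministic(self, small_cfg, small_run):
        res2 = transport.simulate(small_cfg)
        assert np.array_equal(res2.states[-1].phi, small_run.states[-1].phi)
        assert np.array_equal(res2.states[-1].theta,
                              small_run.states[-1].theta)

    def test_doubling_sweeps_changes_nothing(self, small_cfg, small_run):
        import dataclasses
        cfg = RunConfiguration(
            geometry=small_cfg.geometry,
            numerics=dataclasses.replace(small_cfg.numerics, n_picard=40))
        res2 = transport.simulate(cfg)
        rel = (np.abs(res2.states[-1].phi - small_run.states[-1].phi).max()
               / np.abs(small_run.states[-1].phi).max())
        assert rel < 1e-8

    def test_records_shape_and_monotone_saturation(self, small_run):
        rec = small_run.records_frame()
        assert len(rec) == len(small_run.states)
        # hypoxic tissue recovers: final mean theta well above initial
        assert rec["l2_theta"].iloc[-1] > 5 * rec["l2_theta"].iloc[0]
        assert rec["picard_residual"].iloc[-1] < 1e-10

    def test_psi_field_derived_from_phi(self, small_run, table):
        st = small_run.states[-1]
        from oxytrans.kinetics import inverse_hill_eval
        assert np.allclose(st.psi, inverse_hill_eval(table, st.phi))
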