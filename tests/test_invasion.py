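"""IMEX scheme, invariant monitors and the reduced-ODE oracle."""

import numpy as np
import pytest

from mmpinv.homogenize import DiffusivityLaw
from mmpinv.invasion import (FemContext, ModelParams, SimState, hill_fb,
                             hill_fs, imex_step, invariant_monitor,
                             lower_phi_bound, run_simulation)
from mmpinv.mesh import NodalField
from mmpinv.scenarios import Scenario, ellipse2d, patchy2d, table_params
from mmpinv.unitcell import BoxDomainSpec, build_box_mesh

LAW = DiffusivityLaw(0.25, 0.33, 0.42, 1.29e-2, 2)


def scalar_imex_step(y, p, tau):
    """Independent oracle: the IMEX map of the spatially reduced 4-ODE
    system (for homogeneous fields every FE operator is a mass matrix and
    the implicit diffusion acts as the identity)."""
    phi, cs, b, s = y
    one_s = 1.0 - (s if p.suitability_on else 0.0)
    phi_n = phi - tau * (one_s * p.mu_s * phi * cs + one_s * p.mu_b * phi * b)
    cs_n = cs + tau * (p.kappa_s / (1 + cs) * (1 - phi)
                       - (one_s * p.mu_s * phi + p.beta_s) * cs)
    b_n = b + tau * (p.kappa_b * phi / (1 + phi) * (1 - phi)
                     - (one_s * p.mu_b * phi + p.beta_b) * b)
    s_n = s - tau * p.delta_s * b * s if p.suitability_on else s
    return (phi_n, cs_n, b_n, s_n)


def homogeneous_scenario(y0, params, mesh_size=0.5):
    return Scenario("homogeneous", "both",
                    BoxDomainSpec(2, (-1.0, -1.0), (1.0, 1.0), mesh_size),
                    params,
                    phi0=lambda x: np.full(len(x), y0[0]),
                    cs0=lambda x: np.full(len(x), y0[1]),
                    b0=lambda x: np.full(len(x), y0[2]),
                    s0=lambda x: np.full(len(x), y0[3]))


class TestHill:
    @pytest.mark.parametrize("phi,expected", [(0.0, 0.0), (1.0, 0.5),
                                              (1 / 3, 0.25)])
    def test_fb_values(self, phi, expected):
        assert np.isclose(hill_fb(phi), expected, rtol=1e-14)

    @pytest.mark.parametrize("c,expected", [(0.0, 1.0), (1.0, 0.5)])
    def test_fs_values(self, c, expected):
        assert np.isclose(hill_fs(c), expected, rtol=1e-14)

    def test_fs_monotone_decreasing_to_zero(self):
        c = np.linspace(0, 1e3, 500)
        v = hill_fs(c)
        assert np.all(np.diff(v) < 0) and v[-1] < 1e-2

    def test_fb_range_on_unit_interval(self):
        v = hill_fb(np.linspace(0, 1, 100))
        assert v.min() >= 0 and v.max() <= 0.5


class TestImexStep:
    def test_saturated_state_is_fixed_point(self):
        mesh = build_box_mesh(BoxDomainSpec(2, (-1, -1), (1, 1), 0.5))
        params = table_params().replace(suitability_on=True)
        st = SimState(0.0, NodalField.constant(mesh, 1.0),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.3))
        out = imex_step(st, params, 1e-2, FemContext(mesh))
        for a, b in ((out.phi, st.phi), (out.cs, st.cs), (out.b, st.b),
                     (out.s, st.s)):
            assert np.max(np.abs(a.values - b.values)) < 1e-12

    def test_homogeneous_step_equals_scalar_oracle(self):
        y0 = (0.8, 0.5, 0.2, 0.3)
        params = table_params().replace(suitability_on=True, diffusivity=LAW)
        sc = homogeneous_scenario(y0, params)
        mesh = sc.build_mesh()
        st = sc.initial_state(mesh)
        ctx = FemContext(mesh)
        tau = 1e-2
        y = y0
        for _ in range(5):
            st = imex_step(st, params, tau, ctx)
            y = scalar_imex_step(y, params, tau)
        for f, v in zip((st.phi, st.cs, st.b, st.s), y):
            assert np.max(np.abs(f.values - v)) < 1e-10

    def test_rejects_nonpositive_step(self):
        mesh = build_box_mesh(BoxDomainSpec(2, (-1, -1), (1, 1), 0.5))
        sc = ellipse2d(mesh_size=0.5)
        st = sc.initial_state(mesh)
        with pytest.raises(ValueError):
            imex_step(st, sc.params, 0.0, FemContext(mesh))


class TestOdeOracle:
    def test_first_order_convergence_to_reference(self):
        """Trajectory error against a tau/100 reference integration decays
        at first order in the time step."""
        y0 = (0.9, 0.2, 0.1, 0.4)
        params = table_params().replace(suitability_on=True, diffusivity=LAW)
        T = 1.0
        tau_ref = 1e-2 / 100
        y = y0
        for _ in range(int(round(T / tau_ref))):
            y = scalar_imex_step(y, params, tau_ref)
        ref = np.asarray(y)
        errs = []
        for tau in (4e-2, 2e-2, 1e-2):
            sc = homogeneous_scenario(y0, params)
            traj = run_simulation(sc, T, tau, on_violation="ignore")
            got = np.array([traj.final.phi.values[0], traj.final.cs.values[0],
                            traj.final.b.values[0], traj.final.s.values[0]])
            errs.append(np.max(np.abs(got - ref)))
        orders = np.diff(np.log(errs)) / np.diff(np.log([4e-2, 2e-2, 1e-2]))
        assert np.all(orders >= 0.9)


class TestStructuralProperties:
    def test_mass_conservation_without_reactions(self):
        # all reactions off, zero-flux diffusion: int cs dx is constant
        params = ModelParams(kappa_s=0, kappa_b=0, mu_s=0, mu_b=0,
                             beta_s=0.0, beta_b=0.0, delta_s=0,
                             diffusivity=LAW)
        sc = Scenario("cons", "both",
                      BoxDomainSpec(2, (-1, -1), (1, 1), 0.1), params,
                      phi0=lambda x: 1 - np.exp(-(x ** 2).sum(1)),
                      cs0=lambda x: np.exp(-4 * (x ** 2).sum(1)))
        masses = []

        def obs(state):
            masses.append(state.cs.integral())
            return {}
        run_simulation(sc, T=0.2, tau=2e-2, observers=[obs],
                       on_violation="abort")
        masses = np.asarray(masses)
        assert np.max(np.abs(masses - masses[0])) < 1e-10 * abs(masses[0])

    def test_ecm_and_suitability_decay_monotonically(self):
        sc = patchy2d("both", mesh_size=0.05)
        phis, ss = [], []

        def obs(state):
            phis.append(state.phi.values.copy())
            ss.append(state.s.values.copy())
            return {}
        run_simulation(sc, T=0.5, tau=1e-2, observers=[obs])
        tol = 5e-6  # consistent-mass + explicit-reaction wiggle at tau=1e-2
        for a, b in zip(phis[:-1], phis[1:]):
            assert np.all(b <= a + tol)
        for a, b in zip(ss[:-1], ss[1:]):
            assert np.all(b <= a + tol)
            assert b.min() >= -tol and b.max() <= 1 + tol

    def test_degenerate_diffusivity_is_well_posed(self):
        # phi = 0 at the origin makes D_s vanish there; the implicit solve
        # must stay well-posed (M + tau*A is SPD for PSD A)
        sc = ellipse2d("both", mesh_size=0.25)
        traj = run_simulation(sc, T=0.1, tau=1e-2, on_violation="ignore")
        assert np.all(np.isfinite(traj.final.cs.values))


class TestInvariantMonitor:
    def test_constant_state_no_violations(self):
        mesh = build_box_mesh(BoxDomainSpec(2, (0, 0), (1, 1), 0.5))
        st = SimState(0.0, NodalField.constant(mesh, 0.5),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0))
        rep = invariant_monitor(st, table_params())
        assert rep.ok
        assert rep.extrema["phi"] == (0.5, 0.5)

    def test_exponential_floor_toy_parameters(self):
        p = ModelParams(kappa_s=1, kappa_b=1, mu_s=1, mu_b=1,
                        beta_s=1, beta_b=1, delta_s=1, diffusivity=LAW)
        assert np.isclose(lower_phi_bound(1.0, p, 1.0), np.exp(-2.0),
                          rtol=1e-14)

    def test_default_parameter_bounds(self):
        p = table_params()
        assert p.bound_ms() == 40.0   # kappa_s / beta_s
        assert p.bound_mb() == 50.0   # kappa_b / beta_b

    def test_violation_flagged(self):
        mesh = build_box_mesh(BoxDomainSpec(2, (0, 0), (1, 1), 0.5))
        st = SimState(0.0, NodalField.constant(mesh, 1.5),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0))
        rep = invariant_monitor(st, table_params())
        assert not rep.ok and any("phi" in v for v in rep.violations)

    def test_floor_skipped_for_vanishing_initial_ecm(self):
        mesh = build_box_mesh(BoxDomainSpec(2, (0, 0), (1, 1), 0.5))
        st = SimState(0.0, NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0),
                      NodalField.constant(mesh, 0.0))
        rep = invariant_monitor(st, table_params(), delta0=0.0, T=1.0)
        assert rep.phi_floor is None


class TestRunSimulation:
    def test_zero_final_time_returns_initial_state(self):
        sc = ellipse2d(mesh_size=0.5)
        traj = run_simulation(sc, T=0.0, tau=1e-2)
        assert len(traj.times) == 1 and traj.final.t == 0.0

    def test_non_multiple_final_time_rejected(self):
        sc = ellipse2d(mesh_size=0.5)
        with pytest.raises(ValueError, match="multiple"):
            run_simulation(sc, T=0.05, tau=0.02)

    def test_deterministic_repeatability(self):
        sc = ellipse2d(mesh_size=0.4)
        a = run_simulation(sc, T=0.1, tau=1e-2).final.phi.values
        b = run_simulation(sc, T=0.1, tau=1e-2).final.phi.values
        assert np.array_equal(a, b)
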