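"""Integration, attractor refinement, conservation and stability analysis."""

import math

import numpy as np
import pytest

import kinresp as kr
from kinresp.dynamics import (
    AttractorNotFoundError,
    log_uniform_sampler,
    pool_values,
    project_onto_pools,
)


class CubicBistable:
    """dx/dt = -(x-1)(x-2)(x-3): stable roots at 1 and 3, saddle at 2."""

    n_state = 1

    def rhs(self, x):
        return -(x - 1.0) * (x - 2.0) * (x - 3.0)

    def jac(self, x):
        x = x[0]
        return np.array([[-((x - 2) * (x - 3) + (x - 1) * (x - 3) + (x - 1) * (x - 2))]])


class TestIntegrate:
    def test_exponential_decay_closed_form(self, linear_model_factory):
        model = linear_model_factory(np.array([[-1.0]]), np.array([0.0]))
        traj = kr.integrate(model, np.array([1.0]), horizon=10.0, reltol=1e-9, abstol=1e-12)
        assert traj.converged
        assert traj.x_end[0] == pytest.approx(math.exp(-10.0), rel=1e-6)

    def test_two_species_reaction_reaches_detailed_balance_ratio(self):
        beta, dmu = 10.0, 0.3
        net = kr.ReactionNetwork(
            n_species=2,
            reactions=[kr.Reaction((0,), (1,), v=1.0,
                                   k_plus=math.exp(-beta * dmu), k_minus=1.0,
                                   delta_mu=dmu)],
            exchange=np.zeros(2, dtype=bool),
            external=np.ones(2),
        )
        model = kr.build_model(net, beta)
        st = kr.find_attractor(model, [np.array([1.0, 1.0])])
        # equilibrium: k+ x1 = k- x2  =>  x1/x2 = exp(beta dmu)
        assert st.x_st[0] / st.x_st[1] == pytest.approx(math.exp(beta * dmu), rel=1e-10)

    def test_trajectory_stays_at_the_attractor(self, small_minimal):
        model, st = small_minimal
        traj = kr.relax(model, st.x_st)
        drift = np.abs(np.log(traj.states) - np.log(st.x_st)[:, None]).max()
        assert traj.converged
        assert drift < 1e-5

    def test_failure_is_loud_not_silent(self):
        class ConstantDrift:  # no steady state exists
            n_state = 1
            requires_positive = False

            def rhs(self, x):
                return np.ones(1)

            def jac(self, x):
                return np.zeros((1, 1))

        traj = kr.relax(ConstantDrift(), np.array([1.0]), max_time=10.0)
        assert not traj.converged
        assert "no convergence" in traj.failure_reason


class TestAttractor:
    def test_residual_far_below_flux_scale(self, small_minimal):
        model, st = small_minimal
        assert st.residual < 1e-10 * model.flux_scale(st.x_st)

    def test_idempotent_restart_from_the_attractor(self, small_minimal):
        model, st = small_minimal
        again = kr.find_attractor(model, [st.x_st])
        assert np.max(np.abs(again.x_st - st.x_st)) < 1e-10 * np.max(st.x_st)

    def test_closed_cofactor_free_model_reaches_boltzmann_state(self):
        # detailed balance forces x_n = c * exp(-beta mu_n), c set by mass
        rng = np.random.default_rng(77)
        net = kr.build_backbone(6, 8, rng)
        net.exchange[:] = False
        net = kr.assign_rates(kr.assign_thermodynamics(net, 4.0, rng), rng)
        model = kr.build_model(net)
        x0 = np.ones(6)
        st = kr.find_attractor(model, [x0])
        w = np.exp(-4.0 * net.mu)
        expected = w * (x0.sum() / w.sum())
        assert np.allclose(st.x_st, expected, rtol=1e-8)
        assert (np.abs(model.fluxes(st.x_st)) / model.v).max() < 1e-12

    def test_empty_initial_set_is_an_error(self, small_minimal):
        with pytest.raises(AttractorNotFoundError):
            kr.find_attractor(small_minimal[0], [])


class TestConservedPools:
    def test_pool_vectors_annihilate_stoichiometry_exactly(self, small_minimal):
        model, _ = small_minimal
        pools = kr.conserved_pools(model)
        assert len(pools) >= 1
        S = model.S.astype(int)
        assert not (pools @ S).any()  # exact integer arithmetic
        # exchanged species never carry pool weight
        assert not pools[:, model.exchange].any()

    def test_cofactor_total_is_in_the_span(self, small_minimal):
        model, _ = small_minimal
        pools = kr.conserved_pools(model)
        n = model.network.n_species
        cof = np.zeros(model.n_state)
        cof[n:] = 1
        stacked = np.vstack([pools, cof])
        assert np.linalg.matrix_rank(stacked) == np.linalg.matrix_rank(pools)

    def test_full_exchange_breaks_all_conservation(self, rng):
        net = kr.build_backbone(6, 8, rng)
        net.exchange[:] = True
        net = kr.assign_rates(kr.assign_thermodynamics(net, 10.0, rng), rng)
        assert len(kr.conserved_pools(kr.build_model(net))) == 0

    def test_projection_restores_targets_for_signed_overlapping_pools(self, rng):
        pools = np.array([[1, 1, -1, 0], [0, 1, 1, 2]])
        x_ref = rng.uniform(0.5, 2.0, 4)
        target = pools @ x_ref
        x = x_ref * rng.uniform(0.6, 1.4, 4)
        proj = project_onto_pools(x, pools, target)
        assert np.all(proj > 0)
        assert np.allclose(pools @ proj, target, rtol=1e-12, atol=1e-12)

    def test_pool_values_constant_along_response_trajectory(self, small_minimal):
        model, st = small_minimal
        x0 = kr.perturb_state(st.x_st, 0.4, st.pool_matrix, np.random.default_rng(5))
        traj = kr.relax(model, x0)
        vals = st.pool_matrix @ traj.states
        ref = pool_values(st.pool_matrix, x0)
        rel_drift = np.abs(vals - ref[:, None]).max() / np.abs(ref).max()
        assert rel_drift < 1e-6


class TestMultistability:
    def test_monostable_system_reports_single_attractor(self, linear_model_factory):
        model = linear_model_factory(-np.eye(2), np.array([1.0, 2.0]))
        model.requires_positive = True
        screen = kr.screen_multistability(
            model, n_init=8, rng=np.random.default_rng(0),
            sampler=log_uniform_sampler(0.1, 10.0),
        )
        assert screen.single_attractor
        assert screen.n_failed == 0
        assert np.allclose(screen.attractors[0], [1.0, 2.0], atol=1e-6)

    def test_bistable_fixture_reports_both_roots(self):
        model = CubicBistable()
        # oracle: the positive stable roots of the cubic
        roots = np.sort(np.roots([-1, 6, -11, 6]))  # 1, 2, 3
        x0_set = [np.array([v]) for v in (0.5, 1.4, 2.6, 3.8)]
        screen = kr.screen_multistability(model, x0_set=x0_set)
        assert not screen.single_attractor
        found = np.sort([a[0] for a in screen.attractors])
        assert np.allclose(found, [roots[0], roots[2]], atol=1e-6)

    def test_default_sampler_covers_the_documented_range(self):
        sampler = log_uniform_sampler()
        draws = np.concatenate([sampler(np.random.default_rng(i), 50) for i in range(20)])
        assert draws.min() >= 1e-3 and draws.max() <= 1e3
        assert draws.min() < 1e-2 and draws.max() > 1e2  # actually spans it


class TestLinearize:
    def test_scalar_decay(self, linear_model_factory):
        model = linear_model_factory(np.array([[-1.0]]), np.array([0.0]))
        J, lin = kr.linearize(model, np.array([0.5]))
        assert J[0, 0] == -1.0
        assert lin.rhs(np.array([0.7]))[0] == pytest.approx(-0.2)

    def test_analytic_jacobian_matches_finite_differences(self, small_minimal):
        model, st = small_minimal
        J = model.jac(st.x_st)
        eps = 1e-6
        f0 = model.rhs(st.x_st)
        for i in range(model.n_state):
            xp = st.x_st.copy()
            h = eps * max(xp[i], 1e-3)
            xp[i] += h
            col = (model.rhs(xp) - f0) / h
            mask = np.abs(J[:, i]) > 1e-8 * np.abs(J).max()
            assert np.allclose(col[mask], J[mask, i], rtol=1e-4)

    def test_certified_attractor_is_linearly_stable(self, small_minimal):
        model, st = small_minimal
        assert st.stable
        max_re, scale = kr.max_real_eigenvalue(model, st.x_st, st.pool_matrix)
        assert max_re < 1e-8 * max(scale, 1.0)
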