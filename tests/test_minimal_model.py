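"""Generator invariants: backbone topology, cofactor coupling, thermodynamics."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import kinresp as kr
from kinresp.minimal_model import LOG10_RATE_RANGE, ParameterError
from kinresp.util import round_half_away


def backbone_graph(net):
    g = nx.Graph()
    g.add_nodes_from(range(net.n_species))
    g.add_edges_from(r.backbone_pair for r in net.reactions)
    return g


class TestBackbone:
    def test_minimum_network_is_exchanged_chain(self, rng):
        net = kr.build_backbone(2, 1, rng)
        assert [r.backbone_pair for r in net.reactions] == [(0, 1)]
        assert net.exchange.tolist() == [True, True]
        assert net.external[0] == 100.0 and net.external[1] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_tree_case_is_exactly_the_path(self, seed):
        # with zero extra reactions the only 3-edge connected graph on 4
        # nodes produced is the chain 1-2-3-4 (exhaustive over seeds)
        net = kr.build_backbone(4, 3, np.random.default_rng(seed))
        assert sorted(r.backbone_pair for r in net.reactions) == [(0, 1), (1, 2), (2, 3)]

    def test_reference_size_counts_and_connectivity(self, rng):
        net = kr.build_backbone(64, 96, rng)
        assert net.n_reactions == 96
        chain = [r.backbone_pair for r in net.reactions[:63]]
        assert chain == [(i, i + 1) for i in range(63)]
        assert nx.is_connected(backbone_graph(net))
        # no duplicate pairs, no self-loops
        pairs = [tuple(sorted(r.backbone_pair)) for r in net.reactions]
        assert len(set(pairs)) == 96
        assert all(a != b for a, b in pairs)
        # exchange on Round(0.05*64)=3 species including both endpoints
        assert net.exchange.sum() == 3
        assert net.exchange[0] and net.exchange[63]
        assert net.external[0] == 100.0
        assert np.all(net.external[1:] == 1.0)

    def test_infeasible_reaction_counts_raise(self, rng):
        with pytest.raises(ParameterError):
            kr.build_backbone(5, 3, rng)  # below N-1
        with pytest.raises(ParameterError):
            kr.build_backbone(5, 11, rng)  # above C(5,2)=10


class TestCofactorCoupling:
    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("n_reactions", [63, 96, 128])
    def test_coupled_count_is_round_fr(self, f, n_reactions, rng):
        net = kr.build_backbone(40, n_reactions, rng)
        net = kr.couple_cofactors(net, f, rng)
        n_coupled = sum(r.cofactor_pair is not None for r in net.reactions)
        assert n_coupled == round_half_away(f * n_reactions)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.5 * 63) == 32  # 31.5 -> 32, deterministically
        assert round_half_away(-31.5) == -32

    def test_coupled_forms_distinct_and_not_backbone(self, rng):
        net = kr.couple_cofactors(kr.build_backbone(10, 14, rng), 1.0, rng)
        for r in net.reactions:
            frm, to = r.cofactor_pair
            assert frm != to
            assert r.substrates[1] == 10 + frm and r.products[1] == 10 + to
            assert r.substrates[0] < 10 and r.products[0] < 10
        assert not net.exchange[10:].any()  # cofactors carry no exchange

    def test_invalid_fraction_rejected(self, rng):
        net = kr.build_backbone(6, 6, rng)
        with pytest.raises(ParameterError):
            kr.couple_cofactors(net, 1.5, rng)


class TestThermodynamics:
    def test_detailed_balance_and_min_rule(self, rng):
        net = kr.couple_cofactors(kr.build_backbone(20, 30, rng), 0.5, rng)
        beta = 10.0
        net = kr.assign_thermodynamics(net, beta, rng)
        assert np.allclose(net.mu[20:], [1.0, 0.5, 0.0])
        for r in net.reactions:
            assert max(r.k_plus, r.k_minus) == 1.0
            assert r.k_plus == min(1.0, math.exp(-beta * r.delta_mu))
            assert r.k_minus == min(1.0, math.exp(beta * r.delta_mu))
            # detailed balance to machine precision
            assert r.k_plus / r.k_minus == pytest.approx(
                math.exp(-beta * r.delta_mu), rel=1e-14
            )
            dmu = net.mu[list(r.products)].sum() - net.mu[list(r.substrates)].sum()
            assert r.delta_mu == pytest.approx(dmu, abs=1e-15)

    def test_known_irreversibility_values(self):
        # beta=10, dmu=0.3: uphill direction carries exp(-3), downhill is 1
        beta, dmu = 10.0, 0.3
        k_plus = min(1.0, math.exp(-beta * dmu))
        assert k_plus == pytest.approx(0.049787, rel=1e-4)
        # a zero potential difference makes the reaction fully reversible
        assert min(1.0, math.exp(-beta * 0.0)) == 1.0

    def test_sup_delta_mu_cofactor_and_catalytic(self):
        assert kr.sup_delta_mu(kr.CofactorSpec()) == 2.0
        assert kr.sup_delta_mu(None) == 1.0


class TestRates:
    def test_rates_within_documented_range(self, rng):
        net = kr.assign_rates(kr.build_backbone(30, 60, rng), rng)
        logs = np.log10([r.v for r in net.reactions])
        assert logs.min() >= LOG10_RATE_RANGE[0]
        assert logs.max() <= LOG10_RATE_RANGE[1]

    def test_log_rate_distribution_uniform(self):
        rng = np.random.default_rng(7)
        lo, hi = LOG10_RATE_RANGE
        u = rng.uniform(lo, hi, size=100_000)  # same sampler the builder uses
        stat = kstest((u - lo) / (hi - lo), "uniform")
        assert stat.pvalue > 0.01


class TestModelAssembly:
    def test_stoichiometry_mass_balance(self, small_minimal):
        model, _ = small_minimal
        n = model.network.n_species
        for j, r in enumerate(model.network.reactions):
            col = model.S[:, j]
            assert col[:n].sum() == 0  # backbone mass balance
            if r.cofactor_pair is not None:
                cof = col[n:]
                assert sorted(cof.tolist()) == [-1.0, 0.0, 1.0]
            else:
                assert not col[n:].any()

    def test_symmetric_two_species_equilibrium(self):
        net = kr.ReactionNetwork(
            n_species=2,
            reactions=[kr.Reaction((0,), (1,), v=1.0, k_plus=1.0, k_minus=1.0, delta_mu=0.0)],
            exchange=np.zeros(2, dtype=bool),
            external=np.ones(2),
        )
        model = kr.build_model(net, beta=1.0)
        assert np.allclose(model.rhs(np.array([1.0, 1.0])), 0.0)

    def test_cofactor_pool_total_conserved_along_trajectory(self, small_minimal):
        model, st = small_minimal
        pool = model.network.n_species
        x0 = kr.perturb_state(st.x_st, 0.4, st.pool_matrix, np.random.default_rng(0))
        traj = kr.relax(model, x0)
        totals = traj.states[pool:].sum(axis=0)
        assert traj.converged
        assert np.abs(totals - 1.0).max() < 1e-6  # unit cofactor total

    def test_numba_and_numpy_paths_agree(self, small_minimal, rng):
        model, st = small_minimal
        x = st.x_st * rng.uniform(0.5, 1.5, model.n_state)
        assert np.allclose(model.rhs(x), model._rhs_numpy(x), rtol=1e-13, atol=0)
        assert np.allclose(model.jac(x), model._jac_numpy(x), rtol=1e-12, atol=1e-12)

    def test_unparameterized_reaction_rejected(self, rng):
        net = kr.build_backbone(4, 4, rng)  # no rates assigned
        with pytest.raises(ParameterError):
            kr.build_model(net, beta=10.0)


class TestCatalyticVariant:
    def test_catalyst_row_of_stoichiometry_is_zero(self):
        model = kr.build_catalytic_variant(10, 14, 20.0, np.random.default_rng(3))
        for j, r in enumerate(model.network.reactions):
            assert r.catalyst is not None
            a, b = r.backbone_pair
            if r.catalyst not in (a, b):
                assert model.S[r.catalyst, j] == 0
        assert model.network.cofactor is None

    def test_zero_catalyst_concentration_silences_its_reactions(self):
        model = kr.build_catalytic_variant(8, 10, 20.0, np.random.default_rng(5))
        x = np.ones(8)
        cat = model.network.reactions[0].catalyst
        x[cat] = 0.0
        J = model.fluxes(x)
        for j, r in enumerate(model.network.reactions):
            if r.catalyst == cat:
                assert J[j] == 0.0

    def test_delta_mu_bounded_by_one(self):
        model = kr.build_catalytic_variant(30, 60, 20.0, np.random.default_rng(9))
        dmus = np.abs([r.delta_mu for r in model.network.reactions])
        assert dmus.max() <= kr.sup_delta_mu(None)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(4, 12),
    extra=st.integers(0, 8),
    f=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_generator_invariants_hold_for_random_parameters(n, extra, f, seed):
    """Connectivity, coupling count, detailed balance and mass balance hold
    across the generator's whole parameter range."""
    r_total = min(n - 1 + extra, n * (n - 1) // 2)
    rng = np.random.default_rng(seed)
    net = kr.build_backbone(n, r_total, rng)
    assert nx.is_connected(backbone_graph(net))
    net = kr.couple_cofactors(net, f, rng)
    assert sum(r.cofactor_pair is not None for r in net.reactions) == round_half_away(
        f * r_total
    )
    net = kr.assign_rates(kr.assign_thermodynamics(net, 10.0, rng), rng)
    model = kr.build_model(net)
    assert model.S[:n].sum(axis=0).tolist() == [0] * r_total
    for r in net.reactions:
        assert r.k_plus / r.k_minus == pytest.approx(math.exp(-10.0 * r.delta_mu), rel=1e-13)
    assert net.exchange[0] and net.exchange[n - 1]
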