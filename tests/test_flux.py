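"""FBA/FVA constraint system, essentiality and flux-based PEM classes."""

import dataclasses

import pytest

from pemnet import (
    build_network,
    essential_reactions,
    fva,
    make_fixture,
    max_flux,
    optimal_efficiency_pems,
    producibility_pems,
    stoichiometrically_activated,
    TargetInactiveError,
    TargetSpec,
)
from conftest import ALL_FIXTURES, cobra_max_flux, vertex_enumeration_max


def _without_supply(net, rid):
    rxns = dict(net.reactions)
    rxns[rid] = dataclasses.replace(rxns[rid], upper_bound=0.0)
    return dataclasses.replace(net, reactions=rxns)


def _scaled(net, lam):
    rxns = {
        rid: dataclasses.replace(r, upper_bound=r.upper_bound * lam)
        for rid, r in net.reactions.items()
    }
    return dataclasses.replace(net, reactions=rxns)


class TestMaxFlux:
    def test_chain_optimum_is_bottleneck(self):
        net = build_network(
            {
                "r_in": ({}, {"A": 1}, 5.0),
                "r_mid": ({"A": 1}, {"B": 1}, 3.0),
                "r_T": ({"B": 1}, {}, 10.0),
            },
            target_id="r_T",
        )
        res = max_flux(net, "r_T")
        assert res.optimal
        assert res.objective_value == pytest.approx(3.0)

    def test_fig1_target_active_with_all_seeds(self, fig1):
        res = max_flux(fig1.network, "r_T")
        assert res.optimal and res.objective_value > 0

    def test_fig1_no_s2_kills_cycle(self, fig1):
        """Shutting the S2 supply forces v7 = v8 = 0 and zero target flux."""
        net0 = _without_supply(fig1.network, "r_S2")
        assert max_flux(net0, "r_T").objective_value == pytest.approx(0.0, abs=1e-9)
        for rid in ("r7", "r8"):
            iv = fva(net0, rid)
            assert iv.max_v == pytest.approx(0.0, abs=1e-9)

    def test_fixed_flux_out_of_bounds_rejected(self, fig1):
        with pytest.raises(ValueError):
            max_flux(fig1.network, "r_T", fixed={"r6": 99.0})

    def test_mass_conservation_residual(self, fig1):
        res = max_flux(fig1.network, "r_T")
        for mid in fig1.network.metabolites:
            net_rate = 0.0
            for rid, r in fig1.network.reactions.items():
                net_rate += float(r.products.get(mid, 0)) * res.fluxes[rid]
                net_rate -= float(r.reactants.get(mid, 0)) * res.fluxes[rid]
            assert abs(net_rate) <= 1e-6


class TestStoichiometricActivation:
    def test_dead_input_inactive(self):
        # r consumes X which nothing produces
        net = build_network(
            {"r": ({"X": 1}, {"Y": 1}), "exp": ({"Y": 1}, {})}, target_id="r"
        )
        assert not stoichiometrically_activated(net, "r")

    def test_zero_bound_boundary_inactive(self):
        net = build_network({"r_in": ({}, {"A": 1}, 0.0), "r": ({"A": 1}, {})})
        assert not stoichiometrically_activated(net, "r_in")

    def test_fig1_all_reactions_active_with_full_seeds(self, fig1):
        for rid in fig1.network.reactions:
            assert stoichiometrically_activated(fig1.network, rid), rid


class TestProducibilityPems:
    def test_fig2_members(self, fig2):
        pems = producibility_pems(fig2.network, fig2.seeds, fig2.target)
        assert pems == {"E", "G"}

    def test_coproduct_accumulation_is_lethal(self):
        fx = make_fixture("fig8_motif")
        pems = producibility_pems(fx.network, fx.seeds, fx.target)
        assert "dala" in pems

    def test_seeds_never_pems(self, fig2):
        pems = producibility_pems(fig2.network, fig2.seeds, fig2.target)
        assert not pems & fig2.seeds.seeds

    def test_inactive_target_raises(self, fig1):
        net0 = _without_supply(_without_supply(fig1.network, "r_S1"), "r_S2")
        with pytest.raises(TargetInactiveError):
            producibility_pems(net0, fig1.seeds, fig1.target)


class TestEssentialReactions:
    def test_fig2_consumer_of_E_essential(self, fig2):
        ess = essential_reactions(fig2.network, fig2.target)
        assert "r2" in ess
        assert ess == {"r_S", "r0", "r2", "r9", "r_T"}

    def test_fig2_bound_asymmetry_adds_r1_r8(self, fig2, fig2_bounds):
        base = essential_reactions(fig2.network, fig2.target)
        asym = essential_reactions(fig2_bounds.network, fig2_bounds.target)
        assert {"r1", "r8"} & base == set()
        assert {"r1", "r8"} <= asym

    def test_zero_flux_reaction_never_essential(self, fig1):
        # the initiation pathway of fig6 carries zero flux at steady state
        fx = make_fixture("fig6_motif")
        ess = essential_reactions(fx.network, fx.target)
        assert not any(rid.startswith("p") for rid in ess)

    def test_reversible_pair_knocked_jointly(self, fig1):
        ess = essential_reactions(fig1.network, fig1.target)
        assert ("r0" in ess) == ("r1" in ess)


class TestOptimalEfficiencyPems:
    def test_fig2_regions(self, fig2):
        oe = optimal_efficiency_pems(fig2.network, fig2.target)
        assert {"E", "G"} <= oe
        assert "B" not in oe

    def test_fig5_motif_members(self):
        fx = make_fixture("fig5")
        oe = optimal_efficiency_pems(fx.network, fx.target)
        assert {"agm", "urea"} <= oe

    def test_empty_when_target_unboundable(self):
        net = build_network(
            {"r": ({"X": 1}, {"Y": 1}), "r_T": ({"Y": 1}, {})}, target_id="r_T"
        )
        assert optimal_efficiency_pems(net, TargetSpec.from_network(net)) == frozenset()


class TestFva:
    def test_zero_bound_interval(self, fig1):
        net0 = _without_supply(fig1.network, "r_S2")
        iv = fva(net0, "r_S2")
        assert (iv.min_v, iv.max_v) == (0.0, 0.0)

    def test_essential_reaction_min_positive_at_optimum(self, fig2):
        # the only consumer of E must carry flux in every optimal distribution
        iv = fva(fig2.network, "r2", at_optimum=True)
        assert iv.min_v > 1e-6

    def test_interval_ordering_and_bounds(self, fig2):
        for rid, r in fig2.network.reactions.items():
            iv = fva(fig2.network, rid, at_optimum=False)
            assert 0.0 <= iv.min_v <= iv.max_v <= r.upper_bound + 1e-9


@pytest.mark.parametrize("name", ALL_FIXTURES)
def test_knockout_essentiality_equals_fva_at_optimum(name):
    """The two characterizations of optimal-flux essentiality agree:
    knockout lowers the optimum iff the flux is pinned positive at optimum."""
    fx = make_fixture(name)
    net = fx.network
    ess = essential_reactions(net, fx.target)
    for rep, partner in net.reversible_pairs():
        mins = [fva(net, rep, at_optimum=True).min_v]
        if partner is not None:
            mins.append(fva(net, partner, at_optimum=True).min_v)
        assert (rep in ess) == (max(mins) > 1e-6), rep


@pytest.mark.parametrize("name", ALL_FIXTURES)
def test_optimum_matches_cobra(name):
    """Independent FBA cross-check of the target optimum on every fixture."""
    fx = make_fixture(name)
    mine = max_flux(fx.network, fx.network.target_reaction_id)
    theirs = cobra_max_flux(fx.network, fx.network.target_reaction_id)
    assert mine.optimal
    assert mine.objective_value == pytest.approx(theirs, abs=1e-6)


@pytest.mark.parametrize("seed", range(8))
def test_optimum_matches_vertex_enumeration(seed):
    """LP optimum equals the vertex-enumeration oracle on tiny networks
    with small integer bounds."""
    fx = make_fixture("random_small", seed=seed, n_metabolites=4, n_reactions=4)
    rxns = {
        rid: dataclasses.replace(r, upper_bound=float(1 + (seed + i) % 3))
        for i, (rid, r) in enumerate(sorted(fx.network.reactions.items()))
    }
    net = dataclasses.replace(fx.network, reactions=rxns)
    mine = max_flux(net, net.target_reaction_id).objective_value
    oracle = vertex_enumeration_max(net, net.target_reaction_id)
    assert mine == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize("name", ["fig1", "fig2_bounds", "fig5"])
@pytest.mark.parametrize("lam", [0.25, 3.0])
def test_scale_invariance_of_pem_sets(name, lam):
    """Rescaling all upper bounds rescales the optimum and leaves every
    PEM set unchanged."""
    fx = make_fixture(name)
    net, scaled = fx.network, _scaled(make_fixture(name).network, lam)
    mu = max_flux(net, net.target_reaction_id).objective_value
    mu_s = max_flux(scaled, net.target_reaction_id).objective_value
    assert mu_s == pytest.approx(lam * mu, rel=1e-9)
    assert producibility_pems(net, fx.seeds, fx.target) == producibility_pems(
        scaled, fx.seeds, fx.target
    )
    assert optimal_efficiency_pems(net, fx.target) == optimal_efficiency_pems(
        scaled, fx.target
    )


def test_single_reaction_prune_matches_knockout(fig2):
    """When pruning removes exactly one reaction, producibility of the
    metabolite coincides with lethality of that reaction's knockout."""
    net, target = fig2.network, fig2.target
    mu = max_flux(net, "r_T").objective_value
    pems = producibility_pems(net, fig2.seeds, target)
    for mid in ["G", "B", "P"]:  # each consumed by exactly one reaction
        (only,) = net.consumers(mid)
        ko = max_flux(net, "r_T", fixed={only.id: 0.0}).objective_value
        assert (mid in pems) == (ko <= 1e-6), mid
    assert mu > 0
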