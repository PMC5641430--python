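"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately re-derive results along a different path from the
implementation: a naive repeat-until-stable scope, a per-candidate
brute-force sustainability enumeration, a vertex-enumeration LP maximum,
and a cobra-built FBA model.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import pemnet
from pemnet import StoichiometricNetwork, build_network, make_fixture

ALL_FIXTURES = [
    "fig1", "fig2", "fig2_bounds", "fig4", "fig5",
    "fig6_motif", "fig7_motif", "fig8_motif", "chain_n",
]


@pytest.fixture(scope="session")
def fig1():
    return make_fixture("fig1")


@pytest.fixture(scope="session")
def fig2():
    return make_fixture("fig2")


@pytest.fixture(scope="session")
def fig2_bounds():
    return make_fixture("fig2_bounds")


# ---------------------------------------------------------------------------
# oracle: naive scope, recomputed from scratch each pass

def naive_scope(net: StoichiometricNetwork, seeds) -> frozenset[str]:
    reached = set(seeds)
    changed = True
    while changed:
        changed = False
        for r in net.reactions.values():
            if not r.reactants:
                continue
            if set(r.reactants) <= reached and not set(r.products) <= reached:
                reached |= set(r.products)
                changed = True
    return frozenset(reached)


def brute_sustainability(net, seeds, target) -> frozenset[str]:
    """Per-candidate recomputation over every metabolite of the network."""
    rT = net.reaction(target.target_reaction_id)
    base = naive_scope(net, seeds.seeds)
    assert set(rT.reactants) <= base
    out = set()
    for mid in net.metabolites:
        if mid in seeds.seeds or mid in target.targeted_metabolites:
            continue
        pruned = net.prune(mid)
        if not set(rT.reactants) <= naive_scope(pruned, seeds.seeds):
            out.add(mid)
    return frozenset(out)


# ---------------------------------------------------------------------------
# oracle: LP maximum by vertex enumeration of {A v = 0, 0 <= v <= ub}

def vertex_enumeration_max(net: StoichiometricNetwork, objective: str, tol=1e-9):
    rids = sorted(net.reactions)
    mids = [m for m in sorted(net.metabolites) if m not in net.balance_exempt]
    n = len(rids)
    a = np.zeros((len(mids), n))
    for j, rid in enumerate(rids):
        r = net.reactions[rid]
        for m, c in r.products.items():
            if m in mids:
                a[mids.index(m), j] += float(c)
        for m, c in r.reactants.items():
            if m in mids:
                a[mids.index(m), j] -= float(c)
    ubs = np.array([float(net.reactions[rid].upper_bound) for rid in rids])
    rank = np.linalg.matrix_rank(a) if mids else 0
    k = n - rank
    jo = rids.index(objective)
    best = None
    for fixed_idx in itertools.combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for vals in itertools.product(*[(0.0, ubs[j]) for j in fixed_idx]):
            v = np.zeros(n)
            for j, val in zip(fixed_idx, vals):
                v[j] = val
            if free_idx:
                rhs = -a[:, list(fixed_idx)] @ np.array(vals) if fixed_idx else np.zeros(len(mids))
                sub = a[:, free_idx]
                sol, *_ = np.linalg.lstsq(sub, rhs, rcond=None)
                v[free_idx] = sol
            if np.any(v < -tol) or np.any(v > ubs + tol):
                continue
            if mids and np.max(np.abs(a @ v)) > 1e-6:
                continue
            if best is None or v[jo] > best:
                best = v[jo]
    return 0.0 if best is None else max(0.0, float(best))


# ---------------------------------------------------------------------------
# oracle: cobra FBA on the same constraint system

def cobra_max_flux(net: StoichiometricNetwork, objective: str) -> float:
    import cobra

    model = cobra.Model("oracle")
    mets = {
        mid: cobra.Metabolite(mid, compartment=net.metabolites[mid].compartment or "c")
        for mid in net.metabolites
        if mid not in net.balance_exempt
    }
    rxns = []
    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        rx = cobra.Reaction(rid)
        rx.lower_bound, rx.upper_bound = 0.0, float(r.upper_bound)
        coeffs = {}
        for m, c in r.reactants.items():
            if m in mets:
                coeffs[mets[m]] = coeffs.get(mets[m], 0.0) - float(c)
        for m, c in r.products.items():
            if m in mets:
                coeffs[mets[m]] = coeffs.get(mets[m], 0.0) + float(c)
        rx.add_metabolites(coeffs)
        rxns.append(rx)
    model.add_reactions(rxns)
    model.objective = objective
    sol = model.optimize()
    if sol.status != "optimal":
        return 0.0
    return float(sol.objective_value)


# ---------------------------------------------------------------------------
# exhaustively generated tiny networks over a fixed reaction pool

_POOL = {
    "p_sa": ({"S": 1}, {"A": 1}),
    "p_sb": ({"S": 1}, {"B": 1}),
    "p_ab": ({"A": 1}, {"B": 1}),
    "p_ba": ({"B": 1}, {"A": 1}),
    "p_ac": ({"A": 1}, {"C": 1}),
    "p_bc": ({"B": 1}, {"C": 1}),
    "p_abc": ({"A": 1, "B": 1}, {"C": 2}),
    "p_ca": ({"C": 1}, {"A": 1}),
    "p_cb2": ({"C": 2}, {"B": 1}),
}


def tiny_networks(max_extra: int = 4):
    """All networks made of r_S, r_T plus <= max_extra pool reactions.

    Every network has <= 6 reactions; the pool covers branching, joint
    (two-reactant) consumption, cycles and non-unit stoichiometry.
    """
    pool = sorted(_POOL)
    for k in range(max_extra + 1):
        for combo in itertools.combinations(pool, k):
            rxns = {"r_S": ({}, {"S": 1}), "r_T": ({"C": 1}, {})}
            for rid in combo:
                rxns[rid] = _POOL[rid]
            net = build_network(rxns, target_id="r_T")
            yield net


def seed_set_of(net) -> pemnet.SeedSet:
    return pemnet.derive_seed_set(net)
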