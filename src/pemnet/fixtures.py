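"""Programmatic toy networks used for testing and demonstration.

Each named fixture is a small stoichiometric network with designated seeds
and target reaction, built deterministically.  ``fig1`` and ``fig2``
realize the two pedagogical networks the classification is usually
explained on; the ``fig4``–``fig8`` fixtures are *motif* networks that
encode, in minimal form, the mechanisms behind each Venn region of the
classification (alternative pathway pairs, co-product coupling, initiation
pathway feeding a self-activated cycle, seed-disconnected internal cycle,
dual co-product export).  They are labelled motifs: minimal mechanisms,
not excerpts of any genome-scale model.

All fixtures use a default flux upper bound of 10 (arbitrary flux units);
deviations are stoichiometric, not bound asymmetries, except where a
variant exists precisely to demonstrate a bound effect (``fig2_bounds``).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    SeedSet,
    StoichiometricNetwork,
    TargetSpec,
    build_network,
    derive_seed_set,
)

FIXTURE_NAMES = (
    "fig1",
    "fig2",
    "fig2_bounds",
    "fig4",
    "fig5",
    "fig6_motif",
    "fig7_motif",
    "fig8_motif",
    "chain_n",
    "random_small",
)


@dataclass(frozen=True)
class Fixture:
    name: str
    network: StoichiometricNetwork
    seeds: SeedSet
    target: TargetSpec
    description: str = ""


def _fixture(name: str, net: StoichiometricNetwork, description: str) -> Fixture:
    return Fixture(
        name=name,
        network=net,
        seeds=derive_seed_set(net),
        target=TargetSpec.from_network(net),
        description=description,
    )


def _fig1() -> StoichiometricNetwork:
    """Bipartite toy network with boundary seeds {S1, S2, H}.

    Two branches: S1 -> A + G -> F (exported by r_e) and an S2/H-driven
    cycle (r2, r3, r4) whose 2C stoichiometry on r4 feeds the extra C the
    target consumes; r2's H input / J output keeps the cycle mass-
    conserving; r0/r1 form a reversible B <-> S2 pair, and r7/r8 couple B
    and S2 to the cycle so that mass balance forces v7 = v8 = 0 whenever
    the S2 supply is shut.
    """
    return build_network(
        reactions={
            "r_S1": ({}, {"S1": 1}),
            "r_S2": ({}, {"S2": 1}),
            "r_H": ({}, {"H": 1}),
            "r0": ({"S2": 1}, {"B": 1}),
            "r1": ({"B": 1}, {"S2": 1}),
            "r2": ({"C": 1, "H": 1}, {"D": 1, "J": 1}),
            "r3": ({"D": 1}, {"E": 1}),
            "r4": ({"E": 1}, {"C": 2}),
            "r6": ({"S1": 1}, {"A": 1, "G": 1}),
            "r7": ({"B": 1}, {"D": 1}),
            "r8": ({"S2": 1, "J": 1}, {"E": 1}),
            "r9": ({"G": 1}, {"F": 1}),
            "r_T": ({"A": 1, "C": 1}, {}),
            "r_e": ({"F": 1}, {}),
        },
        target_id="r_T",
        reverse_pairs=[("r0", "r1")],
    )


def _fig2(bounds_variant: bool = False) -> StoichiometricNetwork:
    """PEM showcase network: E is SPO, G is PO, B is O under bound asymmetry.

    Single entry S -> E; E feeds two routes to the precursor pool: through
    A (r2) and a stoichiometrically lossy bypass 2E -> P (r4).  Both
    C-producing reactions (r6 and r7) co-produce G, whose only consumer is
    the export r9 — so pruning G blocks all target flux (producibility)
    while leaving the graph scope intact.  In the ``fig2_bounds`` variant
    the direct route r7 is capped (ub 1) so the optimum must run through
    r1/r8, making them essential and B an optimal-efficiency-PEM.
    """
    ub_r7 = 1.0 if bounds_variant else 10.0
    return build_network(
        reactions={
            "r_S": ({}, {"S": 1}),
            "r0": ({"S": 1}, {"E": 1}),
            "r2": ({"E": 1}, {"A": 1}),
            "r4": ({"E": 2}, {"P": 1}),
            "r1": ({"A": 1}, {"B": 1}),
            "r8": ({"B": 1}, {"P": 1}),
            "r6": ({"P": 1}, {"C": 1, "G": 1}),
            "r7": ({"A": 1}, {"C": 1, "G": 1}, ub_r7),
            "r9": ({"G": 1}, {}),
            "r_T": ({"C": 1}, {}),
        },
        target_id="r_T",
    )


def _fig4() -> StoichiometricNetwork:
    """Network-redundancy motif: beta-g6p is SP but not O.

    Two alternative single reactions consume bg6p (towards ag6p or bg1p);
    either alone sustains optimal production of the glycogen target, so
    neither is essential, but pruning bg6p removes both at once.
    """
    return build_network(
        reactions={
            "r_S": ({}, {"bf6p": 1}),
            "r0": ({"bf6p": 1}, {"bg6p": 1}),
            "r1": ({"bg6p": 1}, {"ag6p": 1}),
            "r2": ({"bg6p": 1}, {"bg1p": 1}),
            "r3": ({"ag6p": 1}, {"g1p": 1}),
            "r4": ({"bg1p": 1}, {"g1p": 1}),
            "r5": ({"g1p": 1}, {"glycogen": 1}),
            "r_T": ({"glycogen": 1}, {}),
        },
        target_id="r_T",
    )


def _fig5() -> StoichiometricNetwork:
    """Optimal-pathway-choice motif: agmatine and urea are O-only.

    Putrescine for the target can be imported directly, but the internal
    arginine pathway additionally yields the ammonia the target also
    needs (via urea hydrolysis); the direct ammonia supply is scarce
    (ub 1), so the internal pathway carries the optimum and its reactions
    are essential, although neither graph-based nor steady-state
    producibility depends on it.
    """
    return build_network(
        reactions={
            "r_S_arg": ({}, {"arg": 1}),
            "r_S_ptrc": ({}, {"ptrc": 1}),
            "r_S_nh3": ({}, {"nh3": 1}, 1.0),
            "r1": ({"arg": 1}, {"agm": 1}),
            "r2": ({"agm": 1}, {"ptrc": 1, "urea": 1}),
            "r3": ({"urea": 1}, {"nh3": 1, "co2": 1}),
            "r4": ({"co2": 1}, {}),
            "r_T": ({"ptrc": 1, "nh3": 1}, {}),
        },
        target_id="r_T",
    )


def _fig6_motif(n_pathway: int = 9) -> StoichiometricNetwork:
    """Initiation-pathway motif: the linear-pathway compounds are S-only.

    A self-activated cycle (U -> V -> U + T) produces the target compound
    at steady state with zero flux through the linear initiation pathway
    from the pyruvate-like seed; graph-based activation, by contrast,
    requires the pathway to enter the cycle, so each of its ``n_pathway``
    intermediates is a sustainability-PEM and nothing else.
    """
    if n_pathway < 1:
        raise ValueError("n_pathway must be >= 1")
    rxns: dict = {
        "r_S": ({}, {"pyr": 1}),
        "p1": ({"pyr": 1}, {"I1": 1}),
        "c_a": ({"U": 1}, {"V": 1}),
        "c_b": ({"V": 1}, {"U": 1, "T": 1}),
        "r_T": ({"T": 1}, {}),
    }
    for i in range(1, n_pathway):
        rxns[f"p{i + 1}"] = ({f"I{i}": 1}, {f"I{i + 1}": 1})
    rxns[f"p{n_pathway + 1}"] = ({f"I{n_pathway}": 1}, {"U": 1})
    return build_network(reactions=rxns, target_id="r_T")


def _fig7_motif() -> StoichiometricNetwork:
    """Internal-cycle motif: thm is S and O but not P.

    The main route seed -> thm -> T carries the optimum (capacity 10); a
    seed-disconnected internal cycle (W <-> Z) can still produce T at
    capacity 5, so knocking out the thm-consuming reaction halves the
    optimum (essential) and pruning thm removes the graph path (the cycle
    is outside the seed scope) — yet target flux survives.
    """
    return build_network(
        reactions={
            "r_S": ({}, {"s": 1}),
            "r0": ({"s": 1}, {"thm": 1}),
            "r_m": ({"thm": 1}, {"T": 1}),
            "c_w": ({"W": 1}, {"Z": 1, "T": 1}, 5.0),
            "c_z": ({"Z": 1}, {"W": 1}),
            "r_T": ({"T": 1}, {}),
        },
        target_id="r_T",
    )


def _fig8_motif() -> StoichiometricNetwork:
    """Co-product-export motif: dala is P-only.

    The target precursor's production co-produces dala, which two
    redundant exports remove; pruning dala removes both exports at once so
    it accumulates and blocks all flux, while each single export knockout
    is harmless and the graph scope never depends on dala consumption.
    """
    return build_network(
        reactions={
            "r_S": ({}, {"m5p": 1}),
            "r_m": ({"m5p": 1}, {"mx4p": 1, "dala": 1}),
            "r_e1": ({"dala": 1}, {}),
            "r_e2": ({"dala": 1}, {}),
            "r_T": ({"mx4p": 1}, {}),
        },
        target_id="r_T",
    )


def _chain(n: int = 3) -> StoichiometricNetwork:
    """Linear chain of n reactions from a boundary seed to the target."""
    if n < 1:
        raise ValueError("chain length must be >= 1")
    rxns: dict = {"r_S": ({}, {"C0": 1})}
    for i in range(1, n + 1):
        rxns[f"r{i}"] = ({f"C{i - 1}": 1}, {f"C{i}": 1})
    rxns["r_T"] = ({f"C{n}": 1}, {})
    return build_network(reactions=rxns, target_id="r_T")


def _random_small(
    seed: int = 0, n_metabolites: int = 6, n_reactions: int = 8
) -> StoichiometricNetwork:
    """Deterministic random small network for property tests.

    One boundary reaction seeds M0; the remaining reactions draw 1–2
    reactants and 1–2 products uniformly; the target consumes a random
    metabolite.  Identical (seed, sizes) always yield identical networks.
    """
    rng = random.Random(seed)
    mets = [f"M{i}" for i in range(n_metabolites)]
    rxns: dict = {"r_S": ({}, {"M0": 1})}
    for i in range(n_reactions):
        rcts = {m: 1 for m in rng.sample(mets, rng.randint(1, 2))}
        prds = {
            m: rng.choice([1, 1, 2])
            for m in rng.sample(mets, rng.randint(1, 2))
            if m not in rcts
        }
        if not prds:
            prds = {rng.choice([m for m in mets if m not in rcts]): 1}
        rxns[f"r{i}"] = (rcts, prds)
    rxns["r_T"] = ({rng.choice(mets): 1}, {})
    return build_network(reactions=rxns, target_id="r_T")


_BUILDERS = {
    "fig1": lambda **kw: _fig1(),
    "fig2": lambda **kw: _fig2(bounds_variant=False),
    "fig2_bounds": lambda **kw: _fig2(bounds_variant=True),
    "fig4": lambda **kw: _fig4(),
    "fig5": lambda **kw: _fig5(),
    "fig6_motif": _fig6_motif,
    "fig7_motif": _fig7_motif,
    "fig8_motif": lambda **kw: _fig8_motif(),
    "chain_n": lambda n=3, **kw: _chain(n),
    "random_small": lambda seed=0, **kw: _random_small(seed=seed, **kw),
}


_DESCRIPTIONS = {
    "fig1": "two-branch toy network with a mass-conserving cycle",
    "fig2": "PEM showcase: E is SPO, G is PO",
    "fig2_bounds": "PEM showcase with bound asymmetry making B an O-PEM",
    "fig4": "redundant-pathway motif (SP-only compound)",
    "fig5": "optimal pathway choice motif (O-only compounds)",
    "fig6_motif": "initiation pathway + self-activated cycle (S-only compounds)",
    "fig7_motif": "seed-disconnected internal cycle (SO-only compound)",
    "fig8_motif": "dual co-product export (P-only compound)",
    "chain_n": "linear chain from boundary seed to target",
    "random_small": "seeded random small network",
}


def make_fixture(name: str, **params) -> Fixture:
    """Build a named fixture; unknown names raise ``ValueError``."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown fixture name {name!r}; available: {', '.join(sorted(_BUILDERS))}"
        )
    net = _BUILDERS[name](**params)
    return _fixture(name, net, _DESCRIPTIONS[name])
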