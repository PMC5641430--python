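"""Scope (network expansion) and sustainability-PEM enumeration.

The scope of a seed set S is the least fixpoint of
``M0 = S; M_{i+1} = M_i ∪ prds({r | rcts(r) ⊆ M_i})`` — the closure of
metabolites reachable when a reaction fires only once *all* of its
reactants are reachable.  This is the strictest graph-based producibility
semantics: cycles are not self-initiating, so a metabolite inside a cycle
is reachable only if the cycle can be entered from the seeds.

A sustainability-PEM is an internal compound whose pruning (removal of all
reactions able to consume it) disconnects at least one reactant of the
targeted reaction from the seed scope.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

from .model import SeedSet, StoichiometricNetwork, TargetSpec, UnknownIdError


class TargetUnreachableError(ValueError):
    """The targeted reaction is not topologically activated from the seeds."""

    def __init__(self, target_id: str, missing_reactants: Iterable[str]):
        self.target_id = target_id
        self.missing_reactants = tuple(sorted(missing_reactants))
        super().__init__(
            f"target reaction {target_id!r} is not topologically activated: "
            f"reactants outside the seed scope: {', '.join(self.missing_reactants)}"
        )


@dataclass(frozen=True)
class Scope:
    """Result of a scope computation: Σ(G, S) plus the fired reactions."""

    activated_metabolites: frozenset[str]
    activated_reactions: frozenset[str]
    iterations: int


def compute_scope(net: StoichiometricNetwork, seeds: Iterable[str]) -> Scope:
    """Least fixpoint of the seed closure, via a worklist over reactions.

    Each reaction keeps a counter of reactants not yet in scope; a reaction
    fires when its counter reaches zero.  The result is independent of
    iteration order (the fixpoint is unique); ``iterations`` counts
    breadth-first waves and is at most ``len(reactions) + 1``.

    A self-loop (m both reactant and product of r) follows the strict
    recursive semantics: r fires only once m is already in scope by some
    other route.

    Reactant-free boundary reactions take no part in the closure: their
    role — making their products available by construction — is expressed
    through the seed set (the standing assumption is that every boundary
    seed is a seed), so restricting the analysis to a subset of the seeds
    does not smuggle the other boundary compounds back in.
    """
    seed_set = frozenset(seeds)
    for mid in seed_set:
        net.metabolite(mid)

    unmet: dict[str, int] = {}
    waiting: dict[str, list[str]] = {}  # metabolite -> reactions awaiting it
    in_scope: set[str] = set(seed_set)
    fired: set[str] = set()
    frontier: deque[str] = deque()

    for rid, r in net.reactions.items():
        if not r.reactants:
            continue
        missing = [m for m in r.reactants if m not in in_scope]
        unmet[rid] = len(missing)
        for m in missing:
            waiting.setdefault(m, []).append(rid)
        if not missing:
            frontier.append(rid)

    iterations = 0
    while frontier:
        iterations += 1
        new_mets: list[str] = []
        for _ in range(len(frontier)):
            rid = frontier.popleft()
            if rid in fired:
                continue
            fired.add(rid)
            for m in net.reactions[rid].products:
                if m not in in_scope:
                    in_scope.add(m)
                    new_mets.append(m)
        for m in new_mets:
            for rid in waiting.get(m, ()):
                unmet[rid] -= 1
                if unmet[rid] == 0:
                    frontier.append(rid)

    return Scope(
        activated_metabolites=frozenset(in_scope),
        activated_reactions=frozenset(fired),
        iterations=iterations,
    )


def topologically_activated(
    net: StoichiometricNetwork, seeds: Iterable[str], reaction_id: str
) -> bool:
    """True iff every reactant of the reaction lies in Σ(G, S)."""
    r = net.reaction(reaction_id)
    scope = compute_scope(net, seeds)
    return frozenset(r.reactants) <= scope.activated_metabolites


def _candidates(
    net: StoichiometricNetwork,
    seeds: SeedSet,
    target: TargetSpec,
    scope_mets: frozenset[str],
) -> list[str]:
    """Candidate compounds for pruning-based enumeration.

    Candidates are the compounds in scope that are reactants of at least
    one reaction and are neither seeds nor reactants of the target — the
    excluded compounds can never satisfy the definition, and pruning with
    respect to an out-of-scope or never-consumed compound leaves the scope
    unchanged.
    """
    excluded = seeds.seeds | target.targeted_metabolites
    consumed = {m for r in net.reactions.values() for m in r.reactants}
    return sorted((scope_mets & consumed) - excluded)


def sustainability_pems(
    net: StoichiometricNetwork, seeds: SeedSet, target: TargetSpec
) -> frozenset[str]:
    """Compounds whose pruning breaks topological activation of the target.

    Raises
    ------
    TargetUnreachableError
        If the target is not topologically activated in the unpruned
        network (the classification would be vacuous), naming the
        reactants outside the scope.
    """
    rT = net.reaction(target.target_reaction_id)
    base = compute_scope(net, seeds.seeds)
    missing = frozenset(rT.reactants) - base.activated_metabolites
    if missing:
        raise TargetUnreachableError(rT.id, missing)

    out: set[str] = set()
    for mid in _candidates(net, seeds, target, base.activated_metabolites):
        pruned = net.prune(mid)
        sub = compute_scope(pruned, seeds.seeds)
        if not frozenset(rT.reactants) <= sub.activated_metabolites:
            out.add(mid)
    return frozenset(out)


def blocked_targets(
    net: StoichiometricNetwork,
    seeds: SeedSet,
    target: TargetSpec,
    mid: str,
) -> frozenset[str]:
    """Reactants of the target that leave the scope when pruning w.r.t. mid.

    Non-empty exactly when ``mid`` is a sustainability-PEM (for candidate
    compounds).
    """
    net.metabolite(mid)
    rT = net.reaction(target.target_reaction_id)
    pruned = net.prune(mid)
    sub = compute_scope(pruned, seeds.seeds)
    return frozenset(rT.reactants) - sub.activated_metabolites


def listing_candidate_discrepancy(
    net: StoichiometricNetwork, seeds: SeedSet, target: TargetSpec
) -> frozenset[str]:
    """Target reactants that a looser candidate rule would also admit.

    The strict definition excludes every reactant of the target from the
    candidate set, while a rule excluding only "reactants of the target
    reaction itself" would still admit a target reactant that is also a
    reactant of some other reaction.  Returns that discrepancy set so it
    can be logged; it is never classified.
    """
    out = set()
    for mid in target.targeted_metabolites:
        for r in net.reactions.values():
            if r.id != target.target_reaction_id and mid in r.reactants:
                out.add(mid)
                break
    return frozenset(out)


def write_sustainability_tsv(
    path,
    net: StoichiometricNetwork,
    seeds: SeedSet,
    target: TargetSpec,
    pems: frozenset[str],
) -> None:
    """Per-metabolite sustainability report.

    Columns: metabolite_id, is_sustainability_pem, blocked_target_metabolites
    (semicolon-separated).
    """
    with open(path, "w") as fh:
        fh.write("metabolite_id\tis_sustainability_pem\tblocked_target_metabolites\n")
        for mid in sorted(net.metabolites):
            is_pem = mid in pems
            blocked = ""
            if is_pem:
                blocked = ";".join(sorted(blocked_targets(net, seeds, target, mid)))
            fh.write(f"{mid}\t{int(is_pem)}\t{blocked}\n")
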