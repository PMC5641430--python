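"""Flux-based activation: FBA, FVA, essentiality and PEM enumeration.

All flux problems share one constraint system: non-negative fluxes bounded
above per reaction, and steady-state mass balance for every internal
metabolite (production minus consumption equals zero).  Species flagged as
balance-exempt in the source model get no balance row; influx otherwise
enters only through reactant-free boundary reactions, whose products can
therefore initiate flux.

Linear programs are solved with the HiGHS solver through
``scipy.optimize.linprog`` over a fixed lexicographic variable ordering,
so results are deterministic.  Classification decisions depend only on
optimal *values*, never on which optimizer the solver returns among
degenerate alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .model import SeedSet, StoichiometricNetwork, TargetSpec

logger = logging.getLogger(__name__)

#: A reaction is considered active when it can carry more flux than this.
EPS_ACTIVATION = 1e-6
#: Absolute and relative optimum-drop thresholds for essentiality.
DELTA_ESSENTIAL = 1e-6
RHO_ESSENTIAL = 1e-6


class TargetInactiveError(ValueError):
    """The targeted reaction carries no flux in the unpruned network."""


@dataclass(frozen=True)
class LPResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Mapping[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxInterval:
    min_v: float
    max_v: float


def _lp_arrays(net: StoichiometricNetwork):
    """Stoichiometric matrix (internal metabolites x reactions) and bounds."""
    rids = sorted(net.reactions)
    col = {rid: j for j, rid in enumerate(rids)}
    mids = [m for m in sorted(net.metabolites) if m not in net.balance_exempt]
    row = {mid: i for i, mid in enumerate(mids)}
    data, ri, ci = [], [], []
    for rid, r in net.reactions.items():
        j = col[rid]
        for mid, coeff in r.reactants.items():
            if mid in row:
                ri.append(row[mid]); ci.append(j); data.append(-float(coeff))
        for mid, coeff in r.products.items():
            if mid in row:
                ri.append(row[mid]); ci.append(j); data.append(float(coeff))
    mat = csr_matrix((data, (ri, ci)), shape=(len(mids), len(rids))) if mids else None
    ubs = np.array([float(net.reactions[rid].upper_bound) for rid in rids])
    return rids, col, mat, ubs


def _solve(
    net: StoichiometricNetwork,
    objective_id: str,
    fixed: Optional[Mapping[str, float]] = None,
    lower: Optional[Mapping[str, float]] = None,
    maximize: bool = True,
) -> LPResult:
    """Optimize the flux of one reaction over the Eq (1)-(2) polytope.

    ``fixed`` pins fluxes to exact values (knockouts); ``lower`` raises the
    lower bound of named fluxes (optimum pinning for FVA).
    """
    net.reaction(objective_id)
    rids, col, a_eq, ubs = _lp_arrays(net)
    lo = np.zeros(len(rids))
    hi = ubs.copy()
    for rid, val in (fixed or {}).items():
        j = col[net.reaction(rid).id]
        v = float(val)
        if v < -1e-12 or v > ubs[j] + 1e-9:
            raise ValueError(f"fixed flux for {rid!r} outside [0, {ubs[j]}]: {v}")
        lo[j] = hi[j] = min(v, ubs[j])
    for rid, val in (lower or {}).items():
        j = col[net.reaction(rid).id]
        lo[j] = min(max(lo[j], float(val)), hi[j])
    c = np.zeros(len(rids))
    c[col[objective_id]] = -1.0 if maximize else 1.0
    res = linprog(
        c,
        A_eq=a_eq,
        b_eq=np.zeros(a_eq.shape[0]) if a_eq is not None else None,
        bounds=list(zip(lo, hi)),
        method="highs",
    )
    if res.status == 0:
        fluxes = {rid: max(0.0, float(v)) for rid, v in zip(rids, res.x)}
        return LPResult("optimal", float(fluxes[objective_id]), fluxes)
    if res.status == 2:
        return LPResult("infeasible", None)
    if res.status == 3:
        return LPResult("unbounded", None)
    raise RuntimeError(f"LP solver failure: {res.message}")


def max_flux(
    net: StoichiometricNetwork,
    objective: str,
    fixed: Optional[Mapping[str, float]] = None,
) -> LPResult:
    """Maximize the flux of one reaction under mass balance and bounds."""
    return _solve(net, objective, fixed=fixed, maximize=True)


def stoichiometrically_activated(
    net: StoichiometricNetwork, reaction_id: str, eps: float = EPS_ACTIVATION
) -> bool:
    """True iff some feasible flux vector gives the reaction flux > eps."""
    res = max_flux(net, reaction_id)
    if not res.optimal:
        logger.warning(
            "flux system %s while testing %r; treating as inactive",
            res.status, reaction_id,
        )
        return False
    return res.objective_value > eps


def _flux_candidates(net, seeds: SeedSet, target: TargetSpec) -> list[str]:
    excluded = seeds.seeds | target.targeted_metabolites
    consumed = {m for r in net.reactions.values() for m in r.reactants}
    return sorted((consumed & set(net.metabolites)) - excluded)


def producibility_pems(
    net: StoichiometricNetwork,
    seeds: SeedSet,
    target: TargetSpec,
    eps: float = EPS_ACTIVATION,
) -> frozenset[str]:
    """Compounds whose pruning abolishes all target flux.

    This covers both substrates of single lethal reactions and compounds
    whose multiple consuming reactions are only jointly lethal (pruning
    removes them all at once).

    Raises
    ------
    TargetInactiveError
        If the target carries no flux in the unpruned network.
    """
    rT = net.reaction(target.target_reaction_id)
    if not stoichiometrically_activated(net, rT.id, eps):
        raise TargetInactiveError(
            f"target reaction {rT.id!r} carries no flux in the unpruned network"
        )
    out: set[str] = set()
    for mid in _flux_candidates(net, seeds, target):
        pruned = net.prune(mid)
        if rT.id not in pruned.reactions:
            out.add(mid)  # target itself consumed the compound reversibly
            continue
        if not stoichiometrically_activated(pruned, rT.id, eps):
            out.add(mid)
    return frozenset(out)


def essential_reactions(
    net: StoichiometricNetwork,
    target: TargetSpec,
    delta: float = DELTA_ESSENTIAL,
    rho: float = RHO_ESSENTIAL,
) -> frozenset[str]:
    """Reactions whose knockout strictly lowers the maximal target flux.

    The knockout fixes the flux to zero; both directions of a reversible
    pair are knocked out jointly, and both ids are reported when the pair
    is essential.  A reaction is essential when the knockout optimum drops
    below the base optimum by more than ``delta`` absolutely *and* by more
    than a ``rho`` fraction.
    """
    rT = net.reaction(target.target_reaction_id)
    base = max_flux(net, rT.id)
    if not base.optimal:
        return frozenset()
    mu = base.objective_value
    out: set[str] = set()
    for rep, partner in net.reversible_pairs():
        fixed = {rep: 0.0}
        if partner is not None:
            fixed[partner] = 0.0
        res = max_flux(net, rT.id, fixed=fixed)
        val = res.objective_value if res.optimal else 0.0
        if val < mu - delta and val < mu * (1.0 - rho):
            out.add(rep)
            if partner is not None:
                out.add(partner)
    return frozenset(out)


def optimal_efficiency_pems(
    net: StoichiometricNetwork,
    target: TargetSpec,
    delta: float = DELTA_ESSENTIAL,
    rho: float = RHO_ESSENTIAL,
) -> frozenset[str]:
    """Substrates of reactions essential for the *optimal* target flux.

    Unlike the two pruning-based classes, this is a single-reaction
    criterion and deliberately applies no seed/target-reactant exclusion,
    so the three classes stay logically independent.  For an essential
    reversible pair the substrates of both directions are included.
    """
    ess = essential_reactions(net, target, delta, rho)
    out: set[str] = set()
    for rid in ess:
        out.update(net.reactions[rid].reactants)
    return frozenset(out)


def fva(
    net: StoichiometricNetwork,
    reaction_id: str,
    at_optimum: bool = False,
) -> FluxInterval:
    """Flux variability interval [min, max] for one reaction.

    With ``at_optimum`` the target optimum mu* is computed first and the
    polytope is restricted to flux vectors attaining it (within solver
    tolerance): the interval the optimal-flux essentiality criterion
    reads — an essential reaction has min > 0 at optimum.
    """
    net.reaction(reaction_id)
    lower: dict[str, float] = {}
    if at_optimum:
        rT = net.target_reaction
        base = max_flux(net, rT.id)
        if not base.optimal:
            raise TargetInactiveError("optimum-constrained polytope is infeasible")
        mu = base.objective_value
        lower[rT.id] = max(0.0, mu - 1e-9 * max(1.0, abs(mu)))
    lo_res = _solve(net, reaction_id, lower=lower, maximize=False)
    hi_res = _solve(net, reaction_id, lower=lower, maximize=True)
    if not (lo_res.optimal and hi_res.optimal):
        raise TargetInactiveError("constrained flux polytope is infeasible")
    lo = max(0.0, lo_res.objective_value)
    hi = max(lo, hi_res.objective_value)
    return FluxInterval(min_v=lo, max_v=hi)


def write_essentiality_tsv(
    path, net: StoichiometricNetwork, essential: frozenset[str]
) -> None:
    """Per-reaction essentiality flags (reversible pairs share a verdict)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tis_essential\n")
        for rid in sorted(net.reactions):
            fh.write(f"{rid}\t{int(rid in essential)}\n")


def lp_result_to_json(result: LPResult) -> dict:
    """JSON-serializable audit dump of an LP solution."""
    return {
        "status": result.status,
        "objective_value": result.objective_value,
        "fluxes": {k: result.fluxes[k] for k in sorted(result.fluxes)},
    }
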