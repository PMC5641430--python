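"""SBML ingestion and export of the canonical irreversible network.

Reads SBML Level 2 or Level 3 (with or without the fbc extension) and
returns the canonical form used by the rest of the package: every
reversible reaction is split into a forward/backward pair (backward id
``<id>_rev``) linked through ``reverse_of``, so all fluxes are
non-negative.  Upper bounds are taken from fbc flux-bound parameters or
Level-2 kinetic-law parameters; a reaction with an fbc lower bound < 0 is
treated as reversible regardless of its ``reversible`` attribute, and the
backward direction inherits |lower bound| as its upper bound (the forward
bound when no explicit bounds exist).

Boundary handling follows the structural definition of boundary seeds:
products of reactant-free reactions are seeds, and species flagged
``boundaryCondition`` are both seeds and exempt from mass-balance rows.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Optional

import re

import libsbml

from .model import (
    DEFAULT_UPPER_BOUND,
    Metabolite,
    Reaction,
    SeedSet,
    StoichiometricNetwork,
    TargetSpec,
    UnknownIdError,
    derive_seed_set,
)


#: Annotation carrying the id of the backward direction of a merged
#: reversible pair, so canonical split networks round-trip id-for-id even
#: when the backward direction is not named "<id>_rev".
_ANNOTATION_NS = "https://pemnet.invalid/sbml"
_BACKWARD_ID_RE = re.compile(r"<backwardId[^>]*>([^<]+)</backwardId>")


def _reaction_bounds(model, reaction, default_ub: float) -> tuple[float, Optional[float]]:
    """(upper_bound, lower_bound or None) from fbc or kinetic-law params."""
    ub: Optional[float] = None
    lb: Optional[float] = None
    fbc = reaction.getPlugin("fbc")
    if fbc is not None:
        ub_id = fbc.getUpperFluxBound()
        lb_id = fbc.getLowerFluxBound()
        if ub_id:
            p = model.getParameter(ub_id)
            if p is not None:
                ub = p.getValue()
        if lb_id:
            p = model.getParameter(lb_id)
            if p is not None:
                lb = p.getValue()
    kl = reaction.getKineticLaw()
    if ub is None and kl is not None:
        p = kl.getParameter("UPPER_BOUND")
        if p is not None:
            ub = p.getValue()
    if lb is None and kl is not None:
        p = kl.getParameter("LOWER_BOUND")
        if p is not None:
            lb = p.getValue()
    if ub is None or not math.isfinite(ub):
        ub = default_ub
    if lb is not None and not math.isfinite(lb):
        lb = -default_ub
    return float(ub), (None if lb is None else float(lb))


def parse_sbml(
    path,
    target_id: str,
    seed_override: Optional[Iterable[str]] = None,
    replace_boundary: bool = False,
    default_ub: float = DEFAULT_UPPER_BOUND,
) -> tuple[StoichiometricNetwork, SeedSet, TargetSpec]:
    """Parse an SBML file into (network, seeds, target spec).

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for
    malformed SBML, and ``UnknownIdError`` naming the offending identifier
    for an unknown target or seed id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(f"malformed SBML in {path}: {first.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"malformed SBML in {path}: no model element")

    metabolites: dict[str, Metabolite] = {}
    exempt: set[str] = set()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        sid = sp.getId()
        metabolites[sid] = Metabolite(
            id=sid, name=sp.getName() or "", compartment=sp.getCompartment() or None
        )
        if sp.getBoundaryCondition():
            exempt.add(sid)

    reactions: dict[str, Reaction] = {}
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = rx.getId()
        rcts = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            st = sr.getStoichiometry()
            rcts[sr.getSpecies()] = rcts.get(sr.getSpecies(), 0.0) + (
                st if st and math.isfinite(st) else 1.0
            )
        prds = {}
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            st = sr.getStoichiometry()
            prds[sr.getSpecies()] = prds.get(sr.getSpecies(), 0.0) + (
                st if st and math.isfinite(st) else 1.0
            )
        ub, lb = _reaction_bounds(model, rx, default_ub)
        reversible = rx.getReversible() or (lb is not None and lb < 0)
        back_id = rid + "_rev"
        ann = rx.getAnnotationString() if rx.isSetAnnotation() else ""
        m = _BACKWARD_ID_RE.search(ann)
        if m:
            back_id = m.group(1)
        reactions[rid] = Reaction(
            id=rid,
            reactants=rcts,
            products=prds,
            upper_bound=max(ub, 0.0),
            reverse_of=back_id if reversible else None,
            name=rx.getName() or "",
        )
        if reversible:
            back_ub = abs(lb) if (lb is not None and lb < 0) else ub
            reactions[back_id] = Reaction(
                id=back_id,
                reactants=prds,
                products=rcts,
                upper_bound=max(back_ub, 0.0),
                reverse_of=rid,
                name=rx.getName() or "",
            )

    if target_id not in reactions:
        raise UnknownIdError(f"unknown target reaction id: {target_id!r}")

    net = StoichiometricNetwork(
        metabolites=metabolites,
        reactions=reactions,
        target_reaction_id=target_id,
        balance_exempt=frozenset(exempt),
    )
    net.validate()
    seeds = derive_seed_set(net, seed_override, replace_boundary=replace_boundary)
    return net, seeds, TargetSpec.from_network(net)


def _check(code, what: str) -> None:
    if code not in (libsbml.LIBSBML_OPERATION_SUCCESS, None):
        raise RuntimeError(f"libsbml error while {what}: code {code}")


def write_sbml(net: StoichiometricNetwork, path) -> None:
    """Write the canonical network as SBML Level 3 + fbc.

    A forward/backward pair with canonical naming (``x`` / ``x_rev``) is
    merged back into a single reversible reaction whose fbc lower bound is
    minus the backward upper bound, so a parse/write/parse round trip is
    the identity on ids, coefficients and bounds.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId("pemnet_model")
    mplug = model.getPlugin("fbc")
    if mplug is not None:
        mplug.setStrict(False)

    compartments = sorted(
        {(m.compartment or "c") for m in net.metabolites.values()}
    )
    for cid in compartments:
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for mid in sorted(net.metabolites):
        m = net.metabolites[mid]
        sp = model.createSpecies()
        sp.setId(mid)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(m.compartment or "c")
        sp.setBoundaryCondition(mid in net.balance_exempt)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    def add_bound_param(pid: str, value: float) -> str:
        p = model.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    for rep, partner in net.reversible_pairs():
        r = net.reactions[rep]
        # prefer the member whose partner is named "<id>_rev" as forward
        if partner is not None and rep.endswith("_rev") and not partner.endswith("_rev"):
            rep, partner = partner, rep
            r = net.reactions[rep]
        rx = model.createReaction()
        rx.setId(rep)
        if partner is not None and partner != rep + "_rev":
            rx.appendAnnotation(
                f'<backwardId xmlns="{_ANNOTATION_NS}">{partner}</backwardId>'
            )
        if r.name:
            rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(partner is not None)
        for mid in sorted(r.reactants):
            sr = rx.createReactant()
            sr.setSpecies(mid)
            sr.setStoichiometry(float(r.reactants[mid]))
            sr.setConstant(True)
        for mid in sorted(r.products):
            sr = rx.createProduct()
            sr.setSpecies(mid)
            sr.setStoichiometry(float(r.products[mid]))
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        ub_id = add_bound_param(f"fb_{rep}_ub", r.upper_bound)
        lb_val = -net.reactions[partner].upper_bound if partner is not None else 0.0
        lb_id = add_bound_param(f"fb_{rep}_lb", lb_val)
        if rplug is not None:
            rplug.setUpperFluxBound(ub_id)
            rplug.setLowerFluxBound(lb_id)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise RuntimeError(f"could not write SBML to {path}")
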