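"""Core domain types for stoichiometric metabolic networks.

A metabolic network is a directed bipartite graph over reactions and
metabolites with rational edge labels (stoichiometric coefficients).  The
canonical in-memory form used throughout the package is *irreversible*:
every reversible reaction is represented by a forward/backward pair of
irreversible reactions linked through ``Reaction.reverse_of``, so that all
flux variables are non-negative.

The module also provides the structural primitives the classification is
built on: boundary-seed detection, the connectivity degree of a compound,
and the pruning operator ``prune(G, m)`` that removes every reaction
consuming a metabolite (including the reverse direction of reversible
reactions producing it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

#: Conventional flux cap used when a model supplies no upper bound
#: (mmol/gDW/h in genome-scale models).
DEFAULT_UPPER_BOUND = 1000.0

#: Tolerance for matching stoichiometric coefficients of reverse pairs when
#: coefficients are floats; exact equality is used for int/Fraction values.
COEFF_TOL = 1e-9


class NetworkValidationError(ValueError):
    """The network violates a structural invariant."""


class UnknownIdError(KeyError):
    """An identifier does not name any element of the network."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class Metabolite:
    """A compound node; identity is the full (compartment-qualified) id."""

    id: str
    name: str = ""
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction with positive stoichiometric coefficients.

    ``reverse_of`` links the two directions of a reversible reaction; the
    partner must have mirrored reactants/products with identical
    coefficients (the structural reversibility condition).
    """

    id: str
    reactants: Mapping[str, float] = field(default_factory=dict)
    products: Mapping[str, float] = field(default_factory=dict)
    upper_bound: float = DEFAULT_UPPER_BOUND
    reverse_of: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        for side in (self.reactants, self.products):
            for met, coeff in side.items():
                if not coeff > 0:
                    raise NetworkValidationError(
                        f"reaction {self.id!r}: coefficient for {met!r} "
                        f"must be > 0, got {coeff!r}"
                    )
        if self.upper_bound < 0:
            raise NetworkValidationError(
                f"reaction {self.id!r}: upper bound must be >= 0"
            )

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.reactants) | frozenset(self.products)


def _coeff_maps_equal(a: Mapping[str, float], b: Mapping[str, float]) -> bool:
    if set(a) != set(b):
        return False
    for met, ca in a.items():
        cb = b[met]
        if isinstance(ca, float) or isinstance(cb, float):
            if not math.isclose(float(ca), float(cb), rel_tol=0.0, abs_tol=COEFF_TOL):
                return False
        elif ca != cb:
            return False
    return True


@dataclass
class StoichiometricNetwork:
    """A stoichiometric metabolic network in canonical irreversible form.

    Parameters
    ----------
    metabolites, reactions
        Keyed by id.  Iteration over the network is always in lexicographic
        id order so that derived reports are byte-for-byte reproducible.
    target_reaction_id
        The targeted reaction r_T (typically biomass); its reactants are the
        targeted metabolic compounds.
    balance_exempt
        Species flagged as external/boundary-condition in the source model;
        they receive no mass-balance row in flux problems.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    target_reaction_id: Optional[str] = None
    balance_exempt: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.metabolites = dict(sorted(self.metabolites.items()))
        self.reactions = dict(sorted(self.reactions.items()))

    # -- lookups ---------------------------------------------------------

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self.metabolites[mid]
        except KeyError:
            raise UnknownIdError(f"unknown metabolite id: {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[rid]
        except KeyError:
            raise UnknownIdError(f"unknown reaction id: {rid!r}") from None

    @property
    def target_reaction(self) -> Reaction:
        if self.target_reaction_id is None:
            raise NetworkValidationError("network has no target reaction")
        return self.reaction(self.target_reaction_id)

    def target_reactants(self) -> frozenset[str]:
        return frozenset(self.target_reaction.reactants)

    def consumers(self, mid: str) -> list[Reaction]:
        """Reactions with ``mid`` among their reactants, in id order."""
        self.metabolite(mid)
        return [r for r in self.reactions.values() if mid in r.reactants]

    def producers(self, mid: str) -> list[Reaction]:
        self.metabolite(mid)
        return [r for r in self.reactions.values() if mid in r.products]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and the reverse-pair invariants."""
        for r in self.reactions.values():
            for mid in r.metabolite_ids:
                if mid not in self.metabolites:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
            if r.reverse_of is not None:
                partner = self.reactions.get(r.reverse_of)
                if partner is None:
                    raise NetworkValidationError(
                        f"reaction {r.id!r}: reverse partner {r.reverse_of!r} "
                        "does not exist"
                    )
                if partner.reverse_of != r.id:
                    raise NetworkValidationError(
                        f"reverse_of relation not symmetric for {r.id!r}"
                    )
                if not (
                    _coeff_maps_equal(r.reactants, partner.products)
                    and _coeff_maps_equal(r.products, partner.reactants)
                ):
                    raise NetworkValidationError(
                        f"reverse pair {r.id!r}/{partner.id!r} does not mirror "
                        "stoichiometry"
                    )
        if self.target_reaction_id is not None:
            self.reaction(self.target_reaction_id)

    # -- structural operations ------------------------------------------

    def boundary_seeds(self) -> frozenset[str]:
        """Products of reactant-free reactions: S_b(G).

        These compounds are producible by construction, so their production
        is assumed activated by default.  Species flagged as external in the
        source model (``balance_exempt``) are included as well: SBML encodes
        the same structural idea either as an explicit exchange reaction
        with no reactant or as a boundary-condition species.
        """
        out: set[str] = set(self.balance_exempt)
        for r in self.reactions.values():
            if not r.reactants:
                out.update(r.products)
        return frozenset(out)

    def connectivity(self, mid: str) -> int:
        """Number of distinct reactions consuming or producing ``mid``.

        A reversible forward/backward pair counts as one biological
        reaction (the pair is collapsed before counting).
        """
        self.metabolite(mid)
        seen: set[str] = set()
        for r in self.reactions.values():
            if mid in r.reactants or mid in r.products:
                canonical = r.id
                if r.reverse_of is not None:
                    canonical = min(r.id, r.reverse_of)
                seen.add(canonical)
        return len(seen)

    def reversible_pairs(self) -> list[tuple[str, Optional[str]]]:
        """Canonical (representative, partner-or-None) per biological reaction."""
        out: list[tuple[str, Optional[str]]] = []
        for rid, r in self.reactions.items():
            if r.reverse_of is None:
                out.append((rid, None))
            elif rid < r.reverse_of:
                out.append((rid, r.reverse_of))
        return out

    def prune(self, mid: str) -> "StoichiometricNetwork":
        """Remove every reaction consuming ``mid``.

        Removes ``{r | m in rcts(r)}`` together with the members of
        reversible pairs producing ``m`` (whose partner consumes it), so the
        pruned network contains no reaction able to consume ``m`` in either
        direction.  The metabolite set is unchanged and the receiver is not
        modified.
        """
        self.metabolite(mid)
        kept: dict[str, Reaction] = {}
        removed: set[str] = set()
        for rid, r in self.reactions.items():
            if mid in r.reactants or (r.reverse_of is not None and mid in r.products):
                removed.add(rid)
            else:
                kept[rid] = r
        # a kept reaction may have lost its partner; drop the dangling link
        for rid, r in list(kept.items()):
            if r.reverse_of is not None and r.reverse_of in removed:
                kept[rid] = replace(r, reverse_of=None)
        return StoichiometricNetwork(
            metabolites=dict(self.metabolites),
            reactions=kept,
            target_reaction_id=self.target_reaction_id,
            balance_exempt=self.balance_exempt,
        )

    # -- export ----------------------------------------------------------

    def to_edge_tsv(self, path) -> None:
        """Write the bipartite edge list as TSV.

        Columns: reaction_id, metabolite_id, role (reactant|product),
        coefficient.  Rows are sorted for reproducibility.
        """
        rows = []
        for rid in sorted(self.reactions):
            r = self.reactions[rid]
            for mid in sorted(r.reactants):
                rows.append((rid, mid, "reactant", r.reactants[mid]))
            for mid in sorted(r.products):
                rows.append((rid, mid, "product", r.products[mid]))
        with open(path, "w") as fh:
            fh.write("reaction_id\tmetabolite_id\trole\tcoefficient\n")
            for rid, mid, role, coeff in rows:
                fh.write(f"{rid}\t{mid}\t{role}\t{_fmt_coeff(coeff)}\n")


def _fmt_coeff(c) -> str:
    f = float(c)
    return str(int(f)) if f == int(f) else repr(f)


@dataclass(frozen=True)
class SeedSet:
    """Nutrient seeds S, with the boundary seeds S_b(G) they contain."""

    seeds: frozenset[str]
    boundary_seeds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "seeds", frozenset(self.seeds))
        object.__setattr__(self, "boundary_seeds", frozenset(self.boundary_seeds))
        if not self.boundary_seeds <= self.seeds:
            raise NetworkValidationError(
                "boundary seeds must be a subset of the seed set"
            )


@dataclass(frozen=True)
class TargetSpec:
    """The targeted reaction and its reactants (targeted compounds)."""

    target_reaction_id: str
    targeted_metabolites: frozenset[str]

    @classmethod
    def from_network(cls, net: StoichiometricNetwork) -> "TargetSpec":
        return cls(
            target_reaction_id=net.target_reaction.id,
            targeted_metabolites=net.target_reactants(),
        )


def derive_seed_set(
    net: StoichiometricNetwork,
    seed_override: Optional[Iterable[str]] = None,
    replace_boundary: bool = False,
) -> SeedSet:
    """Build the seed set of a network.

    By default the user-supplied seeds *extend* the structural boundary
    seeds (the standing assumption is that every boundary compound is a
    seed); ``replace_boundary=True`` uses only the supplied list.
    """
    boundary = net.boundary_seeds()
    extra: set[str] = set()
    for mid in seed_override or ():
        net.metabolite(mid)  # raises UnknownIdError with the offending id
        extra.add(mid)
    if replace_boundary:
        return SeedSet(seeds=frozenset(extra), boundary_seeds=frozenset(extra) & boundary)
    return SeedSet(seeds=boundary | extra, boundary_seeds=boundary)


def build_network(
    reactions: Mapping[str, tuple],
    target_id: Optional[str] = None,
    reverse_pairs: Iterable[tuple[str, str]] = (),
    compartment: Optional[str] = "c",
    default_upper_bound: float = 10.0,
) -> StoichiometricNetwork:
    """Construct a network from ``{rid: (reactants, products[, ub])}`` dicts.

    Convenience constructor used by the programmatic fixtures and tests;
    metabolites are inferred from the reactions.
    """
    rxns: dict[str, Reaction] = {}
    rev: dict[str, str] = {}
    for a, b in reverse_pairs:
        rev[a] = b
        rev[b] = a
    mets: dict[str, Metabolite] = {}
    for rid, entry in reactions.items():
        rcts, prds = entry[0], entry[1]
        ub = entry[2] if len(entry) > 2 else default_upper_bound
        rxns[rid] = Reaction(
            id=rid,
            reactants=dict(rcts),
            products=dict(prds),
            upper_bound=ub,
            reverse_of=rev.get(rid),
        )
        for mid in list(rcts) + list(prds):
            mets.setdefault(mid, Metabolite(id=mid, compartment=compartment))
    net = StoichiometricNetwork(
        metabolites=mets, reactions=rxns, target_reaction_id=target_id
    )
    net.validate()
    return net
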