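"""Combine the three PEM classes into Venn regions, summaries and tables.

The three enumerations (sustainability / producibility / optimal
efficiency) are run on one network and merged into a per-metabolite
classification with a 7-region Venn partition.  Reporting roles follow the
precedence seed > target > PEM > other: the pruning-based classes already
exclude seeds and target reactants by definition, while the
optimal-efficiency class may overlap them, so a seed that qualifies is
reported under its seed role (the flags remain visible in the TSV).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import flux as _flux
from . import scope as _scope
from .model import SeedSet, StoichiometricNetwork, TargetSpec

logger = logging.getLogger(__name__)

VENN_REGIONS = ("S-only", "P-only", "O-only", "SP", "SO", "PO", "SPO", "none")


def _region(s: bool, p: bool, o: bool) -> str:
    key = "".join(c for c, flag in zip("SPO", (s, p, o)) if flag)
    return {"S": "S-only", "P": "P-only", "O": "O-only", "": "none"}.get(key, key)


@dataclass(frozen=True)
class PEMClassification:
    """Per-metabolite PEM flags, Venn regions and reporting roles."""

    sustainability: frozenset[str]
    producibility: frozenset[str]
    optimal_efficiency: frozenset[str]
    seeds: frozenset[str]
    target_reactants: frozenset[str]
    metabolites: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def pem_union(self) -> frozenset[str]:
        return self.sustainability | self.producibility | self.optimal_efficiency

    def flags(self, mid: str) -> tuple[bool, bool, bool]:
        return (
            mid in self.sustainability,
            mid in self.producibility,
            mid in self.optimal_efficiency,
        )

    def venn_region(self, mid: str) -> str:
        return _region(*self.flags(mid))

    def role(self, mid: str) -> str:
        if mid in self.seeds:
            return "seed"
        if mid in self.target_reactants:
            return "target"
        if mid in self.pem_union:
            return "PEM"
        return "other"

    def venn_counts(self) -> dict[str, int]:
        counts = {region: 0 for region in VENN_REGIONS if region != "none"}
        for mid in self.pem_union:
            counts[self.venn_region(mid)] += 1
        return counts


@dataclass(frozen=True)
class NetworkSummary:
    """Network-level PEM counts and their percentages of all metabolites."""

    n_reactions: int
    n_metabolites: int
    n_pems: int
    n_sustainability: int
    n_producibility: int
    n_optimal_efficiency: int
    pct_pems: float
    pct_sustainability: float
    pct_producibility: float
    pct_optimal_efficiency: float


def classify(
    net: StoichiometricNetwork,
    seeds: SeedSet,
    target: TargetSpec,
    eps: float = _flux.EPS_ACTIVATION,
    delta: float = _flux.DELTA_ESSENTIAL,
    rho: float = _flux.RHO_ESSENTIAL,
    filter_roles: bool = False,
) -> PEMClassification:
    """Run the three enumerations and merge them.

    If the target is not activated under one semantics, that class comes
    back empty with a recorded warning instead of failing the whole
    classification.  ``filter_roles=True`` additionally removes seeds and
    target reactants from the optimal-efficiency set (an optional
    consistency filter; the literal definition applies no such exclusion).
    """
    notes: list[str] = []
    try:
        sus = _scope.sustainability_pems(net, seeds, target)
    except _scope.TargetUnreachableError as exc:
        notes.append(str(exc))
        sus = frozenset()
    try:
        prod = _flux.producibility_pems(net, seeds, target, eps=eps)
    except _flux.TargetInactiveError as exc:
        notes.append(str(exc))
        prod = frozenset()
    oe = _flux.optimal_efficiency_pems(net, target, delta=delta, rho=rho)
    for note in notes:
        warnings.warn(note, stacklevel=2)
    if filter_roles:
        oe = oe - seeds.seeds - target.targeted_metabolites
    else:
        overlap = oe & (seeds.seeds | target.targeted_metabolites)
        if overlap:
            note = (
                "optimal-efficiency set overlaps seeds/target reactants: "
                + ", ".join(sorted(overlap))
            )
            logger.info("%s", note)
            notes.append(note)
    return PEMClassification(
        sustainability=sus,
        producibility=prod,
        optimal_efficiency=oe,
        seeds=seeds.seeds,
        target_reactants=target.targeted_metabolites,
        metabolites=tuple(sorted(net.metabolites)),
        warnings=tuple(notes),
    )


def summarize(
    classification: PEMClassification, net: StoichiometricNetwork
) -> NetworkSummary:
    """Counts and percentages; denominators are the metabolite total and
    reactions are counted as biological reactions (reversible pairs
    collapsed)."""
    n_met = len(net.metabolites)
    n_rxn = len(net.reversible_pairs())

    def pct(n: int) -> float:
        return 100.0 * n / n_met if n_met else 0.0

    n_s = len(classification.sustainability)
    n_p = len(classification.producibility)
    n_o = len(classification.optimal_efficiency)
    n_u = len(classification.pem_union)
    return NetworkSummary(
        n_reactions=n_rxn,
        n_metabolites=n_met,
        n_pems=n_u,
        n_sustainability=n_s,
        n_producibility=n_p,
        n_optimal_efficiency=n_o,
        pct_pems=pct(n_u),
        pct_sustainability=pct(n_s),
        pct_producibility=pct(n_p),
        pct_optimal_efficiency=pct(n_o),
    )


def degree_role_table(
    net: StoichiometricNetwork,
    classification: PEMClassification,
    bin_edges: Sequence[int],
) -> pd.DataFrame:
    """Connectivity-degree vs functional-role contingency table.

    Bins are ``[e0,e1), [e1,e2), ..., [e_{k-1}, e_k]`` (last bin closed);
    every metabolite must fall in some bin.  Returns one row per non-empty
    bin with role counts and row percentages summing to 100.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    roles = ("PEM", "seed", "target", "other")
    rows = []
    for mid in classification.metabolites:
        deg = net.connectivity(mid)
        if deg < edges[0] or deg > edges[-1]:
            raise ValueError(
                f"connectivity {deg} of {mid!r} outside bin range "
                f"[{edges[0]}, {edges[-1]}]"
            )
        for i in range(len(edges) - 1):
            last = i == len(edges) - 2
            if edges[i] <= deg < edges[i + 1] or (last and deg == edges[-1]):
                rows.append((f"[{edges[i]},{edges[i+1]}]", classification.role(mid)))
                break
    df = pd.DataFrame(rows, columns=["bin", "role"])
    table = (
        df.groupby(["bin", "role"]).size().unstack(fill_value=0)
        .reindex(columns=roles, fill_value=0)
    )
    order = [f"[{a},{b}]" for a, b in zip(edges, edges[1:])]
    table = table.reindex([b for b in order if b in table.index])
    table["total"] = table[list(roles)].sum(axis=1)
    for role in roles:
        table[f"pct_{role}"] = 100.0 * table[role] / table["total"]
    return table.reset_index()


def pairwise_skeleton(
    classifications: Sequence[PEMClassification],
    id_maps: Sequence[Mapping[str, str]],
) -> frozenset[str]:
    """Shared-namespace compounds that are SPO in every classification.

    ``id_maps`` gives, per classification, the mapping from local
    metabolite ids to the shared namespace; compounds without a mapping
    entry cannot match across models and are dropped.  No automatic name
    reconciliation is attempted.
    """
    if len(classifications) < 2:
        raise ValueError("need at least two classifications to compare")
    if len(id_maps) != len(classifications):
        raise ValueError("one id mapping required per classification")
    shared_sets = []
    for cl, mapping in zip(classifications, id_maps):
        if not mapping:
            raise ValueError("empty id mapping")
        spo = {
            mapping[mid]
            for mid in cl.pem_union
            if cl.venn_region(mid) == "SPO" and mid in mapping
        }
        shared_sets.append(spo)
    out = shared_sets[0]
    for s in shared_sets[1:]:
        out &= s
    return frozenset(out)


# ---------------------------------------------------------------------------
# writers

def write_classification_tsv(path, classification: PEMClassification) -> None:
    with open(path, "w") as fh:
        fh.write(
            "metabolite_id\tsustainability\tproducibility\toptimal_efficiency"
            "\tvenn_region\trole\n"
        )
        for mid in classification.metabolites:
            s, p, o = classification.flags(mid)
            fh.write(
                f"{mid}\t{int(s)}\t{int(p)}\t{int(o)}\t"
                f"{classification.venn_region(mid)}\t{classification.role(mid)}\n"
            )


def write_summary_tsv(path, summary: NetworkSummary) -> None:
    cols = [
        ("reactions", summary.n_reactions, None),
        ("metabolites", summary.n_metabolites, None),
        ("pems", summary.n_pems, summary.pct_pems),
        ("sustainability_pems", summary.n_sustainability, summary.pct_sustainability),
        ("producibility_pems", summary.n_producibility, summary.pct_producibility),
        (
            "optimal_efficiency_pems",
            summary.n_optimal_efficiency,
            summary.pct_optimal_efficiency,
        ),
    ]
    with open(path, "w") as fh:
        fh.write("quantity\tcount\tpercent_of_metabolites\n")
        for name, count, pct in cols:
            pct_s = "" if pct is None else f"{pct:.1f}"
            fh.write(f"{name}\t{count}\t{pct_s}\n")


def write_venn_json(path, classification: PEMClassification) -> None:
    with open(path, "w") as fh:
        json.dump(classification.venn_counts(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_degree_role(table: pd.DataFrame, path) -> None:
    """Stacked-bar figure of role percentages per connectivity bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roles = ("PEM", "seed", "target", "other")
    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = None
    for role in roles:
        vals = table[f"pct_{role}"]
        ax.bar(table["bin"], vals, bottom=bottom, label=role)
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel("connectivity degree bin")
    ax.set_ylabel("% of compounds")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
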