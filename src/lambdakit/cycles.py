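"""Thermodynamic-cycle bookkeeping on perturbation networks.

Compounds are nodes of a :class:`PerturbationGraph`; alchemical
transformations are edges carrying ΔΔG ± σ (or per-phase legs). Because
free energy is a state function, edge values compose additively along
paths, cancel around closed cycles, and uncertainties from independent
simulations add in quadrature.

Perturbations that change the net charge of the compound are handled the
way practitioners route them: never directly, but through the neutral
protonation state of the charged substituent, so every individual edge
either preserves net charge or changes it by exactly ±1 via a single
(de)protonation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Compound",
    "PerturbationGraph",
    "RoutingError",
    "rbfe_from_legs",
    "compose_path",
    "route_charge_change",
    "cycle_closure",
    "plan_spanning_tree",
]


class RoutingError(ValueError):
    """No admissible route exists between two compounds."""


@dataclass(frozen=True)
class Compound:
    """A node of the perturbation network.

    ``substituents`` is the base substituent name per site (protonation
    state excluded); ``protonation`` is the per-site charge offset in e
    (0 for the neutral form, +1 protonated, −1 deprotonated). The net
    charge is the base charge plus the protonation offsets.
    """

    name: str
    substituents: tuple
    net_charge: int = 0
    protonation: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "substituents", tuple(self.substituents))
        prot = tuple(self.protonation) or (0,) * len(self.substituents)
        if len(prot) != len(self.substituents):
            raise ValueError("protonation tuple must have one entry per site")
        if any(p not in (-1, 0, 1) for p in prot):
            raise ValueError("protonation offsets must be -1, 0 or +1")
        object.__setattr__(self, "protonation", prot)


def _edge_is_admissible(a: Compound, b: Compound) -> bool:
    """Edge invariant: endpoints differ somewhere; net charge preserved or
    changed by ±1 through a single-site protonation change."""
    sub_diff = sum(x != y for x, y in zip(a.substituents, b.substituents))
    prot_diff = [
        (i, x, y) for i, (x, y) in enumerate(zip(a.protonation, b.protonation)) if x != y
    ]
    if sub_diff == 0 and not prot_diff:
        return False
    dq = b.net_charge - a.net_charge
    if dq == 0:
        return not prot_diff  # charge-preserving edges may not shuffle protons
    if abs(dq) != 1:
        return False
    # a ±1 change must be exactly one protonation step, same substituents
    return (
        sub_diff == 0
        and len(prot_diff) == 1
        and prot_diff[0][2] - prot_diff[0][1] == dq
    )


@dataclass
class PerturbationGraph:
    """Compounds plus alchemical edges with free energy values.

    Edge values are stored with a direction (the ``a -> b`` used at
    insertion); retrieval in the opposite direction negates the value.
    """

    compounds: dict = field(default_factory=dict)
    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_compound(self, compound: Compound) -> None:
        if compound.name in self.compounds:
            raise ValueError(f"duplicate compound {compound.name!r}")
        self.compounds[compound.name] = compound
        self.graph.add_node(compound.name)

    def add_edge(
        self,
        a: str,
        b: str,
        ddg: float | None = None,
        sigma: float = 0.0,
        method: str = "analytic",
    ) -> None:
        ca, cb = self.compounds[a], self.compounds[b]
        if not _edge_is_admissible(ca, cb):
            raise ValueError(
                f"edge {a!r} -> {b!r} violates the perturbation-edge invariant "
                "(identical endpoints, or a net-charge change that is not a "
                "single (de)protonation)"
            )
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        self.graph.add_edge(a, b, ddg=ddg, sigma=sigma, method=method, direction=(a, b))

    def edge_value(self, a: str, b: str) -> tuple:
        """(ΔΔG, σ) of edge a -> b, sign-corrected for stored direction."""
        data = self.graph.edges[a, b]
        val = data["ddg"]
        if val is None:
            raise ValueError(f"edge {a!r} -- {b!r} carries no value")
        if data["direction"] != (a, b):
            val = -val
        return val, data["sigma"]


def rbfe_from_legs(dg_complex, dg_solution) -> tuple:
    """ΔΔG_bind from the two alchemical legs of the thermodynamic cycle.

    Each leg is (ΔG, σ); the binding free energy difference is the
    complex-leg minus solution-leg value, with leg uncertainties combined
    in quadrature (independent simulations).
    """
    for leg in (dg_complex, dg_solution):
        if leg is None or len(leg) != 2:
            raise ValueError("both legs must be provided as (value, sigma)")
    (gc, sc), (gs, ss) = dg_complex, dg_solution
    return gc - gs, math.hypot(sc, ss)


def compose_path(edges) -> tuple:
    """Sum (value, σ) edges along a path; σ adds in quadrature.

    ``edges`` is a non-empty sequence of (ΔΔG, σ) pairs, already oriented
    along the path.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("cannot compose an empty path")
    total = sum(e[0] for e in edges)
    sigma = math.sqrt(sum(e[1] ** 2 for e in edges))
    return total, sigma


def compose_graph_path(graph: PerturbationGraph, nodes) -> tuple:
    """Compose edge values along a node path of a PerturbationGraph."""
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("path must contain at least one edge")
    for a, b in zip(nodes, nodes[1:]):
        if not graph.graph.has_edge(a, b):
            raise ValueError(f"path is disconnected: no edge {a!r} -- {b!r}")
    return compose_path(graph.edge_value(a, b) for a, b in zip(nodes, nodes[1:]))


def _protonation_partners(graph: PerturbationGraph, comp: Compound):
    """Nodes reachable from ``comp`` by one (de)protonation step."""
    out = []
    for other in graph.compounds.values():
        if other.name == comp.name:
            continue
        if other.substituents != comp.substituents:
            continue
        diff = [
            (x, y)
            for x, y in zip(comp.protonation, other.protonation)
            if x != y
        ]
        if len(diff) == 1 and abs(diff[0][1] - diff[0][0]) == 1:
            out.append(other)
    return out


def route_charge_change(graph: PerturbationGraph, source: str, target: str) -> list:
    """Plan an admissible transformation path from source to target.

    Same net charge: the direct edge. Different net charge: the path runs
    through the neutral protonation form(s) of the charged endpoint(s), so
    every hop satisfies the edge invariant. Raises :class:`RoutingError`
    naming the missing neutral intermediates when no route exists.
    """
    if source not in graph.compounds or target not in graph.compounds:
        raise KeyError("source and target must be compounds of the graph")
    src, tgt = graph.compounds[source], graph.compounds[target]
    if src.net_charge == tgt.net_charge:
        return [source, target]

    # search over the admissible-move graph (virtual edges; existing edge
    # values are not required to plan a route)
    admissible = nx.Graph()
    names = list(graph.compounds)
    admissible.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if _edge_is_admissible(graph.compounds[a], graph.compounds[b]):
                admissible.add_edge(a, b)
    try:
        return nx.shortest_path(admissible, source, target)
    except nx.NetworkXNoPath:
        missing = []
        for comp in (src, tgt):
            if comp.net_charge != 0 and not _protonation_partners(graph, comp):
                missing.append(
                    f"neutral protonation form of {comp.name!r} "
                    f"(substituents {comp.substituents})"
                )
        raise RoutingError(
            "no admissible route from "
            f"{source!r} (q={src.net_charge:+d}) to {target!r} "
            f"(q={tgt.net_charge:+d}); missing intermediates: "
            + ("; ".join(missing) if missing else "none identified")
        ) from None


def cycle_closure(graph: PerturbationGraph) -> list:
    """Signed edge sums around every independent cycle of the network.

    For a state function each closed cycle must sum to zero; a cycle sum
    beyond twice its quadrature σ flags an inconsistent edge. Acyclic
    graphs yield an empty list.
    """
    results = []
    for cyc in nx.cycle_basis(graph.graph):
        nodes = cyc + [cyc[0]]
        total, sigma = compose_graph_path(graph, nodes)
        results.append(
            {
                "cycle": tuple(cyc),
                "sum": total,
                "sigma": sigma,
                "closed": abs(total) <= 2.0 * sigma + 1e-12,
            }
        )
    return results


def graph_to_json(graph: PerturbationGraph) -> str:
    """Serialize the network (compounds + valued edges) as JSON text."""
    d = {
        "compounds": [
            {
                "name": c.name,
                "substituents": list(c.substituents),
                "net_charge": c.net_charge,
                "protonation": list(c.protonation),
            }
            for c in graph.compounds.values()
        ],
        "edges": [
            {
                "a": data["direction"][0],
                "b": data["direction"][1],
                "ddg": data["ddg"],
                "sigma": data["sigma"],
                "method": data["method"],
            }
            for _, _, data in graph.graph.edges(data=True)
        ],
    }
    return json.dumps(d, indent=1)


def graph_from_json(text: str) -> PerturbationGraph:
    d = json.loads(text)
    g = PerturbationGraph()
    for c in d["compounds"]:
        g.add_compound(
            Compound(
                name=c["name"],
                substituents=tuple(c["substituents"]),
                net_charge=c.get("net_charge", 0),
                protonation=tuple(c.get("protonation", ())),
            )
        )
    for e in d.get("edges", []):
        g.add_edge(e["a"], e["b"], ddg=e.get("ddg"), sigma=e.get("sigma", 0.0),
                   method=e.get("method", "analytic"))
    return g


def plan_spanning_tree(graph: PerturbationGraph, reference: str) -> list:
    """Star/tree perturbation plan from a declared reference compound.

    Returns one routed path per non-reference compound (charge changes
    detour through neutral intermediates automatically).
    """
    if reference not in graph.compounds:
        raise KeyError(f"reference {reference!r} not in graph")
    return [
        route_charge_change(graph, reference, name)
        for name in graph.compounds
        if name != reference
    ]
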