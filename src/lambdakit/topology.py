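"""Multiple-topology ligand model.

A multiple-topology (hybrid) ligand keeps one common core scaffold with
every alternative substituent at every substitution site attached
simultaneously; λ dynamics then interpolates among them. Two bookkeeping
operations make such a model physically consistent:

* common-core identification — an exact maximum-common-substructure (MCS)
  search over the element-labeled molecular graphs of all compounds;
* charge renormalization — adjusting substituent partial charges so every
  substituent at a site carries the same net partial charge, which keeps
  the total charge of every combinatorial compound at the same integer.
  (De)protonated substituents used for net-charge perturbations are exempt
  and keep their integer charge offset.

Graphs are undirected with element-symbol labels only; no bond orders,
coordinates or force-field typing.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import isomorphism

__all__ = [
    "Atom",
    "MolGraph",
    "Substituent",
    "MultiTopology",
    "ChargeReport",
    "CoreMapping",
    "SizeLimitError",
    "ConsistencyError",
    "find_common_core",
    "renormalize_charges",
]

MCS_SIZE_LIMIT = 20
CHARGE_TOL = 1e-6


class SizeLimitError(ValueError):
    """Input too large for the exact MCS search."""


class ConsistencyError(ValueError):
    """Charge renormalization cannot reach an integer total charge."""


@dataclass(frozen=True)
class Atom:
    id: int
    element: str
    charge: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.charge):
            raise ValueError(f"atom {self.id}: charge must be finite")


@dataclass
class MolGraph:
    """Connected molecular graph: atoms with element labels and partial
    charges (e), plus bonds as atom-id pairs."""

    atoms: list
    bonds: list

    def __post_init__(self) -> None:
        self.atoms = [a if isinstance(a, Atom) else Atom(*a) for a in self.atoms]
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom ids")
        idset = set(ids)
        self.bonds = [tuple(sorted(b)) for b in self.bonds]
        for i, j in self.bonds:
            if i not in idset or j not in idset:
                raise ValueError(f"bond ({i}, {j}) references a missing atom")
            if i == j:
                raise ValueError("self-bonds are not allowed")
        g = self.to_networkx()
        if len(self.atoms) > 1 and not nx.is_connected(g):
            raise ValueError("molecular graph must be connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.id, element=a.element, charge=a.charge)
        g.add_edges_from(self.bonds)
        return g

    @property
    def net_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "atoms": [
                    {"id": a.id, "element": a.element, "charge": a.charge}
                    for a in self.atoms
                ],
                "bonds": [list(b) for b in self.bonds],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MolGraph":
        d = json.loads(text)
        return cls(
            atoms=[Atom(a["id"], a["element"], a.get("charge", 0.0)) for a in d["atoms"]],
            bonds=[tuple(b) for b in d["bonds"]],
        )


# ---------------------------------------------------------------------------
# maximum common substructure


@dataclass(frozen=True)
class CoreMapping:
    """Result of an MCS search: per-graph atom ids of the common core.

    ``mappings[g][k]`` is the atom id in graph g matched to core position
    k; size 0 means no common substructure.
    """

    size: int
    mappings: tuple

    @property
    def core_atoms(self) -> tuple:
        """Core atom ids in the first graph."""
        return self.mappings[0] if self.mappings else ()


def _connected_subsets(g: nx.Graph, size: int):
    """All connected node subsets of a given size (deterministic order)."""
    nodes = sorted(g.nodes)
    seen = set()
    for combo in itertools.combinations(nodes, size):
        if combo in seen:
            continue
        sub = g.subgraph(combo)
        if nx.is_connected(sub):
            yield combo


def _label_key(g: nx.Graph, nodes) -> tuple:
    return tuple(sorted(g.nodes[n]["element"] for n in nodes))


def _embed(candidate: nx.Graph, target: nx.Graph):
    """Smallest node-induced embedding of candidate into target, or None."""
    matcher = isomorphism.GraphMatcher(
        target,
        candidate,
        node_match=lambda a, b: a["element"] == b["element"],
    )
    best = None
    for iso in matcher.subgraph_isomorphisms_iter():
        # iso maps target-node -> candidate-node; invert to candidate order
        inv = {v: k for k, v in iso.items()}
        mapped = tuple(inv[n] for n in sorted(candidate.nodes))
        if best is None or mapped < best:
            best = mapped
    return best


def find_common_core(graphs) -> CoreMapping:
    """Largest common connected labeled subgraph of all input graphs.

    Exact search: enumerate connected node-induced subgraphs of the
    smallest input, largest first, and keep the first one that embeds in
    every other graph. Ties are broken deterministically — smallest sorted
    element-label multiset first, then smallest atom-id tuple in the first
    graph, then smallest embeddings elsewhere.

    Raises :class:`SizeLimitError` when the smallest graph exceeds
    ``MCS_SIZE_LIMIT`` atoms. An empty common substructure returns a
    size-0 mapping, not an error.
    """
    graphs = list(graphs)
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    nxg = [g.to_networkx() for g in graphs]
    smallest = min(range(len(nxg)), key=lambda i: len(nxg[i]))
    base = nxg[smallest]
    if len(base) > MCS_SIZE_LIMIT:
        raise SizeLimitError(
            f"smallest graph has {len(base)} atoms; exact MCS is limited to "
            f"{MCS_SIZE_LIMIT}"
        )
    others = [g for i, g in enumerate(nxg) if i != smallest]

    for size in range(len(base), 0, -1):
        candidates = sorted(
            _connected_subsets(base, size),
            key=lambda nodes: (_label_key(base, nodes), nodes),
        )
        for nodes in candidates:
            sub = base.subgraph(nodes)
            embeddings = []
            ok = True
            for g in others:
                emb = _embed(sub, g)
                if emb is None:
                    ok = False
                    break
                embeddings.append(emb)
            if ok:
                order = sorted(nodes)
                # report in original input order
                per_graph = []
                it = iter(embeddings)
                for i in range(len(nxg)):
                    per_graph.append(tuple(order) if i == smallest else next(it))
                return CoreMapping(size=size, mappings=tuple(per_graph))
    return CoreMapping(size=0, mappings=tuple(() for _ in graphs))


# ---------------------------------------------------------------------------
# multiple topology and charge renormalization


@dataclass
class Substituent:
    """A fragment attached to the core at one site via an anchor atom."""

    name: str
    fragment: MolGraph
    anchor: int  # core atom id the fragment attaches to
    charge_offset: int = 0  # integer offset for (de)protonated forms

    @property
    def net_charge(self) -> float:
        return self.fragment.net_charge


@dataclass
class MultiTopology:
    """Core + per-site substituent sets, with cross-substituent exclusions.

    Every non-core atom belongs to exactly one substituent; the exclusion
    list enumerates all interaction pairs spanning two substituents at the
    same site (no internal energy term may span them).
    """

    core: MolGraph
    sites: list  # list of list[Substituent]
    net_charge: int | None = None
    exclusions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        core_ids = {a.id for a in self.core.atoms}
        seen: set = set()
        for subs in self.sites:
            if not subs:
                raise ValueError("every site needs at least one substituent")
            for sub in subs:
                if sub.anchor not in core_ids:
                    raise ValueError(
                        f"substituent {sub.name!r}: anchor {sub.anchor} not in core"
                    )
                ids = {(sub.name, a.id) for a in sub.fragment.atoms}
                frag_ids = {a.id for a in sub.fragment.atoms}
                if frag_ids & core_ids:
                    raise ValueError(
                        f"substituent {sub.name!r} reuses core atom ids"
                    )
                if ids & seen:
                    raise ValueError("atoms shared between substituents")
                seen |= ids
        if self.net_charge is None:
            ref_total = self.core.net_charge + sum(
                subs[0].net_charge for subs in self.sites
            )
            self.net_charge = round(ref_total)
        self.exclusions = list(self.exclusions) or self._build_exclusions()

    def _build_exclusions(self) -> list:
        """All atom pairs spanning two substituents at one site."""
        out = []
        for s, subs in enumerate(self.sites):
            for a, b in itertools.combinations(subs, 2):
                for ai in a.fragment.atoms:
                    for bi in b.fragment.atoms:
                        out.append(((s, a.name, ai.id), (s, b.name, bi.id)))
        return out

    def compound_charge(self, choice) -> float:
        """Total charge of the compound picking one substituent per site."""
        total = self.core.net_charge
        for s, name in enumerate(choice):
            sub = self.substituent(s, name)
            total += sub.net_charge
        return total

    def substituent(self, site: int, name: str) -> Substituent:
        for sub in self.sites[site]:
            if sub.name == name:
                return sub
        raise KeyError(f"no substituent {name!r} at site {site}")

    def combinations(self):
        """All combinatorial compounds (one substituent name per site)."""
        return itertools.product(*[[s.name for s in subs] for subs in self.sites])


@dataclass
class ChargeReport:
    """Per-atom adjustments from charge renormalization.

    ``adjustments[(site, sub_name, atom_id)]`` in e; ``rmsd`` is the RMS
    adjustment over all atoms of renormalized substituents; ``targets[s]``
    the per-site target net charge.
    """

    adjustments: dict
    rmsd: float
    targets: list

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def renormalize_charges(topology: MultiTopology, exempt=()) -> tuple:
    """Equalize substituent net charges per site; return (topology, report).

    The per-site target net charge is the arithmetic mean of the
    non-exempt substituent nets; each substituent's correction is spread
    uniformly over its atoms (smallest maximum per-atom perturbation).
    Exempt substituents — (de)protonated forms used for net-charge
    perturbations, given as (site, name) pairs — keep their charges and
    their integer offset.

    Raises :class:`ConsistencyError` if any combinatorial compound's total
    charge lands away from its declared integer.
    """
    exempt = {tuple(e) for e in exempt}
    for s, name in exempt:
        topology.substituent(s, name)  # raises KeyError if missing

    new_sites = []
    adjustments = {}
    targets = []
    sq_sum = 0.0
    n_atoms = 0
    for s, subs in enumerate(topology.sites):
        active = [sub for sub in subs if (s, sub.name) not in exempt]
        if not active:
            raise ValueError(f"site {s}: every substituent is exempt")
        target = sum(sub.net_charge for sub in active) / len(active)
        targets.append(target)
        new_subs = []
        for sub in subs:
            if (s, sub.name) in exempt:
                new_subs.append(sub)
                continue
            per_atom = (target - sub.net_charge) / len(sub.fragment)
            atoms = [
                Atom(a.id, a.element, a.charge + per_atom) for a in sub.fragment.atoms
            ]
            for a in sub.fragment.atoms:
                adjustments[(s, sub.name, a.id)] = per_atom
                sq_sum += per_atom**2
                n_atoms += 1
            new_subs.append(
                Substituent(
                    name=sub.name,
                    fragment=MolGraph(atoms=atoms, bonds=list(sub.fragment.bonds)),
                    anchor=sub.anchor,
                    charge_offset=sub.charge_offset,
                )
            )
        new_sites.append(new_subs)

    result = MultiTopology(
        core=topology.core,
        sites=new_sites,
        net_charge=topology.net_charge,
        exclusions=list(topology.exclusions),
    )

    # integer-consistency check over the full combinatorial space
    for choice in result.combinations():
        total = result.compound_charge(choice)
        offset = sum(
            result.substituent(s, name).charge_offset
            for s, name in enumerate(choice)
        )
        expected = result.net_charge + offset
        if abs(total - expected) > CHARGE_TOL:
            raise ConsistencyError(
                f"compound {choice} has total charge {total:.6f}, expected the "
                f"integer {expected}"
            )

    rmsd = math.sqrt(sq_sum / n_atoms) if n_atoms else 0.0
    return result, ChargeReport(adjustments=adjustments, rmsd=rmsd, targets=targets)
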