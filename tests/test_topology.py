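"""Multiple-topology model: MCS search and charge renormalization."""

import itertools
import math

import numpy as np
import pytest

from lambdakit.topology import (
    Atom,
    ConsistencyError,
    MolGraph,
    MultiTopology,
    SizeLimitError,
    Substituent,
    find_common_core,
    renormalize_charges,
)


def linear(elements, start_id=0, charges=None):
    charges = charges or [0.0] * len(elements)
    atoms = [Atom(start_id + i, e, q) for i, (e, q) in enumerate(zip(elements, charges))]
    bonds = [(start_id + i, start_id + i + 1) for i in range(len(elements) - 1)]
    return MolGraph(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# MolGraph validation


def test_molgraph_rejects_disconnected():
    with pytest.raises(ValueError, match="connected"):
        MolGraph(atoms=[Atom(0, "C"), Atom(1, "C")], bonds=[])


def test_molgraph_rejects_dangling_bond():
    with pytest.raises(ValueError, match="missing atom"):
        MolGraph(atoms=[Atom(0, "C"), Atom(1, "C")], bonds=[(0, 2)])


def test_molgraph_json_roundtrip():
    g = linear("CCO", charges=[0.1, -0.2, 0.05])
    g2 = MolGraph.from_json(g.to_json())
    assert g2.atoms == g.atoms and g2.bonds == g.bonds


# ---------------------------------------------------------------------------
# maximum common substructure


def test_mcs_identical_graphs_map_fully():
    g1 = linear("CCOCN")
    g2 = linear("CCOCN")
    core = find_common_core([g1, g2])
    assert core.size == 5
    assert core.mappings[0] == (0, 1, 2, 3, 4)


def test_mcs_linear_cco_vs_ccn_is_cc():
    core = find_common_core([linear("CCO"), linear("CCN")])
    assert core.size == 2
    # the shared fragment is the C-C pair
    assert core.mappings[0] == (0, 1)
    assert core.mappings[1] == (0, 1)


def test_mcs_disjoint_labels_empty_core():
    core = find_common_core([linear("CC"), linear("NO")])
    assert core.size == 0
    assert core.core_atoms == ()


def test_mcs_size_limit():
    big = linear("C" * 25)
    with pytest.raises(SizeLimitError):
        find_common_core([big, big])


def test_mcs_deterministic():
    g1 = linear("CNC")
    g2 = linear("CNO")
    assert find_common_core([g1, g2]) == find_common_core([g1, g2])


# --- brute-force oracle ----------------------------------------------------


def _oracle_mcs_size(g1: MolGraph, g2: MolGraph) -> int:
    """Exhaustive max common connected node-induced subgraph size.

    Fully independent route: enumerate node subsets of g1, check
    connectivity by flood fill, and search label- and edge-preserving
    injections into g2 by raw permutation.
    """
    n1 = {a.id: a.element for a in g1.atoms}
    n2 = {a.id: a.element for a in g2.atoms}
    e1 = {frozenset(b) for b in g1.bonds}
    e2 = {frozenset(b) for b in g2.bonds}

    def connected(nodes, edges):
        nodes = set(nodes)
        if len(nodes) <= 1:
            return True
        seen = {next(iter(nodes))}
        frontier = list(seen)
        while frontier:
            v = frontier.pop()
            for e in edges:
                if v in e:
                    (w,) = e - {v}
                    if w in nodes and w not in seen:
                        seen.add(w)
                        frontier.append(w)
        return seen == nodes

    best = 0
    ids1 = list(n1)
    for size in range(len(ids1), 0, -1):
        if size <= best:
            break
        for sub in itertools.combinations(ids1, size):
            sub_edges = {e for e in e1 if e <= set(sub)}
            if not connected(sub, sub_edges):
                continue
            for target in itertools.permutations(n2, size):
                phi = dict(zip(sub, target))
                if any(n1[a] != n2[phi[a]] for a in sub):
                    continue
                # node-induced: edges must correspond both ways
                mapped = {frozenset({phi[a], phi[b]}) for a, b in
                          (tuple(e) for e in sub_edges)}
                induced_target = {e for e in e2 if e <= set(target)}
                if mapped == induced_target:
                    best = max(best, size)
                    break
            if best == size:
                break
    return best


def _random_molgraph(rng, n, labels="CNO"):
    """Random connected labeled graph built from a spanning tree + extra edges."""
    atoms = [Atom(i, labels[rng.integers(len(labels))]) for i in range(n)]
    bonds = [(int(rng.integers(i)), i) for i in range(1, n)]
    for _ in range(int(rng.integers(0, n))):
        i, j = rng.integers(0, n, size=2)
        if i != j and tuple(sorted((int(i), int(j)))) not in bonds:
            bonds.append(tuple(sorted((int(i), int(j)))))
    return MolGraph(atoms=atoms, bonds=bonds)


@pytest.mark.parametrize("case_seed", range(12))
def test_mcs_matches_bruteforce_oracle(case_seed):
    rng = np.random.default_rng(900 + case_seed)
    g1 = _random_molgraph(rng, int(rng.integers(3, 8)))
    g2 = _random_molgraph(rng, int(rng.integers(3, 8)))
    core = find_common_core([g1, g2])
    assert core.size == _oracle_mcs_size(g1, g2)
    if core.size:
        # returned mapping is a genuine common induced subgraph
        m1, m2 = core.mappings
        lab1 = {a.id: a.element for a in g1.atoms}
        lab2 = {a.id: a.element for a in g2.atoms}
        assert [lab1[i] for i in m1] == [lab2[i] for i in m2]
        e1 = {frozenset(b) for b in g1.bonds}
        e2 = {frozenset(b) for b in g2.bonds}
        for (p, q) in itertools.combinations(range(core.size), 2):
            in1 = frozenset({m1[p], m1[q]}) in e1
            in2 = frozenset({m2[p], m2[q]}) in e2
            assert in1 == in2


# ---------------------------------------------------------------------------
# charge renormalization


def _two_sub_topology(qa=(0.05, 0.05), qb=(-0.02,), core_q=-0.04, offsets=(0, 0)):
    core = MolGraph(atoms=[Atom(0, "C", core_q)], bonds=[])
    sub_a = Substituent(
        name="A",
        fragment=MolGraph(
            atoms=[Atom(10, "C", qa[0])] + [Atom(11 + i, "H", q) for i, q in enumerate(qa[1:])],
            bonds=[(10, 11 + i) for i in range(len(qa) - 1)],
        ),
        anchor=0,
        charge_offset=offsets[0],
    )
    sub_b = Substituent(
        name="B",
        fragment=MolGraph(atoms=[Atom(20, "N", qb[0])], bonds=[]),
        anchor=0,
        charge_offset=offsets[1],
    )
    return MultiTopology(core=core, sites=[[sub_a, sub_b]], net_charge=0)


def test_renormalize_uniform_distribution_example():
    # A: 2 atoms net +0.10; B: 1 atom net -0.02 -> target +0.04
    topo = _two_sub_topology()
    out, report = renormalize_charges(topo)
    a = out.substituent(0, "A")
    b = out.substituent(0, "B")
    assert a.net_charge == pytest.approx(0.04)
    assert b.net_charge == pytest.approx(0.04)
    assert [atom.charge for atom in a.fragment.atoms] == pytest.approx([0.02, 0.02])
    assert b.fragment.atoms[0].charge == pytest.approx(0.04)
    assert report.targets == [pytest.approx(0.04)]
    expected_rmsd = math.sqrt((2 * 0.03**2 + 0.06**2) / 3)
    assert report.rmsd == pytest.approx(expected_rmsd)
    assert report.rmsd == pytest.approx(0.0424, abs=1e-4)


def test_renormalize_already_equal_is_noop():
    topo = _two_sub_topology(qa=(0.02, 0.02), qb=(0.04,), core_q=-0.04)
    out, report = renormalize_charges(topo)
    assert report.rmsd == 0.0
    assert all(a == 0.0 for a in report.adjustments.values())


def test_renormalize_adjustment_sums_match_contract():
    topo = _two_sub_topology()
    _, report = renormalize_charges(topo)
    # per substituent, adjustments sum to (target - original net)
    adj_a = sum(v for (s, n, _), v in report.adjustments.items() if n == "A")
    adj_b = sum(v for (s, n, _), v in report.adjustments.items() if n == "B")
    assert adj_a == pytest.approx(0.04 - 0.10)
    assert adj_b == pytest.approx(0.04 - (-0.02))


def test_renormalize_exempt_substituent_unchanged():
    # B is a deprotonated form carrying integer offset -1
    topo = _two_sub_topology(qa=(0.02, 0.02), qb=(-0.96,), core_q=-0.04, offsets=(0, -1))
    out, report = renormalize_charges(topo, exempt=[(0, "B")])
    assert out.substituent(0, "B").fragment.atoms[0].charge == pytest.approx(-0.96)
    assert all(n != "B" for (_, n, _) in report.adjustments)
    # target excludes the exempt substituent
    assert report.targets == [pytest.approx(0.04)]


def test_renormalize_idempotent():
    topo = _two_sub_topology()
    once, _ = renormalize_charges(topo)
    twice, report2 = renormalize_charges(once)
    assert report2.rmsd == pytest.approx(0.0, abs=1e-12)
    for s, name in [(0, "A"), (0, "B")]:
        q1 = [a.charge for a in once.substituent(s, name).fragment.atoms]
        q2 = [a.charge for a in twice.substituent(s, name).fragment.atoms]
        assert q2 == pytest.approx(q1)


def test_charge_conservation_over_full_enumeration():
    # two sites, uneven nets; core absorbs the residual to integer 0
    core = MolGraph(atoms=[Atom(0, "C", -0.11)], bonds=[])
    site1 = [
        Substituent("p", linear("CH", start_id=10, charges=[0.05, 0.03]), anchor=0),
        Substituent("q", linear("N", start_id=20, charges=[0.12]), anchor=0),
        Substituent("r", linear("OH", start_id=30, charges=[-0.11, 0.15]), anchor=0),
    ]
    site2 = [
        Substituent("x", linear("C", start_id=40, charges=[0.01]), anchor=0),
        Substituent("y", linear("S", start_id=50, charges=[0.05]), anchor=0),
    ]
    topo = MultiTopology(core=core, sites=[site1, site2], net_charge=0)
    out, _ = renormalize_charges(topo)
    for choice in out.combinations():
        assert out.compound_charge(choice) == pytest.approx(0.0, abs=1e-9)


def test_non_integer_total_raises_consistency_error():
    # core does not absorb the site target -> total 0.04 != integer
    topo = _two_sub_topology(core_q=0.0)
    with pytest.raises(ConsistencyError):
        renormalize_charges(topo)


def test_exclusion_list_spans_all_cross_substituent_pairs():
    topo = _two_sub_topology()
    # A has 2 atoms, B has 1 -> 2 cross pairs at the site
    assert len(topo.exclusions) == 2
    for (sa, na, _), (sb, nb, _) in topo.exclusions:
        assert sa == sb and {na, nb} == {"A", "B"}
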