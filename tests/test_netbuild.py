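"""Anchored subnetwork construction and contiguity pruning against brute force."""

import warnings

import networkx as nx
import numpy as np
import pytest

from ctdnet import (
    AnchorSpec,
    AnnotationMap,
    Category,
    RegulationCall,
    build_interactome,
    category_subnetwork,
    classify_nodes,
    first_interactors,
    merge,
    nodes_on_anchor_paths,
    prune_anchored,
)
from ctdnet.io_formats import InteractionRecord

from conftest import random_prune_instance, simple_path_nodes_oracle


def _calls(up=(), down=(), unchanged=()):
    return RegulationCall(frozenset(up), frozenset(down), frozenset(unchanged))


def _chain(*nodes):
    g = nx.Graph()
    for u, v in zip(nodes, nodes[1:]):
        g.add_edge(u, v, evidence=frozenset({"physical"}))
    return g


# --- interactome construction -------------------------------------------

def test_build_interactome_dedupes_and_merges_evidence():
    records = [
        InteractionRecord("A", "B", "two-hybrid"),
        InteractionRecord("B", "A", "affinity"),
        InteractionRecord("A", "A", "self"),
    ]
    g = build_interactome(records)
    assert g.number_of_edges() == 1
    assert g["A"]["B"]["evidence"] == {"two-hybrid", "affinity"}
    assert not g.has_edge("A", "A")
    g_self = build_interactome(records, keep_self=True)
    assert g_self.has_edge("A", "A")


def test_first_interactors_star_and_self_loop():
    g = nx.Graph([("X", "A"), ("X", "B"), ("X", "C")])
    assert first_interactors(g, "X") == {"A", "B", "C"}
    loop = nx.Graph()
    loop.add_edge("X", "X")
    assert first_interactors(loop, "X") == frozenset()
    with pytest.raises(KeyError):
        first_interactors(g, "MISSING")


def test_first_interactors_matches_adjacency_oracle():
    rng = np.random.default_rng(2)
    g = nx.gnp_random_graph(50, 0.1, seed=3)
    adj = nx.to_numpy_array(g)
    for node in range(50):
        expected = {j for j in range(50) if adj[node, j]}
        assert first_interactors(g, node) == expected


# --- category subnetworks -----------------------------------------------

def test_category_subnetwork_seed_plus_neighbors():
    g = nx.Graph([("X", "Y"), ("X", "Z"), ("Y", "Z"), ("Z", "W")])
    calls = _calls(up={"X"}, unchanged={"Y", "Z", "W"})
    ann = AnnotationMap([Category("C", "c", frozenset({"X"}))])
    sub = category_subnetwork(g, calls, ann, {"C"})
    assert set(sub.nodes) == {"X", "Y", "Z"}
    assert set(map(frozenset, sub.edges)) == {frozenset({"X", "Y"}), frozenset({"X", "Z"})}
    full = category_subnetwork(g, calls, ann, {"C"}, include_neighbor_edges=True)
    assert full.has_edge("Y", "Z")


def test_category_subnetwork_empty_seed_warns():
    g = nx.Graph([("A", "B")])
    calls = _calls(unchanged={"A", "B"})
    ann = AnnotationMap([Category("C", "c", frozenset({"A"}))])
    with pytest.warns(UserWarning):
        sub = category_subnetwork(g, calls, ann, {"C"})
    assert sub.number_of_nodes() == 0


def test_category_subnetwork_matches_edge_filter_oracle():
    rng = np.random.default_rng(4)
    g = nx.gnp_random_graph(40, 0.12, seed=5)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    nodes = sorted(g.nodes)
    de = set(nodes[:15])
    members = set(nodes[5:20])
    calls = _calls(up=de, unchanged=set(nodes) - de)
    ann = AnnotationMap([Category("C", "c", frozenset(members))])
    sub = category_subnetwork(g, calls, ann, {"C"})
    seeds = de & members
    expected_edges = {frozenset(e) for e in g.edges if seeds & set(e)}
    assert {frozenset(e) for e in sub.edges} == expected_edges


def test_merge_idempotent_and_additive():
    a = _chain("A", "B", "C")
    assert nx.utils.graphs_equal(merge([a, a]), a)
    b = _chain("X", "Y")
    m = merge([a, b])
    assert m.number_of_nodes() == 5 and m.number_of_edges() == 3
    # evidence tags pool per edge
    a2 = _chain("A", "B")
    a2["A"]["B"]["evidence"] = frozenset({"genetic"})
    assert merge([a, a2])["A"]["B"]["evidence"] == {"physical", "genetic"}


# --- pruning -------------------------------------------------------------

def test_prune_minimal_contiguous_chain():
    g = _chain("RPB1", "I", "G")
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    calls = _calls(down={"G"}, unchanged={"I"})
    net = prune_anchored(g, spec, calls)
    assert set(net.graph.nodes) == {"RPB1", "I", "G"}
    assert net.role == {"RPB1": "anchor", "I": "interactor", "G": "de_gene"}
    net.validate()


def test_prune_breaks_on_inadmissible_node():
    """A non-evidence, non-DE node interrupts contiguity; only the anchor survives."""
    g = _chain("RPB1", "I", "X", "G")
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    calls = _calls(down={"G"}, unchanged={"I", "X"})
    net = prune_anchored(g, spec, calls)
    assert set(net.graph.nodes) == {"RPB1"}


def test_prune_drops_de_gene_behind_inadmissible_node():
    g = _chain("RPB1", "I", "G")
    g.add_edge("X", "H", evidence=frozenset())
    g.add_edge("I", "X", evidence=frozenset())
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    calls = _calls(down={"G", "H"}, unchanged={"I", "X"})
    net = prune_anchored(g, spec, calls)
    assert "H" not in net.graph
    assert set(net.graph.nodes) == {"RPB1", "I", "G"}


def test_prune_missing_anchor_raises():
    g = _chain("A", "B")
    spec = AnchorSpec("RPB1", frozenset({"A"}))
    with pytest.raises(KeyError):
        prune_anchored(g, spec, _calls(up={"B"}))


def test_prune_adds_anchor_star_from_interactome():
    interactome = _chain("G", "I", "RPB1")
    g = _chain("I", "G")  # category net without the anchor
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    net = prune_anchored(g, spec, _calls(up={"G"}), interactome=interactome)
    assert set(net.graph.nodes) == {"RPB1", "I", "G"}


def test_prune_node_in_evidence_and_de_is_de():
    g = _chain("RPB1", "I")
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    net = prune_anchored(g, spec, _calls(up={"I"}))
    assert net.role["I"] == "de_gene"
    assert net.regulation["I"] == "up"


def test_prune_matches_simple_path_oracle_on_random_graphs():
    """Node sets equal the exhaustive all-simple-paths enumeration on small graphs."""
    rng = np.random.default_rng(17)
    for _ in range(150):
        g, anchor, evidence, de = random_prune_instance(rng)
        spec = AnchorSpec(anchor, evidence)
        calls = _calls(up=de, unchanged=set(g.nodes) - de - {anchor})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = prune_anchored(g, spec, calls)
        admissible = {anchor} | set(evidence) | (de - {anchor})
        induced = g.subgraph(admissible & set(g.nodes))
        comp = nx.node_connected_component(induced, anchor)
        expected = simple_path_nodes_oracle(induced.subgraph(comp), anchor, de & comp)
        assert set(net.graph.nodes) == set(expected)
        net.validate()


def test_relaxed_mode_is_monotone_over_strict():
    """Enlarging the bridge set from evidence to all first interactors never removes nodes."""
    rng = np.random.default_rng(23)
    checked = 0
    for _ in range(120):
        g, anchor, evidence, de = random_prune_instance(rng)
        # evidence interactors are by definition first interactors of the anchor
        evidence = evidence & first_interactors(g, anchor)
        if not evidence:
            continue
        calls = _calls(up=de, unchanged=set(g.nodes) - de - {anchor})
        strict = prune_anchored(g, AnchorSpec(anchor, evidence, "strict"), calls)
        relaxed = prune_anchored(g, AnchorSpec(anchor, mode="relaxed"), calls)
        assert set(strict.graph.nodes) <= set(relaxed.graph.nodes)
        checked += 1
    assert checked > 30


def test_prune_independent_of_insertion_order():
    g1 = _chain("RPB1", "I", "G")
    g2 = nx.Graph()
    g2.add_edge("I", "G", evidence=frozenset({"physical"}))
    g2.add_edge("RPB1", "I", evidence=frozenset({"physical"}))
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    calls = _calls(up={"G"}, unchanged={"I"})
    assert prune_anchored(g1, spec, calls) == prune_anchored(g2, spec, calls)


def test_relaxed_de_filter_restricts_endpoints():
    g = _chain("RPB1", "I", "G")
    g.add_edge("I", "H", evidence=frozenset())
    calls = _calls(up={"G", "H"}, unchanged={"I"})
    spec = AnchorSpec("RPB1", mode="relaxed")
    full = prune_anchored(g, spec, calls)
    assert {"G", "H"} <= set(full.graph.nodes)
    filtered = prune_anchored(g, spec, calls, de_filter={"G"})
    assert "H" not in filtered.graph


def test_strict_mode_requires_evidence():
    with pytest.raises(ValueError):
        AnchorSpec("RPB1", frozenset(), "strict")


def test_planted_connector_recovery(small_study):
    """The planted mediator-like connector appears in every category network,
    and vanishes from all of them when removed from the evidence list."""
    from ctdnet import call_regulation, filter_annotated

    calls = call_regulation(small_study.expression)
    filtered, _ = filter_annotated(calls, small_study.annotation)
    connectors = set(small_study.truth["connectors"])
    for cid in small_study.truth["phenotype_categories"]:
        sub = category_subnetwork(small_study.interactome, filtered, small_study.annotation, {cid})
        net = prune_anchored(sub, small_study.anchor_spec, filtered, interactome=small_study.interactome)
        assert net.nodes_with_role("interactor") == connectors
        reduced = AnchorSpec(
            small_study.anchor_spec.anchor,
            small_study.anchor_spec.evidence_interactors - connectors,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            without = prune_anchored(sub, reduced, filtered, interactome=small_study.interactome)
        assert not connectors & set(without.graph.nodes)


# --- node classification --------------------------------------------------

def test_classify_nodes_legend_mapping():
    g = _chain("RPB1", "I", "G")
    g.add_edge("I", "U", evidence=frozenset())
    spec = AnchorSpec("RPB1", frozenset({"I"}))
    calls = _calls(up={"U"}, down={"G"}, unchanged={"I"})
    net = prune_anchored(g, spec, calls)
    table = classify_nodes(net).set_index("node")
    assert table.loc["RPB1", "color"] == "pink"
    assert table.loc["I", "color"] == "lightblue"
    assert table.loc["G", "color"] == "red"
    assert table.loc["U", "color"] == "green"
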