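"""Anchored phenotype-category subnetworks from a protein-interaction graph.

The pipeline implemented here connects one anchor protein (the RPB1/RPO21
role: the RNAP II largest subunit, whose C-terminal domain is the mutated
element) to differentially expressed (DE) genes grouped by phenotype-related
GO categories:

1. for each category, take the DE genes annotated to it as seeds and pull in
   their direct interactions (edges incident to a seed);
2. merge the per-category networks with the anchor's first-interaction star;
3. prune to the *contiguous* core: keep exactly the nodes lying on at least
   one simple path from the anchor to a DE gene whose every node is
   admissible — the anchor, a DE gene, or a bridge interactor.  In strict
   mode the bridge set is the curated CTD-evidence interactor list; in
   relaxed mode it is every first interactor of the anchor.

Graphs are undirected :class:`networkx.Graph` objects; each edge carries a
frozenset attribute ``evidence`` of experimental-system tags, which never
affects topology, only reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import AnnotationMap
from .expression import RegulationCall

__all__ = [
    "AnchorSpec",
    "AnchoredSubnetwork",
    "build_interactome",
    "first_interactors",
    "category_subnetwork",
    "merge",
    "prune_anchored",
    "nodes_on_anchor_paths",
    "classify_nodes",
    "NODE_COLORS",
]

ROLE_ANCHOR = "anchor"
ROLE_INTERACTOR = "interactor"
ROLE_DE = "de_gene"

# Figure-legend colour semantics: the anchor is a pink diamond, bridge
# interactors (no regulation change) light blue, DE genes red (down) or
# green (up).  Plain blue is the fallback for an interactor that does carry
# a regulation call (possible only with non-default role assignment).
NODE_COLORS = {
    (ROLE_ANCHOR, "up"): "pink",
    (ROLE_ANCHOR, "down"): "pink",
    (ROLE_ANCHOR, "unchanged"): "pink",
    (ROLE_DE, "up"): "green",
    (ROLE_DE, "down"): "red",
    (ROLE_DE, "unchanged"): "lightblue",
    (ROLE_INTERACTOR, "unchanged"): "lightblue",
    (ROLE_INTERACTOR, "up"): "blue",
    (ROLE_INTERACTOR, "down"): "blue",
}


@dataclass(frozen=True)
class AnchorSpec:
    """The anchor gene and its evidence-qualified bridge interactors.

    ``mode="strict"`` admits only ``evidence_interactors`` (interactors with
    characterized CTD-binding evidence) as bridges; ``mode="relaxed"`` admits
    every first interactor of the anchor.
    """

    anchor: str
    evidence_interactors: frozenset[str] = frozenset()
    mode: str = "strict"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise ValueError(f"mode must be 'strict' or 'relaxed', got {self.mode!r}")
        if self.mode == "strict" and not self.evidence_interactors:
            raise ValueError("strict mode requires a non-empty evidence_interactors set")
        object.__setattr__(self, "evidence_interactors", frozenset(self.evidence_interactors))


@dataclass
class AnchoredSubnetwork:
    """A pruned anchored subnetwork with per-node role and regulation state."""

    graph: nx.Graph
    role: dict[str, str]
    regulation: dict[str, str]

    @property
    def anchor(self) -> str:
        anchors = [n for n, r in self.role.items() if r == ROLE_ANCHOR]
        if len(anchors) != 1:
            raise ValueError(f"expected exactly one anchor, found {len(anchors)}")
        return anchors[0]

    def nodes_with_role(self, role: str) -> frozenset[str]:
        return frozenset(n for n in self.graph.nodes if self.role.get(n) == role)

    def validate(self) -> None:
        """Check the structural invariants of a pruned subnetwork."""
        nodes = set(self.graph.nodes)
        if set(self.role) != nodes or set(self.regulation) != nodes:
            raise ValueError("role/regulation maps must cover exactly the graph nodes")
        anchor = self.anchor  # raises unless exactly one
        bad = {n for n, r in self.role.items() if r not in (ROLE_ANCHOR, ROLE_INTERACTOR, ROLE_DE)}
        if bad:
            raise ValueError(f"unknown roles for nodes {sorted(bad)}")
        if nodes != {anchor} and not nx.is_connected(self.graph):
            raise ValueError("subnetwork must be connected")
        de = self.nodes_with_role(ROLE_DE)
        if len(nodes) > 1:
            on_paths = nodes_on_anchor_paths(self.graph, anchor, de)
            if on_paths != nodes:
                raise ValueError(
                    f"nodes not on any anchor-DE path: {sorted(nodes - on_paths)}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnchoredSubnetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and {frozenset(e) for e in self.graph.edges} == {frozenset(e) for e in other.graph.edges}
            and self.role == other.role
            and self.regulation == other.regulation
        )


def _merge_evidence(a: frozenset[str] | None, b: frozenset[str] | None) -> frozenset[str]:
    return frozenset(a or ()) | frozenset(b or ())


def build_interactome(
    records: Iterable,
    keep_self: bool = False,
) -> nx.Graph:
    """Build a deduplicated undirected interactome from interaction records.

    Duplicate edges collapse to one, pooling their evidence tags; self
    interactions are dropped unless ``keep_self`` (they cannot participate in
    anchor-to-DE paths).
    """
    g = nx.Graph()
    for rec in records:
        a, b = rec.gene_a, rec.gene_b
        if a == b and not keep_self:
            continue
        ev = frozenset({rec.evidence}) if rec.evidence else frozenset()
        if g.has_edge(a, b):
            g[a][b]["evidence"] = _merge_evidence(g[a][b].get("evidence"), ev)
        else:
            g.add_edge(a, b, evidence=ev)
    return g


def first_interactors(g: nx.Graph, anchor: str) -> frozenset[str]:
    """Open neighborhood of the anchor (self-loops excluded)."""
    if anchor not in g:
        raise KeyError(f"anchor {anchor!r} not present in the interactome")
    return frozenset(n for n in g.neighbors(anchor) if n != anchor)


def category_subnetwork(
    g: nx.Graph,
    calls: RegulationCall,
    ann: AnnotationMap,
    categories: Iterable[str],
    include_neighbor_edges: bool = False,
) -> nx.Graph:
    """Direct-interaction network of the DE genes annotated to *categories*.

    Seeds are DE genes annotated to any listed category.  Returned nodes are
    the seeds plus their interaction partners; returned edges are the edges
    incident to a seed (with ``include_neighbor_edges`` additionally the
    edges among the partners, i.e. the full induced subgraph).
    """
    categories = set(categories)
    if not categories:
        raise ValueError("categories must be non-empty")
    members: set[str] = set()
    for cid in categories:
        cat = ann.categories.get(cid)
        if cat is not None:
            members |= cat.members
    seeds = calls.de & members
    sub = nx.Graph()
    if not seeds:
        warnings.warn("empty seed set: no DE gene annotated to the requested categories")
        return sub
    sub.add_nodes_from(seeds)
    for s in seeds:
        if s not in g:
            continue
        for nb, data in g.adj[s].items():
            sub.add_edge(s, nb, evidence=frozenset(data.get("evidence", ())))
    if include_neighbor_edges:
        nodes = set(sub.nodes)
        for u, v, data in g.subgraph(nodes).edges(data=True):
            if not sub.has_edge(u, v):
                sub.add_edge(u, v, evidence=frozenset(data.get("evidence", ())))
    return sub


def merge(nets: Sequence[nx.Graph]) -> nx.Graph:
    """Node/edge union of networks, pooling per-edge evidence tags."""
    out = nx.Graph()
    for net in nets:
        out.add_nodes_from(net.nodes)
        for u, v, data in net.edges(data=True):
            ev = frozenset(data.get("evidence", ()))
            if out.has_edge(u, v):
                out[u][v]["evidence"] = _merge_evidence(out[u][v].get("evidence"), ev)
            else:
                out.add_edge(u, v, evidence=ev)
    return out


def nodes_on_anchor_paths(g: nx.Graph, anchor: str, targets: Iterable[str]) -> frozenset[str]:
    """Nodes lying on at least one simple path from *anchor* to any target.

    Computed through the block-cut tree: the vertices on some simple s-t path
    are exactly the union of the biconnected components along the unique
    block-cut-tree path between s and t.  Equivalent to (but far cheaper
    than) enumerating all simple paths.
    """
    targets = {t for t in targets if t in g and nx.has_path(g, anchor, t)}
    kept = {anchor}
    targets.discard(anchor)
    if not targets:
        return frozenset(kept)
    comp = g.subgraph(nx.node_connected_component(g, anchor))
    bicomps = list(nx.biconnected_components(comp))
    cuts = set(nx.articulation_points(comp))
    tree = nx.Graph()
    vertex_block: dict[str, tuple] = {}
    for i, block in enumerate(bicomps):
        bnode = ("B", i)
        tree.add_node(bnode)
        for v in block:
            if v in cuts:
                tree.add_edge(bnode, ("C", v))
            else:
                vertex_block[v] = bnode

    def rep(v: str) -> tuple:
        return ("C", v) if v in cuts else vertex_block[v]

    source = rep(anchor)
    for t in targets:
        for node in nx.shortest_path(tree, source, rep(t)):
            if node[0] == "B":
                kept |= bicomps[node[1]]
    return frozenset(kept)


def prune_anchored(
    g: nx.Graph,
    spec: AnchorSpec,
    calls: RegulationCall,
    interactome: nx.Graph | None = None,
    de_filter: Iterable[str] | None = None,
) -> AnchoredSubnetwork:
    """Prune a merged category network to contiguous anchor-to-DE paths.

    The admissible node set is ``{anchor} | E | D`` where ``D`` is the DE
    genes present in the graph and ``E`` the bridge set (evidence interactors
    in strict mode, all first interactors in relaxed mode).  The result is
    the set of admissible nodes lying on at least one simple path between the
    anchor and a DE gene, with the induced edges; it degenerates to the lone
    anchor when no DE gene is reachable.

    If *interactome* is given, the anchor and its first-interaction star are
    unioned into the graph first.  *de_filter*, when given, restricts the DE
    endpoint set to a curated gene list (the relaxed-mode phenotype-evidence
    filter); bridge admissibility is unaffected.
    """
    work = g.copy()
    if interactome is not None and spec.anchor in interactome:
        work.add_node(spec.anchor)
        for nb, data in interactome.adj[spec.anchor].items():
            if nb == spec.anchor:
                continue
            ev = frozenset(data.get("evidence", ()))
            if work.has_edge(spec.anchor, nb):
                work[spec.anchor][nb]["evidence"] = _merge_evidence(
                    work[spec.anchor][nb].get("evidence"), ev
                )
            else:
                work.add_edge(spec.anchor, nb, evidence=ev)
    if spec.anchor not in work:
        raise KeyError(
            f"anchor {spec.anchor!r} absent from the network; supply the "
            "interactome so its first-interaction star can be added"
        )
    neighbors = first_interactors(work, spec.anchor)
    if spec.mode == "strict":
        bridge = set(spec.evidence_interactors)
        missing = bridge - neighbors
        if missing:
            warnings.warn(
                f"evidence interactors not among the anchor's current first "
                f"interactors: {sorted(missing)}"
            )
    else:
        bridge = set(neighbors)
    de = set(calls.de)
    if de_filter is not None:
        de &= set(de_filter)
    de_in_graph = (de & set(work.nodes)) - {spec.anchor}

    admissible = ({spec.anchor} | bridge | de_in_graph) & set(work.nodes)
    induced = work.subgraph(admissible)
    component = nx.node_connected_component(induced, spec.anchor)
    comp_graph = induced.subgraph(component)
    kept = nodes_on_anchor_paths(comp_graph, spec.anchor, de_in_graph & component)
    pruned = nx.Graph()
    pruned.add_nodes_from(kept)
    for u, v, data in comp_graph.subgraph(kept).edges(data=True):
        pruned.add_edge(u, v, evidence=frozenset(data.get("evidence", ())))

    role: dict[str, str] = {}
    regulation: dict[str, str] = {}
    for node in pruned.nodes:
        if node == spec.anchor:
            role[node] = ROLE_ANCHOR
        elif node in de_in_graph:
            role[node] = ROLE_DE  # a node in both bridge set and DE displays as DE
        else:
            role[node] = ROLE_INTERACTOR
        regulation[node] = calls.label(node)
    return AnchoredSubnetwork(graph=pruned, role=role, regulation=regulation)


def classify_nodes(net: AnchoredSubnetwork) -> pd.DataFrame:
    """Node attribute table (node, role, regulation, color) for display."""
    rows = [
        (
            node,
            net.role[node],
            net.regulation[node],
            NODE_COLORS[(net.role[node], net.regulation[node])],
        )
        for node in sorted(net.graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "role", "regulation", "color"])
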