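"""Shared fixtures: scaled-down planted studies and random-graph helpers."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from ctdnet import StudyConfig, generate_study


SMALL_STUDY = StudyConfig(
    n_genes=400,
    n_up=30,
    n_down=40,
    n_unannotated_de=10,
    n_categories=6,
    category_size_range=(20, 60),
    n_category_de=5,
    anchor_degree=10,
    n_evidence_interactors=4,
    planted_connectors=2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down planted study shared across tests (read-only)."""
    return generate_study(SMALL_STUDY)


@pytest.fixture(scope="session")
def full_study():
    """The default-size planted study (6,221 genes)."""
    return generate_study(StudyConfig(seed=7))


def random_prune_instance(rng: np.random.Generator, max_nodes: int = 12):
    """A random graph with anchor, bridge set E and DE set D for prune tests."""
    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    nodes = sorted(g.nodes)
    anchor = nodes[int(rng.integers(n))]
    others = [v for v in nodes if v != anchor]
    rng.shuffle(others)
    n_e = int(rng.integers(1, max(2, len(others))))
    n_d = int(rng.integers(1, max(2, len(others))))
    evidence = frozenset(others[:n_e])
    de = frozenset(others[-n_d:]) if n_d else frozenset()
    for u, v in g.edges:
        g[u][v]["evidence"] = frozenset({"physical"})
    return g, anchor, evidence, de


def simple_path_nodes_oracle(g: nx.Graph, anchor: str, targets) -> frozenset:
    """Brute-force: nodes on any simple anchor->target path via full enumeration."""
    kept = {anchor}
    for t in targets:
        if t not in g or not nx.has_path(g, anchor, t):
            continue
        if t == anchor:
            continue
        for path in nx.all_simple_paths(g, anchor, t):
            kept.update(path)
    return frozenset(kept)


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail probability by integer-arithmetic enumeration of the pmf."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return float(Fraction(num, comb(N, n)))


def bh_stepup_oracle(pvalues) -> np.ndarray:
    """Independent BH step-up: sort, scale by m/rank, cumulative min from the top."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
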