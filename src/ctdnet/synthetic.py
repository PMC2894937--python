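"""Synthetic study and cell-population generators with known ground truth.

Two simulators stand in for the study's deposited data so every pipeline
stage is testable without downloads:

* :func:`generate_study` emits an interactome with a planted anchored
  pathway, an expression ratio table with planted up/down sets, a flat GO
  annotation with a planted unannotated DE fraction, and the anchor
  specification.  Defaults mirror the study conditions: a 6,221-gene array
  universe with 325 up- and 493 down-regulated genes, 277 of the DE genes
  lacking annotation, and a single mediator-like connector (the "CSE2 role")
  that is the unique evidence interactor linking the anchor to the planted
  DE genes of all three phenotype categories.

* :func:`simulate_population` emits fluorescence event vectors for an
  asynchronous budding-yeast population whose aneuploid fraction grows with
  the culture's growth-cycle index until an equilibrium cycle, emulating the
  observed DNA-content drift and plateau.

Planting is margin-safe: planted up/down log2-ratios are truncated beyond
the fold-change cutoffs and background ratios strictly inside them, so
regulation calling recovers the planted sets exactly and downstream network
recovery is deterministic.  All randomness flows through a single
integer-seeded generator, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .enrichment import AnnotationMap, Category
from .expression import ExpressionTable, RegulationCall
from .facs import FacsSample
from .netbuild import AnchorSpec

__all__ = [
    "StudyConfig",
    "PopulationConfig",
    "StudyData",
    "generate_study",
    "simulate_population",
    "generate_enrichment_instance",
]

PHENOTYPE_CATEGORIES = {
    "GO:CHRSEG": "chromosome segregation",
    "GO:CELLWALL": "cell wall and membrane biosynthesis",
    "GO:CYCREP": "cell cycle regulation and DNA repair",
}

# Aneuploid ploidy multipliers and their geometric weights (8:4:2:1): most
# aneuploid cells gain modest extra content, a few approach triploid.
ANEUPLOID_MULTIPLIERS = np.array([1.5, 2.0, 2.5, 3.0])
ANEUPLOID_WEIGHTS = np.array([8.0, 4.0, 2.0, 1.0]) / 15.0


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the planted synthetic study.

    Defaults mirror the study conditions: 6,221 array genes of which 325 are
    up- and 493 down-regulated, 277 DE genes without functional annotation.
    """

    n_genes: int = 6221
    n_up: int = 325
    n_down: int = 493
    n_unannotated_de: int = 277
    n_categories: int = 24
    category_size_range: tuple[int, int] = (100, 500)
    n_category_de: int = 12  # planted DE genes per phenotype category
    anchor_degree: int = 30
    n_evidence_interactors: int = 8
    planted_connectors: int = 1
    noise_sd: float = 0.3  # log2-ratio scale
    seed: int = 0
    anchor: str = "RPB1"

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must not exceed n_genes")
        if self.n_unannotated_de > self.n_up + self.n_down:
            raise ValueError("n_unannotated_de must not exceed the DE count")
        if not (1 <= self.planted_connectors <= self.n_evidence_interactors):
            raise ValueError("planted_connectors must be in [1, n_evidence_interactors]")
        if self.n_evidence_interactors > self.anchor_degree:
            raise ValueError("n_evidence_interactors must not exceed anchor_degree")
        if self.n_categories < len(PHENOTYPE_CATEGORIES):
            raise ValueError("need at least the three phenotype categories")
        lo, hi = self.category_size_range
        if not (0 < lo <= hi):
            raise ValueError("category_size_range must be a positive ordered interval")
        de_needed = len(PHENOTYPE_CATEGORIES) * self.n_category_de + self.n_unannotated_de
        if de_needed > self.n_up + self.n_down:
            raise ValueError("not enough DE genes for the phenotype categories plus the unannotated fraction")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


class StudyData(NamedTuple):
    interactome: nx.Graph
    expression: ExpressionTable
    annotation: AnnotationMap
    anchor_spec: AnchorSpec
    truth: dict


def _truncated_log2(rng: np.random.Generator, n: int, mean: float, sd: float,
                    lo: float, hi: float) -> np.ndarray:
    """Normal(mean, sd) log2-ratios clipped into the open-safe band [lo, hi]."""
    x = rng.normal(mean, sd, size=n)
    return np.clip(x, lo, hi)


def generate_study(cfg: StudyConfig | None = None) -> StudyData:
    """Generate interactome, expression, annotation and anchor spec with planted truth.

    The interactome is a configuration-model random graph (power-law-ish
    degree sequence, exponent 2.5) over background genes, plus a planted
    motif: the anchor is wired to ``anchor_degree`` first interactors drawn
    from non-DE genes; ``n_evidence_interactors`` of them form the evidence
    set and the first ``planted_connectors`` of those are each wired to the
    planted DE genes of every phenotype category.  Planted DE genes and
    evidence interactors take part in no other random edges, so the pruned
    networks recover the connectors exactly.
    """
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]

    # --- planted regulation --------------------------------------------
    perm = rng.permutation(cfg.n_genes)
    up = [genes[i] for i in perm[: cfg.n_up]]
    down = [genes[i] for i in perm[cfg.n_up : cfg.n_up + cfg.n_down]]
    margin = 0.05
    log2 = np.empty(cfg.n_genes)
    log2[perm[: cfg.n_up]] = _truncated_log2(rng, cfg.n_up, 2.0, cfg.noise_sd, 1.0 + margin, 6.0)
    log2[perm[cfg.n_up : cfg.n_up + cfg.n_down]] = _truncated_log2(
        rng, cfg.n_down, -2.0, cfg.noise_sd, -6.0, -(1.0 + margin)
    )
    n_bg = cfg.n_genes - cfg.n_up - cfg.n_down
    log2[perm[cfg.n_up + cfg.n_down :]] = _truncated_log2(
        rng, n_bg, 0.0, cfg.noise_sd, -(1.0 - margin), 1.0 - margin
    )
    expression = ExpressionTable({g: 2.0 ** v for g, v in zip(genes, log2)})

    # --- planted annotation structure ----------------------------------
    de = up + down
    de_shuffled = [de[i] for i in rng.permutation(len(de))]
    unannotated = set(de_shuffled[: cfg.n_unannotated_de])
    annotated_de = de_shuffled[cfg.n_unannotated_de :]
    phen_ids = list(PHENOTYPE_CATEGORIES)
    category_de: dict[str, list[str]] = {}
    cursor = 0
    for cid in phen_ids:
        category_de[cid] = sorted(annotated_de[cursor : cursor + cfg.n_category_de])
        cursor += cfg.n_category_de

    annotated_genes = sorted(set(genes) - unannotated)
    n_background_cats = cfg.n_categories - len(phen_ids)
    cat_ids = phen_ids + [f"GO:{7000000 + i}" for i in range(n_background_cats)]
    cat_names = dict(PHENOTYPE_CATEGORIES)
    cat_names.update({cid: f"background process {i}" for i, cid in enumerate(cat_ids[len(phen_ids):])})
    members: dict[str, set[str]] = {cid: set() for cid in cat_ids}
    lo, hi = cfg.category_size_range
    for cid in cat_ids:
        size = int(rng.integers(lo, hi + 1))
        pick = rng.choice(len(annotated_genes), size=min(size, len(annotated_genes)), replace=False)
        members[cid].update(annotated_genes[i] for i in pick)
    for cid in phen_ids:  # force the planted DE members in
        members[cid].update(category_de[cid])
    for cid in cat_ids:
        members[cid] -= unannotated
    covered = set().union(*members.values())
    leftovers = [g for g in annotated_genes if g not in covered]
    if leftovers:
        assignment = rng.integers(0, len(cat_ids), size=len(leftovers))
        for g, idx in zip(leftovers, assignment):
            members[cat_ids[idx]].add(g)
    annotation = AnnotationMap(
        Category(cid, cat_names[cid], frozenset(members[cid])) for cid in cat_ids
    )

    # --- planted interactome -------------------------------------------
    de_set = set(de)
    non_de = [g for g in genes if g not in de_set]
    idx = rng.choice(len(non_de), size=cfg.anchor_degree, replace=False)
    interactors = [non_de[i] for i in sorted(idx)]
    evidence = interactors[: cfg.n_evidence_interactors]
    connectors = evidence[: cfg.planted_connectors]

    # random background over genes that are neither DE nor evidence
    # interactors: accidental bridges into the admissible set are impossible
    excluded = de_set | set(evidence)
    safe = [g for g in genes if g not in excluded]
    graph = _background_graph(safe, rng)
    graph.add_node(cfg.anchor)
    for nb in interactors:
        graph.add_edge(cfg.anchor, nb, evidence=frozenset({"physical"}))
    for conn in connectors:
        for cid in phen_ids:
            for target in category_de[cid]:
                graph.add_edge(conn, target, evidence=frozenset({"physical"}))
    # cosmetic edges from planted nodes into the inadmissible background
    for node in de + [e for e in evidence if e not in connectors]:
        for i in rng.choice(len(safe), size=int(rng.integers(1, 4)), replace=False):
            graph.add_edge(node, safe[i], evidence=frozenset({"genetic"}))

    anchor_spec = AnchorSpec(
        anchor=cfg.anchor, evidence_interactors=frozenset(evidence), mode="strict"
    )
    truth = {
        "up": set(up),
        "down": set(down),
        "unannotated_de": set(unannotated),
        "category_de": {cid: list(category_de[cid]) for cid in phen_ids},
        "categories": {cid: cat_names[cid] for cid in cat_ids},
        "phenotype_categories": phen_ids,
        "first_interactors": list(interactors),
        "evidence_interactors": list(evidence),
        "connectors": list(connectors),
    }
    return StudyData(graph, expression, annotation, anchor_spec, truth)


def _background_graph(nodes: list[str], rng: np.random.Generator) -> nx.Graph:
    """Configuration-model graph with a power-law-ish degree sequence (exp 2.5)."""
    n = len(nodes)
    u = rng.random(n)
    degrees = np.minimum(np.floor(u ** (-1.0 / 1.5)).astype(int), 60)  # min degree 1
    if degrees.sum() % 2:
        degrees[0] += 1
    multigraph = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in multigraph.edges():
        if a != b:
            g.add_edge(nodes[a], nodes[b], evidence=frozenset({"genetic"}))
    return g


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the simulated asynchronous cell population.

    ``phase_fractions`` are the (G1, S, G2) occupancies (default 60/20/20,
    the exponential-growth control profile); ``c1_signal`` is the 1C
    fluorescence position; ``stain_cv`` the multiplicative staining noise;
    ``aneuploidy_rate`` the per-growth-cycle probability that a lineage turns
    aneuploid, accumulating until ``equilibrium_cycle`` and constant after
    (the observed plateau).  S-phase DNA content is drawn uniformly from
    ``s_content_range`` times 1C — by default the open interval between the
    G1 and G2 brackets, so noiseless populations gate exactly.
    """

    n_cells: int = 10000
    phase_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    c1_signal: float = 200.0
    stain_cv: float = 0.05
    aneuploidy_rate: float = 0.08
    n_cycles: int = 20
    equilibrium_cycle: int = 11
    s_content_range: tuple[float, float] = (1.25, 1.75)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.phase_fractions, dtype=float)
        if f.size != 3 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("phase_fractions must be three non-negative numbers summing to 1")
        if self.c1_signal <= 0:
            raise ValueError("c1_signal must be positive")
        if self.stain_cv < 0:
            raise ValueError("stain_cv must be non-negative")
        if not 0 <= self.aneuploidy_rate <= 1:
            raise ValueError("aneuploidy_rate must be a probability")
        lo, hi = self.s_content_range
        if not (1.0 <= lo < hi <= 2.0):
            raise ValueError("s_content_range must lie inside [1, 2]")


def aneuploid_fraction(cfg: PopulationConfig, cycle: int) -> float:
    """Expected aneuploid fraction at a growth cycle (plateaus at equilibrium)."""
    c_eff = min(int(cycle), cfg.equilibrium_cycle)
    return 1.0 - (1.0 - cfg.aneuploidy_rate) ** c_eff


def simulate_population(cfg: PopulationConfig, cycle: int = 0) -> FacsSample:
    """Simulate one propidium-iodide event vector at a growth-cycle index.

    Each cell draws a cell-cycle phase (base DNA content 1x, S-range x, or
    2x), a ploidy multiplier (1 for euploid; >1 with the cycle-dependent
    aneuploid probability, drawn from {1.5, 2, 2.5, 3} with geometric
    weights), and multiplicative Gaussian stain noise.  Identical config and
    cycle reproduce an identical event vector.
    """
    if cycle < 0 or cycle > cfg.n_cycles:
        raise ValueError(f"cycle must be in [0, {cfg.n_cycles}]")
    rng = np.random.default_rng([cfg.seed, int(cycle)])
    n = cfg.n_cells
    phase = rng.permutation(_exact_phase_counts(n, cfg.phase_fractions))
    lo, hi = cfg.s_content_range
    content = np.where(
        phase == 0, 1.0, np.where(phase == 2, 2.0, lo + (hi - lo) * rng.random(n))
    )
    mult = np.ones(n)
    p_aneu = aneuploid_fraction(cfg, cycle)
    if p_aneu > 0:
        aneu = rng.random(n) < p_aneu
        mult[aneu] = rng.choice(ANEUPLOID_MULTIPLIERS, size=int(aneu.sum()), p=ANEUPLOID_WEIGHTS)
    signal = cfg.c1_signal * content * mult
    if cfg.stain_cv > 0:
        signal = signal * (1.0 + cfg.stain_cv * rng.standard_normal(n))
        signal = np.maximum(signal, 0.0)
    return FacsSample(events=signal, label=f"cycle{int(cycle):02d}")


def _exact_phase_counts(n: int, fractions: tuple[float, float, float]) -> np.ndarray:
    """Phase labels with deterministic largest-remainder counts (order unshuffled).

    Exact counts (rather than multinomial draws) make noiseless populations
    gate back to the configured phase fractions exactly.
    """
    f = np.asarray(fractions, dtype=float)
    counts = np.floor(n * f).astype(int)
    remainder = n * f - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return np.repeat(np.arange(3), counts)


def generate_enrichment_instance(
    rng: np.random.Generator,
    n_genes: int = 2000,
    n_categories: int = 50,
    category_size_range: tuple[int, int] = (20, 80),
    de_rate: float = 0.05,
    planted: bool = False,
    enrichment_fold: float = 10.0,
) -> tuple[RegulationCall, AnnotationMap, str | None]:
    """One enrichment test instance: random categories, Bernoulli DE draws.

    With ``planted`` the members of the first category enter the DE set at
    ``enrichment_fold`` times the background rate; otherwise the DE draw is
    uniform (the global null).  Returns the calls, the annotation, and the
    planted category id (or None).
    """
    genes = np.array([f"G{i:04d}" for i in range(1, n_genes + 1)])
    lo, hi = category_size_range
    cats = []
    member_sets = []
    for i in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        pick = frozenset(rng.choice(genes, size=size, replace=False))
        cats.append(Category(f"C{i:03d}", f"category {i}", pick))
        member_sets.append(pick)
    p = np.full(n_genes, de_rate)
    planted_id = None
    if planted:
        planted_id = cats[0].category_id
        planted_mask = np.isin(genes, list(member_sets[0]))
        p[planted_mask] = min(1.0, de_rate * enrichment_fold)
    is_de = rng.random(n_genes) < p
    de_genes = genes[is_de]
    half = de_genes.size // 2
    calls = RegulationCall(
        up=frozenset(de_genes[:half]),
        down=frozenset(de_genes[half:]),
        unchanged=frozenset(genes[~is_de]),
    )
    return calls, AnnotationMap(cats), planted_id
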