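"""Hypergeometric GO-category overrepresentation with BH FDR control.

Given a set of differentially expressed genes inside a fixed gene universe
and a flat gene -> GO-category annotation, each category is tested for
overrepresentation with the hypergeometric upper tail
``P(X >= k)`` where ``X ~ Hypergeom(N, K, n)`` (universe size N, category
size K, DE draw size n, observed overlap k).  Raw p-values are corrected
across *all tested categories* with the Benjamini-Hochberg step-up
procedure; categories with zero DE overlap are excluded from the output but
still count toward the number of hypotheses.

Annotation is taken as given, flat memberships: no ontology-graph
up-propagation is performed (pre-propagated annotation can be supplied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import RegulationCall

__all__ = [
    "Category",
    "AnnotationMap",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class Category:
    """A GO category: identifier, human-readable name, member gene set."""

    category_id: str
    name: str
    members: frozenset[str]


class AnnotationMap:
    """Gene -> GO-category memberships and the inverse category -> members view.

    The two views are kept mutually consistent by construction:
    ``g in categories[c].members`` iff ``c in memberships[g]``.
    """

    def __init__(self, categories: Iterable[Category]) -> None:
        self._categories: dict[str, Category] = {}
        memberships: dict[str, set[str]] = {}
        for cat in categories:
            if cat.category_id in self._categories:
                raise ValueError(f"duplicate category id {cat.category_id!r}")
            self._categories[cat.category_id] = cat
            for gene in cat.members:
                memberships.setdefault(gene, set()).add(cat.category_id)
        self._memberships = {g: frozenset(cs) for g, cs in memberships.items()}

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "AnnotationMap":
        """Build from (gene, category_id, category_name) rows."""
        members: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for gene, cat_id, cat_name in rows:
            members.setdefault(cat_id, set()).add(gene)
            if cat_name:
                names.setdefault(cat_id, cat_name)
        return cls(
            Category(cid, names.get(cid, cid), frozenset(genes))
            for cid, genes in members.items()
        )

    @property
    def memberships(self) -> dict[str, frozenset[str]]:
        return dict(self._memberships)

    @property
    def categories(self) -> dict[str, Category]:
        return dict(self._categories)

    @property
    def genes(self) -> frozenset[str]:
        """All genes with at least one category membership."""
        return frozenset(self._memberships)

    def annotated(self, gene: str) -> bool:
        return bool(self._memberships.get(gene))

    def rows(self) -> Iterable[tuple[str, str, str]]:
        """(gene, category_id, category_name) rows, deterministically ordered."""
        for cid in sorted(self._categories):
            cat = self._categories[cid]
            for gene in sorted(cat.members):
                yield gene, cid, cat.name

    def __len__(self) -> int:
        return len(self._categories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self._categories == other._categories

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnnotationMap(n_categories={len(self)}, n_genes={len(self._memberships)})"


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts category members among ``n`` genes drawn without replacement
    from a universe of ``N`` genes of which ``K`` belong to the category.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Returns ``(p_adj, significant)`` in the input order, where
    ``p_adj[i] = min_{j: p_j ranked >= rank_i} min(1, p_(j) * m / j)`` and
    ``significant = p_adj <= alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj <= alpha


def enrich(
    calls: RegulationCall,
    ann: AnnotationMap,
    universe_mode: str = "all_array_genes",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every annotation category for overrepresentation of DE genes.

    Parameters
    ----------
    calls : RegulationCall
        Regulation calls; the DE set (up or down) is the draw.
    ann : AnnotationMap
        Flat gene -> category annotation.
    universe_mode : {"all_array_genes", "annotated_only"}
        Background universe: every gene in the calls' universe (default,
        mirroring whole-annotation Bingo behaviour) or only annotated genes.
    alpha : float
        Significance level applied to BH-adjusted p-values.

    Returns
    -------
    pandas.DataFrame
        One row per category with at least one DE member, columns
        ``category, name, N, K, n, k, p_raw, p_adj, significant``, sorted by
        raw p-value.  Categories with zero DE overlap are dropped from the
        output but counted as tested hypotheses in the BH correction.
    """
    if universe_mode not in ("all_array_genes", "annotated_only"):
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    universe = calls.universe
    if universe_mode == "annotated_only":
        universe = universe & ann.genes
    de = calls.de & universe
    if not de:
        raise ValueError(
            "empty DE set: call regulation with wider cutoffs or check the "
            "expression table before running enrichment"
        )
    N, n = len(universe), len(de)
    rows = []
    for cid in sorted(ann.categories):
        cat = ann.categories[cid]
        members = cat.members & universe
        K = len(members)
        if K == 0:
            continue  # not testable in this universe
        k = len(members & de)
        rows.append((cid, cat.name, N, K, n, k))
    if not rows:
        return _empty_result()
    df = pd.DataFrame(rows, columns=["category", "name", "N", "K", "n", "k"])
    df["p_raw"] = stats.hypergeom.sf(df["k"] - 1, df["N"], df["K"], df["n"])
    df.loc[df["k"] == 0, "p_raw"] = 1.0
    p_adj, significant = bh_adjust(df["p_raw"].to_numpy(), alpha=alpha)
    df["p_adj"] = p_adj
    df["significant"] = significant
    df = df[df["k"] >= 1]
    df = df.sort_values(["p_raw", "category"], kind="mergesort").reset_index(drop=True)
    return df


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["category", "name", "N", "K", "n", "k", "p_raw", "p_adj", "significant"]
    )
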