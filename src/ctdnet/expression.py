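"""Fold-change regulation calling from mutant/control expression ratios.

Differential expression here is a pure fold-change criterion on per-gene
expression ratios (mutant over control): a gene is called *up* when its ratio
reaches the upper cutoff (default 2.0), *down* when it falls to the lower
cutoff (default 0.5), and *unchanged* otherwise.  No variance modelling or
test statistic is involved; the ratio table is assumed to be post-averaging,
one ratio per gene.

Genes called differentially expressed but lacking any functional (GO)
annotation are removed before network construction by
:func:`filter_annotated`, since unannotated genes cannot seed a
phenotype-category subnetwork.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import AnnotationMap

__all__ = [
    "DEConfig",
    "ExpressionTable",
    "RegulationCall",
    "call_regulation",
    "filter_annotated",
]


@dataclass(frozen=True)
class DEConfig:
    """Cutoffs for fold-change regulation calling.

    Parameters
    ----------
    low_cut : float
        Down-regulation cutoff on the mutant/control ratio (default 0.5).
    high_cut : float
        Up-regulation cutoff (default 2.0).
    inclusive : bool
        Whether a ratio exactly at a cutoff is called differentially
        expressed (default True).
    """

    low_cut: float = 0.5
    high_cut: float = 2.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.low_cut < 1.0 < self.high_cut):
            raise ValueError(
                f"cutoffs must satisfy 0 < low_cut < 1 < high_cut, "
                f"got low_cut={self.low_cut}, high_cut={self.high_cut}"
            )


class ExpressionTable:
    """Per-gene mutant/control expression ratios over a fixed gene universe.

    Every gene has exactly one strictly positive, finite ratio.
    """

    def __init__(self, ratios: Mapping[str, float]) -> None:
        clean: dict[str, float] = {}
        for gene, ratio in ratios.items():
            r = float(ratio)
            if not math.isfinite(r) or r <= 0.0:
                raise ValueError(f"ratio for gene {gene!r} must be positive and finite, got {ratio!r}")
            clean[str(gene)] = r
        self._ratios = clean

    @classmethod
    def from_log2(cls, log2_ratios: Mapping[str, float]) -> "ExpressionTable":
        """Build a table from log2 ratios (any finite real)."""
        return cls({g: 2.0 ** float(v) for g, v in log2_ratios.items()})

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self._ratios)

    @property
    def ratios(self) -> dict[str, float]:
        return dict(self._ratios)

    def __len__(self) -> int:
        return len(self._ratios)

    def __contains__(self, gene: str) -> bool:
        return gene in self._ratios

    def __getitem__(self, gene: str) -> float:
        return self._ratios[gene]

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(self._ratios.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return self._ratios == other._ratios

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionTable(n_genes={len(self)})"


@dataclass(frozen=True)
class RegulationCall:
    """A partition of a gene universe into up / down / unchanged sets."""

    up: frozenset[str]
    down: frozenset[str]
    unchanged: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down or self.up & self.unchanged or self.down & self.unchanged:
            raise ValueError("up/down/unchanged sets must be pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.up | self.down | self.unchanged

    @property
    def de(self) -> frozenset[str]:
        """The differentially expressed set (up or down)."""
        return self.up | self.down

    def label(self, gene: str) -> str:
        """Regulation label for *gene*; genes outside the universe are 'unchanged'."""
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return "unchanged"

    def summary(self) -> dict[str, int]:
        return {
            "n_up": len(self.up),
            "n_down": len(self.down),
            "n_de": len(self.de),
            "n_universe": len(self.universe),
        }


def call_regulation(table: ExpressionTable, cfg: DEConfig | None = None) -> RegulationCall:
    """Call up/down/unchanged regulation from an expression ratio table.

    With ``cfg.inclusive`` (the default) a gene is *up* iff its ratio is
    >= ``high_cut`` and *down* iff it is <= ``low_cut``; with
    ``inclusive=False`` the comparisons are strict.
    """
    cfg = cfg or DEConfig()
    up, down, unchanged = set(), set(), set()
    for gene, ratio in table.items():
        if (ratio >= cfg.high_cut) if cfg.inclusive else (ratio > cfg.high_cut):
            up.add(gene)
        elif (ratio <= cfg.low_cut) if cfg.inclusive else (ratio < cfg.low_cut):
            down.add(gene)
        else:
            unchanged.add(gene)
    return RegulationCall(frozenset(up), frozenset(down), frozenset(unchanged))


def filter_annotated(
    calls: RegulationCall, ann: "AnnotationMap"
) -> tuple[RegulationCall, list[str]]:
    """Drop differentially expressed genes that carry no functional annotation.

    Returns the restricted :class:`RegulationCall` (excluded genes removed
    from the universe) and the sorted list of excluded DE genes.  Unchanged
    genes are retained regardless of annotation, since only DE genes seed
    network construction.
    """
    excluded = sorted(g for g in calls.de if not ann.memberships.get(g))
    dropped = frozenset(excluded)
    filtered = RegulationCall(
        up=calls.up - dropped,
        down=calls.down - dropped,
        unchanged=calls.unchanged,
    )
    return filtered, excluded
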