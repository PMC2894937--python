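"""Readers and writers for the external formats the pipeline touches.

Tab-delimited edge lists (a simple gene_a/gene_b dialect and the BioGRID
Tab 2.0 column layout), gene -> GO-category annotation tables, expression
ratio tables, one-column fluorescence event vectors, and SIF / GraphML /
edge-TSV network export with a node-attribute sidecar.

Gene identifiers are case-insensitive tokens; an optional alias table maps
synonyms (e.g. RPO21) to one canonical name (RPB1) and canonicalization is
idempotent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .enrichment import AnnotationMap
from .expression import ExpressionTable, RegulationCall
from .netbuild import AnchoredSubnetwork

__all__ = [
    "FormatError",
    "InteractionRecord",
    "canonical_gene_id",
    "load_aliases",
    "read_interactions",
    "write_interactions",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_events",
    "write_events",
    "read_calls",
    "write_calls",
    "write_subnetwork",
    "read_subnetwork",
]

# BioGRID Tab 2.0 0-based column positions; only the official symbol and
# experimental-system columns matter for topology and evidence class.
_BIOGRID_SYMBOL_A = 7
_BIOGRID_SYMBOL_B = 8
_BIOGRID_SYSTEM = 11
_BIOGRID_MIN_COLS = 12

_SIMPLE_HEADER = ("gene_a", "gene_b", "evidence", "source")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def canonical_gene_id(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Trim, uppercase and (optionally) alias-resolve a gene identifier."""
    token = str(name).strip().upper()
    if not token:
        raise ValueError("gene identifier must be a non-empty token")
    if aliases:
        token = aliases.get(token, token)
    return token


def load_aliases(path: str | Path) -> dict[str, str]:
    """Load a two-column alias -> canonical TSV into an idempotent mapping.

    Chains (A -> B, B -> C) are resolved to their terminal name so applying
    the table once is equivalent to applying it repeatedly.
    """
    raw: dict[str, str] = {}
    for lineno, fields in _iter_rows(path, delimiter="\t"):
        if len(fields) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        raw[fields[0].strip().upper()] = fields[1].strip().upper()
    resolved: dict[str, str] = {}
    for key in raw:
        seen, cur = {key}, raw[key]
        while cur in raw and cur not in seen:
            seen.add(cur)
            cur = raw[cur]
        resolved[key] = cur
    return resolved


@dataclass(frozen=True)
class InteractionRecord:
    """One gene-gene interaction row with its evidence (experimental system) tag."""

    gene_a: str
    gene_b: str
    evidence: str = ""
    source: str = ""

    @property
    def is_self(self) -> bool:
        return self.gene_a == self.gene_b


def _iter_rows(path: str | Path, delimiter: str = "\t"):
    """Yield (1-based line number, fields) for non-empty, non-comment lines."""
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split(delimiter)


def read_interactions(
    path: str | Path,
    dialect: str = "simple_tsv",
    aliases: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Read an interaction edge list.

    ``simple_tsv`` rows are ``gene_a<TAB>gene_b[<TAB>evidence[<TAB>source]]``
    with an optional header; ``biogrid_tab`` is the BioGRID Tab 2.0 layout,
    of which only the official symbol columns and the experimental-system
    column are used.  Duplicate rows are preserved (deduplication is the
    graph builder's job) and self-interactions are representable.
    """
    if dialect not in ("simple_tsv", "biogrid_tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[InteractionRecord] = []
    first = True
    for lineno, fields in _iter_rows(path):
        if dialect == "simple_tsv":
            if first and fields[0].strip().lower() == "gene_a":
                first = False
                continue
            first = False
            if not 2 <= len(fields) <= 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2-4 tab-delimited columns, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            evidence = fields[2].strip() if len(fields) > 2 else ""
            source = fields[3].strip() if len(fields) > 3 else ""
        else:
            if first and fields[0].strip().lower() in ("#biogrid interaction id", "biogrid interaction id"):
                first = False
                continue
            first = False
            if len(fields) < _BIOGRID_MIN_COLS:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {_BIOGRID_MIN_COLS} BioGRID "
                    f"Tab 2.0 columns, got {len(fields)}"
                )
            a, b = fields[_BIOGRID_SYMBOL_A], fields[_BIOGRID_SYMBOL_B]
            evidence = fields[_BIOGRID_SYSTEM].strip()
            source = "BioGRID"
        try:
            rec = InteractionRecord(
                canonical_gene_id(a, aliases), canonical_gene_id(b, aliases), evidence, source
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records as simple_tsv (with header)."""
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_SIMPLE_HEADER) + "\n")
        for rec in records:
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.evidence}\t{rec.source}\n")


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def read_expression(
    path: str | Path,
    log2_input: bool = False,
    aliases: Mapping[str, str] | None = None,
) -> ExpressionTable:
    """Read a (gene, ratio) table; tab- or comma-delimited, optional header.

    Ratios must be positive finite numbers (or any finite real with
    ``log2_input``, in which case they are exponentiated).  A gene appearing
    twice is an error: the upstream array pipeline yields one averaged ratio
    per gene.
    """
    delim = _sniff_delimiter(path)
    ratios: dict[str, float] = {}
    first = True
    for lineno, fields in _iter_rows(path, delimiter=delim):
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        gene_raw, value_raw = fields[0], fields[1]
        if first:
            first = False
            if not _is_number(value_raw):
                continue  # header row
        if not _is_number(value_raw):
            raise FormatError(f"{path}: line {lineno}: non-numeric ratio {value_raw!r}")
        gene = canonical_gene_id(gene_raw, aliases)
        if gene in ratios:
            raise FormatError(f"{path}: line {lineno}: duplicate gene {gene!r}")
        value = float(value_raw)
        if log2_input:
            value = 2.0 ** value
        if not math.isfinite(value) or value <= 0:
            raise FormatError(f"{path}: line {lineno}: ratio must be positive and finite")
        ratios[gene] = value
    return ExpressionTable(ratios)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tratio\n")
        for gene in sorted(table.universe):
            fh.write(f"{gene}\t{table[gene]:.10g}\n")


def read_annotation(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> AnnotationMap:
    """Read a (gene, category_id, category_name) TSV into an AnnotationMap."""
    rows: list[tuple[str, str, str]] = []
    first = True
    for lineno, fields in _iter_rows(path):
        if first and fields[0].strip().lower() == "gene":
            first = False
            continue
        first = False
        if not 2 <= len(fields) <= 3:
            raise FormatError(f"{path}: line {lineno}: expected 2-3 columns, got {len(fields)}")
        gene = canonical_gene_id(fields[0], aliases)
        cat_id = fields[1].strip()
        name = fields[2].strip() if len(fields) > 2 else ""
        if not cat_id:
            raise FormatError(f"{path}: line {lineno}: empty category id")
        rows.append((gene, cat_id, name))
    return AnnotationMap.from_rows(rows)


def write_annotation(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcategory_id\tcategory_name\n")
        for gene, cid, name in ann.rows():
            fh.write(f"{gene}\t{cid}\t{name}\n")


def read_events(path: str | Path) -> np.ndarray:
    """Read a one-column event vector (CSV/TSV); a non-numeric first row is a header."""
    values: list[float] = []
    delim = _sniff_delimiter(path)
    first = True
    for lineno, fields in _iter_rows(path, delimiter=delim):
        token = fields[0].strip()
        if first:
            first = False
            if not _is_number(token):
                continue  # auto-detected header
        if not _is_number(token):
            raise FormatError(f"{path}: line {lineno}: non-numeric event value {token!r}")
        value = float(token)
        if not math.isfinite(value) or value < 0:
            raise FormatError(f"{path}: line {lineno}: event values must be non-negative and finite")
        values.append(value)
    return np.asarray(values, dtype=float)


def write_events(events: np.ndarray, path: str | Path, header: str | None = "signal") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"{header}\n")
        for v in np.asarray(events, dtype=float):
            fh.write(f"{v:.10g}\n")


def write_calls(table: ExpressionTable, calls: RegulationCall, path: str | Path) -> None:
    """Write a (gene, ratio, call) TSV of regulation calls."""
    with open(path, "w") as fh:
        fh.write("gene\tratio\tcall\n")
        for gene in sorted(calls.universe):
            ratio = table[gene] if gene in table else float("nan")
            fh.write(f"{gene}\t{ratio:.10g}\t{calls.label(gene)}\n")


def read_calls(path: str | Path) -> RegulationCall:
    """Read a (gene, ratio, call) TSV back into a RegulationCall."""
    sets: dict[str, set[str]] = {"up": set(), "down": set(), "unchanged": set()}
    first = True
    for lineno, fields in _iter_rows(path):
        if first and fields[0].strip().lower() == "gene":
            first = False
            continue
        first = False
        if len(fields) != 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
        gene, _, call = fields
        call = call.strip()
        if call not in sets:
            raise FormatError(f"{path}: line {lineno}: unknown call {call!r}")
        sets[call].add(canonical_gene_id(gene))
    return RegulationCall(
        frozenset(sets["up"]), frozenset(sets["down"]), frozenset(sets["unchanged"])
    )


# --- network export -------------------------------------------------------

def _nodes_sidecar(path: Path) -> Path:
    return path.with_suffix(".nodes.tsv")


def _write_nodes_sidecar(net: AnchoredSubnetwork, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\trole\tregulation\n")
        for node in sorted(net.graph.nodes):
            fh.write(f"{node}\t{net.role[node]}\t{net.regulation[node]}\n")


def _evidence_str(data: Mapping) -> str:
    return "|".join(sorted(data.get("evidence", ()) or ()))


def write_subnetwork(net: AnchoredSubnetwork, path: str | Path, format: str = "sif") -> None:
    """Serialize a pruned subnetwork.

    ``sif`` writes ``source<TAB>interaction-type<TAB>target`` lines plus a
    ``<stem>.nodes.tsv`` sidecar with per-node role and regulation;
    ``edge_tsv`` writes source/target/evidence rows with the same sidecar;
    ``graphml`` embeds the node attributes and the joined evidence string.
    An empty network yields a file with zero edge lines.
    """
    path = Path(path)
    edges = sorted((min(u, v), max(u, v)) for u, v in net.graph.edges)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\tpp\t{v}\n")
        _write_nodes_sidecar(net, _nodes_sidecar(path))
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tevidence\n")
            for u, v in edges:
                fh.write(f"{u}\t{v}\t{_evidence_str(net.graph[u][v])}\n")
        _write_nodes_sidecar(net, _nodes_sidecar(path))
    elif format == "graphml":
        g = nx.Graph()
        for node in net.graph.nodes:
            g.add_node(node, role=net.role[node], regulation=net.regulation[node])
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, evidence=_evidence_str(data))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_subnetwork(path: str | Path, format: str = "sif") -> AnchoredSubnetwork:
    """Re-read a serialized subnetwork (inverse of :func:`write_subnetwork`)."""
    path = Path(path)
    graph = nx.Graph()
    role: dict[str, str] = {}
    regulation: dict[str, str] = {}
    if format in ("sif", "edge_tsv"):
        for lineno, fields in _iter_rows(path):
            if format == "sif":
                if len(fields) == 1:
                    graph.add_node(fields[0])
                    continue
                if len(fields) != 3:
                    raise FormatError(f"{path}: line {lineno}: expected 3 SIF columns")
                u, _, v = fields
                graph.add_edge(u, v, evidence=frozenset())
            else:
                if fields[0].strip().lower() == "source":
                    continue
                if len(fields) != 3:
                    raise FormatError(f"{path}: line {lineno}: expected 3 columns")
                u, v, ev = fields
                graph.add_edge(u, v, evidence=frozenset(t for t in ev.split("|") if t))
        sidecar = _nodes_sidecar(path)
        for lineno, fields in _iter_rows(sidecar):
            if fields[0].strip().lower() == "node":
                continue
            if len(fields) != 3:
                raise FormatError(f"{sidecar}: line {lineno}: expected 3 columns")
            node, r, reg = fields
            graph.add_node(node)
            role[node] = r
            regulation[node] = reg
    elif format == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            graph.add_node(node)
            role[node] = data.get("role", "")
            regulation[node] = data.get("regulation", "")
        for u, v, data in g.edges(data=True):
            ev = data.get("evidence", "")
            graph.add_edge(u, v, evidence=frozenset(t for t in ev.split("|") if t))
    else:
        raise ValueError(f"unknown format {format!r}")
    return AnchoredSubnetwork(graph=graph, role=role, regulation=regulation)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
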