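"""Connectivity summaries of interaction networks over gene lists."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Components below this size are isolated nodes, not interacting sets.
COMPONENT_FLOOR = 2


def read_edge_list(path, min_score: float | None = None) -> nx.Graph:
    """Read a 2- or 3-column tab-separated edge list into a simple graph.

    A third column, if present, is an edge confidence score; ``min_score``
    drops edges below the cutoff. Self-loops and duplicate pairs collapse
    silently (the format STRING exports may list both directions).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise ValidationError(f"edge list {path} needs at least two columns")
    first = df.iloc[0]
    header_names = {"gene_a", "gene_b", "protein1", "protein2", "node1", "node2"}
    has_header = str(first[0]).lower() in header_names
    if not has_header and df.shape[1] > 2:
        try:
            float(first[2])
        except (TypeError, ValueError):
            has_header = not pd.isna(first[2])
    if has_header:
        df = df.iloc[1:]
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = row[0], row[1]
        if a == b:
            continue
        if min_score is not None and len(row) > 2 and float(row[2]) < min_score:
            continue
        if len(row) > 2 and not pd.isna(row[2]):
            graph.add_edge(a, b, score=float(row[2]))
        else:
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = sorted((min(a, b), max(a, b)) for a, b in graph.edges())
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ComponentSummary:
    nodes: frozenset
    n_edges: int
    mean_degree: float
    hubs: tuple

    @property
    def size(self) -> int:
        return len(self.nodes)

    def as_dict(self) -> dict:
        return {
            "size": self.size,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "n_hubs": len(self.hubs),
            "hubs": list(self.hubs),
        }


def _largest_component(graph: nx.Graph):
    components = list(nx.connected_components(graph))
    if not components:
        return set()
    max_size = max(len(c) for c in components)
    ties = [c for c in components if len(c) == max_size]
    return min(ties, key=lambda c: min(c))  # lexicographic smallest member


def largest_component_summary(graph: nx.Graph, hub_threshold: int = 10) -> ComponentSummary:
    """Largest connected component with its mean degree and hub list.

    Mean degree is ``2 * edges / nodes`` within the component; hubs are
    component members whose within-component degree reaches ``hub_threshold``.
    Ties between equal-size components break toward the one containing the
    lexicographically smallest node.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    component = _largest_component(graph)
    sub = graph.subgraph(component)
    n_edges = sub.number_of_edges()
    mean_degree = 2.0 * n_edges / sub.number_of_nodes()
    hubs = tuple(sorted(n for n, d in sub.degree() if d >= hub_threshold))
    return ComponentSummary(
        nodes=frozenset(component), n_edges=n_edges, mean_degree=mean_degree, hubs=hubs
    )


@dataclass(frozen=True)
class RetentionResult:
    n_list: int
    n_in_component: int
    component: frozenset

    @property
    def fraction(self) -> float:
        return self.n_in_component / self.n_list

    @property
    def percent(self) -> int:
        return int(round(100.0 * self.fraction))

    def as_dict(self) -> dict:
        return {
            "n_list": self.n_list,
            "n_in_component": self.n_in_component,
            "fraction": self.fraction,
            "percent": self.percent,
        }


def component_retention(genes: Sequence[str], graph: nx.Graph) -> RetentionResult:
    """Share of a gene list captured by its largest induced connected component.

    The subgraph induced on the list is decomposed; components below size 2
    do not count (isolated nodes are non-interacting). The percentage is
    relative to the full (de-duplicated) list; the exact fraction is kept
    alongside the rounded display value.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("empty gene list")
    present = gene_set & set(graph.nodes)
    if not present:
        log.info("no list gene present in the graph; retention is 0")
        return RetentionResult(n_list=len(gene_set), n_in_component=0, component=frozenset())
    sub = graph.subgraph(present)
    components = [c for c in nx.connected_components(sub) if len(c) >= COMPONENT_FLOOR]
    if not components:
        return RetentionResult(n_list=len(gene_set), n_in_component=0, component=frozenset())
    max_size = max(len(c) for c in components)
    largest = min((c for c in components if len(c) == max_size), key=lambda c: min(c))
    return RetentionResult(
        n_list=len(gene_set), n_in_component=len(largest), component=frozenset(largest)
    )


def neighbor_subset(genes: Sequence[str], graph: nx.Graph, hub: str) -> list:
    """List genes adjacent to a hub, in input order (for interactant analyses)."""
    if hub not in graph:
        raise ValidationError(f"hub {hub!r} absent from the graph")
    neighbors = set(graph.adj[hub])
    seen: set = set()
    out = []
    for g in genes:
        if g in neighbors and g not in seen:
            out.append(g)
            seen.add(g)
    return out


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    table = pd.DataFrame(sorted(graph.degree()), columns=["gene", "degree"])
    return table.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)
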