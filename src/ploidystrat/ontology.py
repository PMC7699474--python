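"""Ontology/pathway enrichment: DAG propagation + hypergeometric tests.

The ontology is a plain child -> parent edge table plus direct gene-to-term
assignments; no OBO parsing. A gene belongs to a term if it is directly
assigned to the term or to any of its descendants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .stats import bh_adjust, hypergeom_tail

log = logging.getLogger(__name__)


@dataclass
class Ontology:
    """Term DAG (edges run child -> parent) with direct gene assignments."""

    terms: set
    edges: list
    term_genes: Mapping[str, set]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValidationError(f"edge ({child}, {parent}) references an unknown term")
        unknown = set(self.term_genes) - self.terms
        if unknown:
            raise ValidationError(f"gene assignments to unknown terms: {sorted(unknown)}")
        self._check_acyclic()

    def _check_acyclic(self):
        sorter = TopologicalSorter()
        for t in self.terms:
            sorter.add(t)
        for child, parent in self.edges:
            sorter.add(parent, child)  # child precedes parent
        try:
            self._topo_order = list(sorter.static_order())
        except CycleError as err:
            member = err.args[1][0] if len(err.args) > 1 and err.args[1] else "?"
            raise ValidationError(f"ontology edges contain a cycle through {member!r}") from err

    @classmethod
    def from_tables(cls, edges_df: pd.DataFrame, gene2term_df: pd.DataFrame, labels_df=None):
        edges = list(zip(edges_df.iloc[:, 0], edges_df.iloc[:, 1]))
        terms = {t for e in edges for t in e} | set(gene2term_df.iloc[:, 1])
        term_genes: dict = {}
        for gene, term in zip(gene2term_df.iloc[:, 0], gene2term_df.iloc[:, 1]):
            term_genes.setdefault(term, set()).add(gene)
        labels = {}
        if labels_df is not None:
            labels = dict(zip(labels_df.iloc[:, 0], labels_df.iloc[:, 1]))
        return cls(terms=terms, edges=edges, term_genes=term_genes, labels=labels)

    def write(self, edges_path, gene2term_path, labels_path=None) -> None:
        pd.DataFrame(self.edges, columns=["child", "parent"]).to_csv(edges_path, sep="\t", index=False)
        rows = [(g, t) for t in sorted(self.term_genes) for g in sorted(self.term_genes[t])]
        pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(gene2term_path, sep="\t", index=False)
        if labels_path is not None:
            pd.DataFrame(sorted(self.labels.items()), columns=["term", "label"]).to_csv(
                labels_path, sep="\t", index=False
            )


def propagate_ontology(ontology: Ontology) -> dict:
    """Close gene-to-term assignments over the DAG.

    Returns term -> frozenset of genes, where a gene belongs to a term iff it
    is directly assigned to the term or to any of its descendants.
    """
    children: dict = {t: [] for t in ontology.terms}
    for child, parent in ontology.edges:
        children[parent].append(child)
    closed: dict = {}
    for term in ontology._topo_order:  # children come before parents
        genes = set(ontology.term_genes.get(term, ()))
        for child in children[term]:
            genes |= closed[child]
        closed[term] = frozenset(genes)
    return closed


def hypergeometric_enrichment(
    genes: Sequence[str],
    background: Sequence[str],
    closed_term_genes: Mapping[str, frozenset],
    labels: Mapping[str, str] | None = None,
    merge_identical: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list per ontology term.

    Terms whose gene set (restricted to the background) is empty, or that
    contain no list gene, are excluded from testing and from the
    multiple-testing count. Terms with identical background-restricted gene
    sets are merged into one row (ids joined with ``|``). Rows come back
    sorted by q then p.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("empty gene list")
    bg = set(background)
    stray = gene_set - bg
    if stray:
        raise ValidationError(f"list genes outside the background: {sorted(stray)[:5]}")
    labels = labels or {}
    N, n = len(bg), len(gene_set)

    restricted: dict = {}
    for term, members in closed_term_genes.items():
        inside = frozenset(members & bg)
        if inside:
            restricted[term] = inside
    if merge_identical:
        by_set: dict = {}
        for term in sorted(restricted):
            by_set.setdefault(restricted[term], []).append(term)
        merged = {
            "|".join(terms): gene_subset for gene_subset, terms in by_set.items()
        }
        label_of = {
            "|".join(terms): "; ".join(filter(None, (labels.get(t, t) for t in terms)))
            for _, terms in by_set.items()
        }
    else:
        merged = restricted
        label_of = {t: labels.get(t, t) for t in merged}

    rows = []
    for term in sorted(merged):
        members = merged[term]
        k = len(members & gene_set)
        if k == 0:
            continue
        tail = hypergeom_tail(k, n, len(members), N, alternative="greater")
        rows.append(
            {
                "term": term,
                "label": label_of[term],
                "k": k,
                "n": n,
                "K": len(members),
                "N": N,
                "p": tail.p,
                "log10_p": tail.log10_p,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["term", "label", "k", "n", "K", "N", "p", "log10_p", "q"])
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)
    return table


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values (validated re-export of :func:`bh_adjust`)."""
    return bh_adjust(p_values)
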