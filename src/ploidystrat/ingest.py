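"""Reading, validation, ortholog matching and quantile normalization.

File formats are plain tab-separated tables (see the README). Lines starting
with ``#`` are treated as provenance comments and skipped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneAnnotation, OrthologyMap, PairedExpression
from .errors import ValidationError

log = logging.getLogger(__name__)


def read_expression(table_path, meta_path) -> ExpressionMatrix:
    """Read a gene x sample table plus its sample-metadata sidecar.

    Genes with any missing value are dropped with a logged count. Duplicate
    gene ids, negative values, or a metadata/table sample mismatch raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(table_path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {table_path}: {dups}")
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    if "sample_id" not in meta.columns:
        raise ValidationError(f"metadata {meta_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")

    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        log.warning("dropping %d genes with missing values from %s", n_na, table_path)
        df = df.dropna(axis=0)
    return ExpressionMatrix(values=df, sample_meta=meta)


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "driver_class" in df.columns:
        df["driver_class"] = df["driver_class"].fillna("none")
    return GeneAnnotation(df)


def read_orthology(path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"orthology table {path} needs two columns")
    if not {"gene_a", "gene_b"} <= set(df.columns):
        df = df.iloc[:, :2].set_axis(["gene_a", "gene_b"], axis=1)
    return OrthologyMap(df)


def match_orthologs(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    orthology: OrthologyMap,
    annotation: GeneAnnotation,
) -> PairedExpression:
    """Join the two species on one-to-one orthologs with known phylostrata.

    One output row per ortholog pair present in both matrices and annotated
    with a phylostratum (lookup by either member); columns are the union of
    samples from both species.
    """
    if len(orthology) == 0:
        raise ValidationError("empty orthology map")
    pairs = orthology.pairs
    present = pairs["gene_a"].isin(expr_a.genes) & pairs["gene_b"].isin(expr_b.genes)
    pairs = pairs[present]
    annotated = pairs["gene_a"].isin(annotation.genes) | pairs["gene_b"].isin(annotation.genes)
    n_dropped = int((~annotated).sum())
    if n_dropped:
        log.info("dropping %d ortholog pairs without stratigraphic annotation", n_dropped)
    pairs = pairs[annotated]
    if pairs.empty:
        raise ValidationError("no annotated ortholog pairs shared by both matrices")

    va = expr_a.values.loc[pairs["gene_a"]]
    vb = expr_b.values.loc[pairs["gene_b"]].set_axis(pairs["gene_a"].to_numpy(), axis=0)
    overlap = set(va.columns) & set(vb.columns)
    if overlap:
        raise ValidationError(f"sample ids shared between species: {sorted(overlap)}")
    values = pd.concat([va, vb], axis=1)
    meta = pd.concat([expr_a.sample_meta, expr_b.sample_meta])
    pair_map = pd.Series(pairs["gene_b"].to_numpy(), index=pd.Index(pairs["gene_a"], name="gene_id"))
    log.info("matched %d ortholog pairs with stratigraphic data", len(pair_map))
    return PairedExpression(values=values, pair_map=pair_map, sample_meta=meta)


def log2_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """``log2(x + pseudocount)`` on a linear-scale matrix."""
    if (values < 0).any().any():
        raise ValidationError("negative values cannot be log-transformed")
    return np.log2(values + pseudocount)


def _normalize_group(arr: np.ndarray) -> np.ndarray:
    """Quantile-normalize one group of columns against the mean order statistics.

    Tied values within a column receive the mean of the reference values at
    their tied ranks.
    """
    order = np.argsort(arr, axis=0, kind="mergesort")
    ref = np.take_along_axis(arr, order, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        col = arr[:, j]
        assigned = np.empty(n, dtype=float)
        assigned[order[:, j]] = ref
        if np.unique(col).size != n:  # resolve ties by averaging the reference
            assigned = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = assigned
    return out


def quantile_normalize(values: pd.DataFrame, groups) -> pd.DataFrame:
    """Quantile normalization applied separately within each sample group.

    Parameters
    ----------
    values : DataFrame
        Gene x sample matrix.
    groups : mapping or Series
        Sample id -> group label (e.g. the tissue of each sample). Every
        group must contain at least two samples.

    Within each group the sorted values of every column become the row-wise
    mean of order statistics; ranks within each column are preserved.
    """
    groups = pd.Series(groups)
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a normalization group: {missing}")
    out = values.copy().astype(float)
    for label, members in groups.loc[values.columns].groupby(groups.loc[values.columns]).groups.items():
        cols = list(members)
        if len(cols) < 2:
            raise ValidationError(f"normalization group {label!r} has fewer than 2 samples")
        out[cols] = _normalize_group(values[cols].to_numpy(dtype=float))
    return out
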