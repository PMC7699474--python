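"""Core data containers shared across pipeline stages.

All tabular state is held in pandas objects; the dataclasses only add
validation and a few convenience accessors. Expression values are stored on
the linear scale; the log2 transform is applied explicitly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import ValidationError

SPECIES = ("A", "B")
TISSUES = ("heart", "liver")
PLOIDIES = ("polyploid", "diploid")
DRIVER_CLASSES = ("oncogene", "tumour_suppressor", "none")
META_COLUMNS = ("species", "tissue", "ploidy", "batch", "replicate")
N_STRATA = 16

#: Ploidy of each (species, tissue) cell in the reciprocal criss-cross design:
#: species A polyploid in heart / diploid in liver, species B the reverse.
CRISSCROSS_PLOIDY = {
    ("A", "heart"): "polyploid",
    ("A", "liver"): "diploid",
    ("B", "heart"): "diploid",
    ("B", "liver"): "polyploid",
}

STRATUM_NAMES = {
    1: "cellular organisms",
    2: "Eukaryota",
    3: "Opisthokonta",
    4: "Metazoa",
    5: "Eumetazoa",
    6: "Bilateria",
    7: "Chordata",
    8: "Euteleostomi",
    9: "Amniota",
    10: "Mammalia",
    11: "Theria",
    12: "Eutheria",
    13: "Euarchontoglires",
    14: "Catarrhini",
    15: "Homininae",
    16: "Homo sapiens",
}


def _validate_meta(sample_meta: pd.DataFrame, sample_ids) -> pd.DataFrame:
    missing_cols = set(META_COLUMNS) - set(sample_meta.columns)
    if missing_cols:
        raise ValidationError(f"sample metadata lacks columns: {sorted(missing_cols)}")
    if sample_meta.index.duplicated().any():
        dups = sample_meta.index[sample_meta.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    sample_ids = list(sample_ids)
    not_in_meta = [s for s in sample_ids if s not in sample_meta.index]
    if not_in_meta:
        raise ValidationError(f"samples missing from metadata: {not_in_meta}")
    extra = [s for s in sample_meta.index if s not in set(sample_ids)]
    if extra:
        raise ValidationError(f"metadata samples absent from expression table: {extra}")
    meta = sample_meta.loc[sample_ids].copy()
    bad_tissue = set(meta["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissue labels: {sorted(bad_tissue)}")
    bad_ploidy = set(meta["ploidy"]) - set(PLOIDIES)
    if bad_ploidy:
        raise ValidationError(f"unknown ploidy labels: {sorted(bad_ploidy)}")
    # Ploidy must be a deterministic function of (species, tissue).
    per_cell = meta.groupby(["species", "tissue"], sort=False)["ploidy"].nunique()
    if (per_cell > 1).any():
        cells = per_cell[per_cell > 1].index.tolist()
        raise ValidationError(f"inconsistent ploidy within (species, tissue) cells: {cells}")
    return meta


def samples_where(sample_meta: pd.DataFrame, **criteria) -> list:
    """Sample ids matching all ``column=value`` criteria."""
    mask = pd.Series(True, index=sample_meta.index)
    for col, val in criteria.items():
        mask &= sample_meta[col] == val
    return list(sample_meta.index[mask])


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (linear scale) plus sample metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (self.values < 0).any().any():
            raise ValidationError("expression values must be nonnegative")
        self.sample_meta = _validate_meta(self.sample_meta, self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, **criteria) -> list:
        return samples_where(self.sample_meta, **criteria)

    def write(self, table_path, meta_path) -> None:
        self.values.rename_axis("gene_id").to_csv(table_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


@dataclass
class PairedExpression:
    """Ortholog-paired expression: one row per pair, columns from both species.

    Rows are indexed by the species-A member of each pair; ``pair_map`` keeps
    the corresponding species-B ids.
    """

    values: pd.DataFrame
    pair_map: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate pair ids in paired matrix")
        if not self.values.index.equals(self.pair_map.index):
            raise ValidationError("pair_map index must match paired matrix rows")
        self.sample_meta = _validate_meta(self.sample_meta, self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_where(self, **criteria) -> list:
        return samples_where(self.sample_meta, **criteria)

    def with_values(self, values: pd.DataFrame) -> "PairedExpression":
        if not values.index.equals(self.values.index):
            raise ValidationError("replacement values must keep the same rows")
        return replace(self, values=values)

    def pairs(self) -> set:
        return {frozenset((a, b)) for a, b in self.pair_map.items()}

    def write(self, table_path, meta_path) -> None:
        self.values.rename_axis("gene_id").to_csv(table_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


@dataclass
class GeneAnnotation:
    """Per-gene phylostratum (1..16), bivalency flag and driver class."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"phylostratum", "bivalent", "driver_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation lacks columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        strata = self.table["phylostratum"]
        if not strata.between(1, N_STRATA).all():
            bad = self.table.index[~strata.between(1, N_STRATA)].tolist()[:5]
            raise ValidationError(f"phylostratum outside 1..{N_STRATA} for genes: {bad}")
        bad_class = set(self.table["driver_class"]) - set(DRIVER_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown driver classes: {sorted(bad_class)}")
        self.table = self.table.assign(
            phylostratum=strata.astype(int), bivalent=self.table["bivalent"].astype(bool)
        )

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, genes) -> pd.DataFrame:
        present = [g for g in genes if g in self.table.index]
        return self.table.loc[present]

    def write(self, path) -> None:
        out = self.table.copy()
        out["bivalent"] = out["bivalent"].astype(int)
        out.rename_axis("gene_id").to_csv(path, sep="\t")


@dataclass
class OrthologyMap:
    """One-to-one orthology: each id appears in at most one pair."""

    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene_a", "gene_b"]))

    def __post_init__(self):
        required = {"gene_a", "gene_b"}
        if set(self.pairs.columns) >= required:
            self.pairs = self.pairs[["gene_a", "gene_b"]].reset_index(drop=True)
        else:
            raise ValidationError("orthology table needs columns gene_a, gene_b")
        for col in ("gene_a", "gene_b"):
            if self.pairs[col].duplicated().any():
                dups = self.pairs.loc[self.pairs[col].duplicated(), col].tolist()[:5]
                raise ValidationError(f"orthology not one-to-one; repeated {col}: {dups}")

    def __len__(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "OrthologyMap":
        flipped = self.pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        return OrthologyMap(flipped)

    def write(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)
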