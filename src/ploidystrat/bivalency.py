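"""Bivalent-gene enrichment, per-stratum bivalency profiles, driver panel."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import N_STRATA, GeneAnnotation
from .errors import ValidationError
from .stats import TailProbability, binom_tail

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BivalencyResult:
    """Outcome of one binomial bivalency-enrichment test."""

    k: int  # bivalent genes in the list
    n: int  # list size
    K: int  # bivalent genes in the background
    N: int  # background size
    p_value: float
    log10_p: float
    direction: str

    def __post_init__(self):
        if not (0 <= self.k <= self.n <= self.N and 0 <= self.K <= self.N):
            raise ValidationError("invalid counts: need 0 <= k <= n <= N and 0 <= K <= N")

    @property
    def fraction(self) -> float:
        return self.k / self.n

    @property
    def p0(self) -> float:
        return self.K / self.N

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "K": self.K,
            "N": self.N,
            "fraction": self.fraction,
            "p0": self.p0,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
            "direction": self.direction,
        }


def bivalent_enrichment_test(
    genes: Sequence[str],
    annotation: GeneAnnotation,
    background: Sequence[str] | None = None,
    direction: str = "greater",
) -> BivalencyResult:
    """Exact binomial test of bivalent-gene over/under-representation.

    The list must be a subset of the background (default background: all
    annotated genes). The tail is computed in log space, so p-values far below
    float underflow are still reported via ``log10_p``.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("empty gene list")
    if background is None:
        background_set = set(annotation.genes)
    else:
        background_set = set(background)
    stray = gene_set - background_set
    if stray:
        raise ValidationError(f"list genes outside the background: {sorted(stray)[:5]}")

    bivalent = set(annotation.table.index[annotation.table["bivalent"]])
    k = len(gene_set & bivalent)
    n = len(gene_set)
    K = len(background_set & bivalent)
    N = len(background_set)
    tail: TailProbability = binom_tail(k, n, K / N, alternative=direction)
    return BivalencyResult(
        k=k, n=n, K=K, N=N, p_value=tail.p, log10_p=tail.log10_p, direction=direction
    )


def bivalent_by_stratum(
    up: Sequence[str], down: Sequence[str], annotation: GeneAnnotation
) -> pd.DataFrame:
    """Per-stratum bivalent fractions for all genes, the up list, the down list.

    A stratum with no genes in a given list yields ``NaN`` (absent), not 0.
    """

    def profile(table: pd.DataFrame) -> pd.Series:
        grouped = table.groupby("phylostratum")["bivalent"].agg(["sum", "size"])
        grouped = grouped.reindex(range(1, N_STRATA + 1))
        return grouped["sum"] / grouped["size"]

    up_tab = annotation.subset(up)
    down_tab = annotation.subset(down)
    out = pd.DataFrame(
        {
            "frac_all": profile(annotation.table),
            "frac_up": profile(up_tab) if not up_tab.empty else np.nan,
            "frac_down": profile(down_tab) if not down_tab.empty else np.nan,
        }
    )
    out.index.name = "stratum"
    return out


@dataclass(frozen=True)
class DriverComparison:
    """One-sided comparison of bivalent fractions between driver groups."""

    name: str
    k: int
    n: int
    p0: float
    p_value: float
    log10_p: float

    def as_dict(self) -> dict:
        return {
            "comparison": self.name,
            "k": self.k,
            "n": self.n,
            "p0": self.p0,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
        }


def driver_panel(
    up: Sequence[str],
    down: Sequence[str],
    annotation: GeneAnnotation,
    contrasts: pd.DataFrame | None = None,
    method: str = "binomial",
) -> tuple[pd.DataFrame, list]:
    """Driver genes (oncogenes / tumour suppressors) in the ploidy lists.

    Returns the per-gene panel table plus pairwise comparisons of bivalent
    fractions: up-oncogenes against down-oncogenes and against tumour
    suppressors. ``method="binomial"`` uses an exact one-sided binomial with
    the reference group's fraction as null probability; ``method="fisher"``
    the two-sample Fisher exact alternative. Groups without members are
    skipped with a notice.
    """
    if method not in ("binomial", "fisher"):
        raise ValidationError(f"method must be 'binomial' or 'fisher', got {method!r}")
    rows = []
    for direction, genes in (("up", up), ("down", down)):
        sub = annotation.subset(genes)
        drivers = sub[sub["driver_class"] != "none"]
        for gene, rec in drivers.iterrows():
            fold = np.nan
            if contrasts is not None and gene in contrasts.index:
                mean_lfc = (contrasts.loc[gene, "lfc_heart"] + contrasts.loc[gene, "lfc_liver"]) / 2
                fold = float(2.0**mean_lfc)
            rows.append(
                {
                    "gene": gene,
                    "driver_class": rec["driver_class"],
                    "direction": direction,
                    "fold": fold,
                    "stratum": int(rec["phylostratum"]),
                    "bivalent": bool(rec["bivalent"]),
                }
            )
    panel = pd.DataFrame(rows, columns=["gene", "driver_class", "direction", "fold", "stratum", "bivalent"])
    if panel.empty:
        log.info("no driver genes found in the lists; comparisons skipped")
        return panel, []

    def group(direction, klass):
        sub = panel[(panel["direction"] == direction) & (panel["driver_class"] == klass)]
        return int(sub["bivalent"].sum()), len(sub)

    k_ref = {
        "down_oncogenes": group("down", "oncogene"),
        "up_tumour_suppressors": group("up", "tumour_suppressor"),
        "down_tumour_suppressors": group("down", "tumour_suppressor"),
    }
    k_up, n_up = group("up", "oncogene")
    comparisons = []
    if n_up == 0:
        log.info("no upregulated oncogenes; comparisons skipped")
        return panel, comparisons
    for name, (k2, n2) in k_ref.items():
        if n2 == 0:
            log.info("reference group %s empty; comparison skipped", name)
            continue
        if method == "binomial":
            tail = binom_tail(k_up, n_up, k2 / n2, alternative="greater")
            p, lp = tail.p, tail.log10_p
        else:
            table = [[k_up, n_up - k_up], [k2, n2 - k2]]
            p = float(sps.fisher_exact(table, alternative="greater")[1])
            lp = float(np.log10(p)) if p > 0 else -np.inf
        comparisons.append(
            DriverComparison(
                name=f"up_oncogenes_vs_{name}",
                k=k_up,
                n=n_up,
                p0=k2 / n2,
                p_value=p,
                log10_p=lp,
            )
        )
    return panel, comparisons
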