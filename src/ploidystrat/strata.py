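"""Phylostratum distributions and per-stratum enrichment tests.

Gene lists are compared stratum by stratum against the annotated background
with an exact binomial test, one-sided in the direction of the observed
deviation, followed by Benjamini-Hochberg correction across the 16 strata
within each list.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import N_STRATA, GeneAnnotation
from .errors import ValidationError
from .stats import bh_adjust, binom_tail

log = logging.getLogger(__name__)


def _annotated(genes: Sequence[str], annotation: GeneAnnotation, what: str) -> pd.DataFrame:
    genes = list(genes)
    if not genes:
        raise ValidationError(f"{what}: empty gene list")
    sub = annotation.subset(genes)
    n_dropped = len(set(genes)) - len(sub)
    if n_dropped:
        log.warning("%s: dropped %d unannotated genes", what, n_dropped)
    if sub.empty:
        raise ValidationError(f"{what}: no genes remain after annotation filtering")
    return sub


def _stratum_counts(table: pd.DataFrame) -> pd.Series:
    counts = table["phylostratum"].value_counts()
    return counts.reindex(range(1, N_STRATA + 1), fill_value=0).astype(int)


def stratum_distribution(genes: Sequence[str], annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-stratum counts and proportions of a gene list.

    Unannotated genes are dropped with a warning; an empty post-filter list is
    an error. Proportions sum to 1 over strata 1..16.
    """
    sub = _annotated(genes, annotation, "stratum_distribution")
    counts = _stratum_counts(sub)
    out = pd.DataFrame({"n": counts, "proportion": counts / counts.sum()})
    out.index.name = "stratum"
    return out


def _one_list_tests(counts: pd.Series, n: int, bg_fraction: pd.Series):
    p_values, log10_p, directions = [], [], []
    for s in counts.index:
        k, p0 = int(counts[s]), float(bg_fraction[s])
        direction = "greater" if (n > 0 and k / n >= p0) else "less"
        tail = binom_tail(k, n, p0, alternative=direction)
        p_values.append(tail.p)
        log10_p.append(tail.log10_p)
        directions.append(direction)
    return np.array(p_values), np.array(log10_p), directions


def stratum_shift_test(
    up: Sequence[str],
    down: Sequence[str],
    annotation: GeneAnnotation,
    compare: str = "background",
) -> pd.DataFrame:
    """Per-stratum enrichment of the up and down lists.

    ``compare="background"`` (default) tests each list's stratum count
    against the background stratum fraction with an exact binomial tail in the
    direction of the deviation. ``compare="up_vs_down"`` adds a two-sided
    Fisher exact comparison of the two lists per stratum.
    """
    if compare not in ("background", "up_vs_down"):
        raise ValidationError(f"compare must be 'background' or 'up_vs_down', got {compare!r}")
    up_tab = _annotated(up, annotation, "up list")
    down_tab = _annotated(down, annotation, "down list")
    bg_counts = _stratum_counts(annotation.table)
    bg_fraction = bg_counts / bg_counts.sum()

    up_counts = _stratum_counts(up_tab)
    down_counts = _stratum_counts(down_tab)
    n_up, n_down = int(up_counts.sum()), int(down_counts.sum())

    p_up, lp_up, dir_up = _one_list_tests(up_counts, n_up, bg_fraction)
    p_down, lp_down, dir_down = _one_list_tests(down_counts, n_down, bg_fraction)

    out = pd.DataFrame(
        {
            "n_up": up_counts,
            "n_down": down_counts,
            "n_background": bg_counts,
            "prop_up": up_counts / n_up,
            "prop_down": down_counts / n_down,
            "prop_bg": bg_fraction,
            "p_up": p_up,
            "p_down": p_down,
            "log10_p_up": lp_up,
            "log10_p_down": lp_down,
            "q_up": bh_adjust(p_up),
            "q_down": bh_adjust(p_down),
            "direction_up": dir_up,
            "direction_down": dir_down,
        }
    )
    out.index.name = "stratum"

    if compare == "up_vs_down":
        fisher = []
        for s in out.index:
            table = [
                [int(out.loc[s, "n_up"]), n_up - int(out.loc[s, "n_up"])],
                [int(out.loc[s, "n_down"]), n_down - int(out.loc[s, "n_down"])],
            ]
            fisher.append(sps.fisher_exact(table, alternative="two-sided")[1])
        out["p_up_vs_down"] = fisher
        out["q_up_vs_down"] = bh_adjust(np.array(fisher))
    return out


def aggregate_shift(shift: pd.DataFrame) -> dict:
    """Old-strata (1-3) vs young-strata (6-16) shares for a quick shift read-out."""
    old = list(range(1, 4))
    young = list(range(6, N_STRATA + 1))
    return {
        "up_old_share": float(shift.loc[old, "prop_up"].sum()),
        "bg_old_share": float(shift.loc[old, "prop_bg"].sum()),
        "down_young_share": float(shift.loc[young, "prop_down"].sum()),
        "bg_young_share": float(shift.loc[young, "prop_bg"].sum()),
    }
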