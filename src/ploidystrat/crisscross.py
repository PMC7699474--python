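"""Reciprocal polyploid-vs-diploid contrasts and concordant gene selection.

Within each tissue pair the fold change is always oriented polyploid minus
diploid, so a gene driven by ploidy moves the same way in both tissues while
a species-driven gene moves in opposite directions and is filtered out as
discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .datatypes import TISSUES, PairedExpression
from .errors import ValidationError

log = logging.getLogger(__name__)

CALLS = ("up", "down", "discordant", "below_threshold")


@dataclass
class ContrastResult:
    """Per-gene reciprocal log2 fold changes plus the concordance call."""

    table: pd.DataFrame
    threshold_fold: float | None = None

    @property
    def up(self) -> list:
        return list(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> list:
        return list(self.table.index[self.table["call"] == "down"])


def compute_ploidy_contrasts(paired: PairedExpression) -> pd.DataFrame:
    """Per-gene lfc_heart and lfc_liver (log2, polyploid minus diploid).

    Expects ``paired.values`` already log2-transformed and normalized. The
    fold change per tissue is the difference of unweighted means of the
    polyploid and diploid sample groups.
    """
    out = {}
    for tissue in TISSUES:
        poly = paired.samples_where(tissue=tissue, ploidy="polyploid")
        dip = paired.samples_where(tissue=tissue, ploidy="diploid")
        if not poly or not dip:
            raise ValidationError(
                f"missing condition cell: tissue={tissue} needs both polyploid and diploid samples"
            )
        out[f"lfc_{tissue}"] = paired.values[poly].mean(axis=1) - paired.values[dip].mean(axis=1)
    return pd.DataFrame(out)


def classify_calls(contrasts: pd.DataFrame, threshold_fold: float) -> pd.Series:
    """Concordance call per gene at a linear fold threshold (inclusive)."""
    if threshold_fold <= 1:
        raise ValidationError(f"threshold_fold must be > 1, got {threshold_fold}")
    cutoff = np.log2(threshold_fold)
    heart, liver = contrasts["lfc_heart"], contrasts["lfc_liver"]
    up = (heart >= cutoff) & (liver >= cutoff)
    down = (heart <= -cutoff) & (liver <= -cutoff)
    discordant = (heart.abs() >= cutoff) & (liver.abs() >= cutoff) & ~up & ~down
    call = pd.Series("below_threshold", index=contrasts.index, name="call")
    call[up] = "up"
    call[down] = "down"
    call[discordant] = "discordant"
    return call


def select_concordant_genes(contrasts: pd.DataFrame, threshold_fold: float) -> tuple[list, list]:
    """Genes concordantly up / down in both tissue contrasts at a fold cutoff."""
    call = classify_calls(contrasts, threshold_fold)
    up = list(contrasts.index[call == "up"])
    down = list(contrasts.index[call == "down"])
    log.info(
        "fold %.2f: %d upregulated, %d downregulated, %d discordant",
        threshold_fold,
        len(up),
        len(down),
        int((call == "discordant").sum()),
    )
    return up, down


def contrast_table(
    paired: PairedExpression, threshold_fold: float, moderated: bool = False
) -> ContrastResult:
    """Full per-gene contrast table (lfcs, call, optionally moderated t / p)."""
    contrasts = compute_ploidy_contrasts(paired)
    table = contrasts.assign(call=classify_calls(contrasts, threshold_fold))
    if moderated:
        table = table.join(moderated_test(paired))
    return ContrastResult(table=table, threshold_fold=threshold_fold)


# --- simplified empirical-Bayes moderation -------------------------------
#
# Per-gene residual variances (pooled over the four design cells) are shrunk
# toward a common prior fitted by matching the moments of log variances, and
# the contrast t statistics gain the prior degrees of freedom. This is a
# documented simplification of moderated differential-expression statistics,
# not a replica of precision-weighted model fits.


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` from sample variances.

    Moment matching on ``log(s2)``: under the scaled-chi-square model the
    excess spread of log variances beyond ``trigamma(df/2)`` determines the
    prior degrees of freedom. Genes with zero variance are excluded from the
    fit. Returns ``(d0, s0_squared)`` with ``d0 = inf`` when no excess spread
    remains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all gene variances are zero; cannot fit a variance prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if ok.sum() < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_test(paired: PairedExpression) -> pd.DataFrame:
    """Moderated two-sided t-test per tissue contrast.

    Requires >= 2 replicates in each of the four (tissue, ploidy) cells;
    otherwise raises instructing fold-only mode. Returns columns
    ``t_heart, p_heart, t_liver, p_liver``.
    """
    cells = {}
    for tissue in TISSUES:
        for ploidy in ("polyploid", "diploid"):
            samples = paired.samples_where(tissue=tissue, ploidy=ploidy)
            if len(samples) < 2:
                raise ValidationError(
                    f"cell (tissue={tissue}, ploidy={ploidy}) has {len(samples)} sample(s); "
                    "moderated statistics need >= 2 replicates per cell - use fold-only mode"
                )
            cells[(tissue, ploidy)] = samples

    values = paired.values
    n_total = sum(len(s) for s in cells.values())
    df_resid = n_total - len(cells)
    rss = np.zeros(len(values))
    means = {}
    for key, samples in cells.items():
        sub = values[samples]
        mean = sub.mean(axis=1)
        means[key] = mean
        rss += ((sub.sub(mean, axis=0)) ** 2).sum(axis=1).to_numpy()
    s2 = rss / df_resid

    d0, s0_2 = squeeze_variances(s2, df_resid)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    out = {}
    for tissue in TISSUES:
        n1 = len(cells[(tissue, "polyploid")])
        n2 = len(cells[(tissue, "diploid")])
        diff = means[(tissue, "polyploid")] - means[(tissue, "diploid")]
        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = 2.0 * sps.t.sf(np.abs(t), df_total)
        out[f"t_{tissue}"] = t
        out[f"p_{tissue}"] = np.minimum(p, 1.0)
    return pd.DataFrame(out, index=values.index)
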