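"""PCA with samples as variables and genes as statistical units.

The decomposition is covariance PCA on sample-centered log2 values. Each
component's gene scores are standardized to unit variance so that a cutoff of
2 means two standard deviations. Components are assigned to the design
factors (tissue, species, ploidy) by point-biserial correlation of their
sample loadings with the factor indicators; the highest-variance leftover
component is labeled batch when its loadings follow the batch blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

#: Greedy assignment order, by descending expected variance share.
FACTOR_ORDER = ("tissue", "species", "ploidy")
MIN_ABS_R = 0.5
MIN_BATCH_R = 0.7


@dataclass
class PloidyComponents:
    """PCA decomposition plus (optional) component -> factor assignment."""

    loadings: pd.DataFrame  # component x sample
    scores: pd.DataFrame  # gene x component, unit variance per component
    variance_explained: pd.Series  # per component, non-increasing
    assignment: dict = field(default_factory=dict)  # factor -> component
    correlations: pd.DataFrame | None = None  # factor x component, |r|

    @property
    def components(self) -> pd.Index:
        return self.loadings.index

    def component_for(self, factor: str) -> str:
        if factor not in self.assignment or self.assignment[factor] is None:
            raise ValidationError(f"factor {factor!r} has no assigned component")
        return self.assignment[factor]


def run_pca(values: pd.DataFrame) -> PloidyComponents:
    """Full-rank covariance PCA of a gene x sample log2 matrix.

    Columns (sample variables) are mean-centered before the singular value
    decomposition; no further scaling is applied.
    """
    X = values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValidationError(f"PCA needs >= 4 samples (one per design cell), got {n_samples}")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc**2).sum())
    if total_var <= 0:
        raise ValidationError("zero-variance matrix; PCA is undefined")

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    names = [f"PC{i + 1}" for i in range(len(S))]
    loadings = pd.DataFrame(Vt, index=names, columns=values.columns)
    raw_scores = U * S  # gene projections
    sd = raw_scores.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        standardized = np.where(sd > 0, raw_scores / np.where(sd > 0, sd, 1.0), 0.0)
    scores = pd.DataFrame(standardized, index=values.index, columns=names)
    variance = pd.Series(S**2 / total_var, index=names, name="variance_explained")
    return PloidyComponents(loadings=loadings, scores=scores, variance_explained=variance)


def _point_biserial(loading: np.ndarray, indicator: np.ndarray) -> float:
    if loading.std() == 0 or indicator.std() == 0:
        return 0.0
    return float(np.corrcoef(loading, indicator)[0, 1])


def _block_r(loading: np.ndarray, blocks: pd.Series) -> float:
    """Multiple correlation between loadings and the batch block means."""
    centered = loading - loading.mean()
    ss_total = float((centered**2).sum())
    if ss_total == 0:
        return 0.0
    fitted = pd.Series(loading).groupby(blocks.to_numpy()).transform("mean").to_numpy()
    ss_model = float(((fitted - loading.mean()) ** 2).sum())
    return float(np.sqrt(max(0.0, min(1.0, ss_model / ss_total))))


def assign_components(components: PloidyComponents, sample_meta: pd.DataFrame) -> PloidyComponents:
    """Greedy component -> factor assignment without component reuse.

    Tissue, species and ploidy each take the unused component maximizing the
    absolute point-biserial correlation of its loadings with the factor
    indicator; matches below |r| = 0.5 stay unassigned. The highest-variance
    remaining component is labeled batch when its loadings track the batch
    blocks. The ploidy component is sign-oriented so polyploid samples load
    positively.
    """
    meta = sample_meta.loc[components.loadings.columns]
    if len(components.components) < 4:
        raise ValidationError("fewer components than design factors")
    indicators = {
        "tissue": (meta["tissue"] == "heart").to_numpy(dtype=float),
        "species": (meta["species"] == "A").to_numpy(dtype=float),
        "ploidy": (meta["ploidy"] == "polyploid").to_numpy(dtype=float),
    }

    corr = pd.DataFrame(
        {
            comp: {
                factor: _point_biserial(components.loadings.loc[comp].to_numpy(), ind)
                for factor, ind in indicators.items()
            }
            for comp in components.components
        }
    )

    assignment: dict = {}
    used: set = set()
    for factor in FACTOR_ORDER:
        available = [c for c in components.components if c not in used]
        best = max(available, key=lambda c: abs(corr.loc[factor, c]))
        if abs(corr.loc[factor, best]) >= MIN_ABS_R:
            assignment[factor] = best
            used.add(best)
        else:
            assignment[factor] = None

    remaining = [c for c in components.components if c not in used]
    batch_comp = None
    if remaining:
        candidate = remaining[0]  # components are ordered by variance
        blocks = meta["batch"]
        r_batch = _block_r(components.loadings.loc[candidate].to_numpy(), blocks)
        if r_batch >= MIN_BATCH_R:
            batch_comp = candidate
        corr.loc["batch", :] = [
            _block_r(components.loadings.loc[c].to_numpy(), blocks) for c in components.components
        ]
    assignment["batch"] = batch_comp

    out = replace(components, assignment=assignment, correlations=corr)
    if assignment.get("ploidy"):
        comp = assignment["ploidy"]
        load = out.loadings.loc[comp].to_numpy()
        poly = indicators["ploidy"].astype(bool)
        if load[poly].mean() < load[~poly].mean():
            out.loadings.loc[comp] = -out.loadings.loc[comp]
            out.scores[comp] = -out.scores[comp]
            if out.correlations is not None:
                rows = list(FACTOR_ORDER)
                out.correlations.loc[rows, comp] = -out.correlations.loc[rows, comp]
    for factor, comp in assignment.items():
        if comp is not None:
            log.info(
                "%s -> %s (variance %.1f%%)",
                factor,
                comp,
                100 * out.variance_explained[comp],
            )
    return out


def select_component_genes(
    components: PloidyComponents, threshold: float = 2.0
) -> tuple[list, list]:
    """Genes with extreme standardized scores on the ploidy component.

    Inclusive at the cutoff: ``score >= threshold`` is up, ``<= -threshold``
    is down (after sign orientation).
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    comp = components.component_for("ploidy")
    z = components.scores[comp]
    up = list(z.index[z >= threshold])
    down = list(z.index[z <= -threshold])
    log.info("ploidy component %s: %d up, %d down at |score| >= %g", comp, len(up), len(down), threshold)
    return up, down
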