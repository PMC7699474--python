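"""Synthetic data with planted structure for every downstream stage.

The generators emulate the reciprocal criss-cross design: species A carries a
polyploid heart and a diploid liver, species B the reverse. A planted set of
genes receives an additive ploidy effect on the log2 scale whose sign depends
on the gene's phylostratum (old strata mostly up, young strata mostly down),
and the planted up-set is enriched in bivalent genes. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    CRISSCROSS_PLOIDY,
    N_STRATA,
    ExpressionMatrix,
    GeneAnnotation,
    OrthologyMap,
)
from .errors import ValidationError
from .ontology import Ontology

#: Genome-wide phylostratum frequencies used by default (old strata heavy,
#: recent strata sparse); sums to 1 over strata 1..16.
DEFAULT_STRATUM_PROBS = np.array(
    [0.24, 0.13, 0.05, 0.09, 0.07, 0.10, 0.05, 0.11, 0.03, 0.04, 0.02, 0.03, 0.01, 0.01, 0.01, 0.01]
)

#: Probability that a planted gene of a given stratum is planted *up*:
#: high for unicellular strata 1-3, neutral for early metazoan 4-5, low for
#: bilaterian-and-later 6-16.
DEFAULT_SIGN_PROBS = {s: (0.8 if s <= 3 else 0.5 if s <= 5 else 0.2) for s in range(1, N_STRATA + 1)}

BACKGROUND_BIVALENT_RATE = 3024 / 14093


def _as_mapping(probs) -> dict:
    if isinstance(probs, Mapping):
        out = {int(k): float(v) for k, v in probs.items()}
    else:
        out = {s + 1: float(v) for s, v in enumerate(probs)}
    missing = set(range(1, N_STRATA + 1)) - set(out)
    if missing:
        raise ValidationError(f"stratum_sign_probs lacks strata: {sorted(missing)}")
    return out


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of one simulated study."""

    seed: int
    planted_up: frozenset
    planted_down: frozenset
    effect_size: Mapping[str, float]
    stratum_sign_probs: Mapping[int, float]
    bivalent_rate_background: float
    bivalent_rate_up: float
    noise_sd: float
    batch_sd: float
    tissue_effect: float
    species_effect: float

    def __post_init__(self):
        if self.planted_up & self.planted_down:
            raise ValidationError("planted_up and planted_down must be disjoint")
        for name in ("bivalent_rate_background", "bivalent_rate_up"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {rate}")
        for s, p in self.stratum_sign_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"stratum_sign_probs[{s}] must be in [0, 1]")

    def delta(self, genes: pd.Index) -> np.ndarray:
        """Signed per-gene ploidy effect over an index of genes."""
        d = np.zeros(len(genes))
        for i, g in enumerate(genes):
            if g in self.planted_up:
                d[i] = self.effect_size[g]
            elif g in self.planted_down:
                d[i] = -self.effect_size[g]
        return d


@dataclass
class SimulationParams:
    """Knobs for one synthetic study; defaults mirror the magnitudes of the
    real analysis (14,093 annotated ortholog pairs, 584 up / 711 down planted
    genes, ~21.5% background bivalency vs 45.7% among the up-set)."""

    n_genes: int = 14093
    n_up: int = 584
    n_down: int = 711
    effect_low: float = 1.0
    effect_high: float = 2.5
    stratum_probs: Sequence[float] = field(default_factory=lambda: DEFAULT_STRATUM_PROBS.copy())
    stratum_sign_probs: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_SIGN_PROBS))
    bivalent_rate_background: float = BACKGROUND_BIVALENT_RATE
    bivalent_rate_up: float = 0.457
    driver_rates: tuple = (0.02, 0.015)
    noise_sd: float = 0.25
    batch_sd: float = 0.25
    tissue_effect: float = 1.2
    species_effect: float = 0.6
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_reps: int = 4


def noiseless_params(**overrides) -> SimulationParams:
    """Parameters under which criss-cross selection must recover the planted
    sets exactly: all stochastic nuisance terms (noise, batch, per-gene
    species bias) are zeroed and effects clear the 2-fold cutoff with margin.

    The tissue effect is kept nonzero on purpose: it cancels within each
    tissue pair, which is the point of the reciprocal design.
    """
    params = SimulationParams(
        noise_sd=0.0,
        batch_sd=0.0,
        species_effect=0.0,
        effect_low=1.1,
        baseline_mean=9.0,
        baseline_sd=1.0,
    )
    for key, value in overrides.items():
        setattr(params, key, value)
    return params


def species_b_id(gene_a: str) -> str:
    """Species-B ortholog id for a species-A gene id."""
    return "GB" + gene_a[2:] if gene_a.startswith("GA") else gene_a + "_B"


def generate_annotation(n_genes, stratum_probs, bivalent_rate, driver_rates, seed) -> GeneAnnotation:
    """Random gene annotation: phylostratum, bivalency flag, driver class.

    ``stratum_probs`` are 16 probabilities over strata 1..16 summing to 1
    (within 1e-9). Bivalent flags are independent Bernoulli(bivalent_rate);
    driver classes (oncogene / tumour suppressor) are mutually exclusive draws
    at the two ``driver_rates``.
    """
    if n_genes < 1:
        raise ValidationError(f"n_genes must be >= 1, got {n_genes}")
    probs = np.asarray(stratum_probs, dtype=float)
    if probs.size != N_STRATA:
        raise ValidationError(f"need {N_STRATA} stratum probabilities, got {probs.size}")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"stratum probabilities sum to {probs.sum()}, expected 1")
    if not 0.0 <= bivalent_rate <= 1.0:
        raise ValidationError("bivalent_rate must be in [0, 1]")
    r_onc, r_ts = driver_rates
    if r_onc < 0 or r_ts < 0 or r_onc + r_ts > 1:
        raise ValidationError("driver_rates must be nonnegative and sum to <= 1")

    rng = np.random.default_rng(seed)
    genes = pd.Index([f"GA{i:05d}" for i in range(n_genes)], name="gene_id")
    strata = rng.choice(np.arange(1, N_STRATA + 1), size=n_genes, p=probs)
    bivalent = rng.random(n_genes) < bivalent_rate
    u = rng.random(n_genes)
    driver = np.select([u < r_onc, u < r_onc + r_ts], ["oncogene", "tumour_suppressor"], "none")
    table = pd.DataFrame(
        {"phylostratum": strata, "bivalent": bivalent, "driver_class": driver}, index=genes
    )
    return GeneAnnotation(table)


def plant_truth(
    annotation: GeneAnnotation, params: SimulationParams, seed: int
) -> tuple[SyntheticTruth, GeneAnnotation]:
    """Choose the planted up/down sets and their effect sizes.

    Up genes are drawn without replacement with weights proportional to their
    stratum's sign probability; down genes from the remainder with the
    complementary weights. Bivalent flags of the planted up-set are redrawn at
    ``bivalent_rate_up``. Returns the truth plus the updated annotation.
    """
    n = len(annotation)
    if params.n_up + params.n_down > n:
        raise ValidationError("cannot plant more genes than the annotation contains")
    sign_probs = _as_mapping(params.stratum_sign_probs)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    genes = annotation.genes.to_numpy()
    w_up = annotation.table["phylostratum"].map(sign_probs).to_numpy(dtype=float)

    up = rng.choice(genes, size=params.n_up, replace=False, p=w_up / w_up.sum())
    up_set = set(up)
    rest_mask = ~np.isin(genes, up)
    w_down = (1.0 - w_up)[rest_mask]
    if w_down.sum() <= 0:
        raise ValidationError("down-weights are all zero; adjust stratum_sign_probs")
    down = rng.choice(genes[rest_mask], size=params.n_down, replace=False, p=w_down / w_down.sum())

    planted = list(up) + list(down)
    sizes = rng.uniform(params.effect_low, params.effect_high, size=len(planted))
    effect_size = dict(zip(planted, sizes))

    table = annotation.table.copy()
    table.loc[list(up), "bivalent"] = rng.random(len(up)) < params.bivalent_rate_up
    truth = SyntheticTruth(
        seed=seed,
        planted_up=frozenset(up),
        planted_down=frozenset(down),
        effect_size=effect_size,
        stratum_sign_probs=sign_probs,
        bivalent_rate_background=params.bivalent_rate_background,
        bivalent_rate_up=params.bivalent_rate_up,
        noise_sd=params.noise_sd,
        batch_sd=params.batch_sd,
        tissue_effect=params.tissue_effect,
        species_effect=params.species_effect,
    )
    return truth, GeneAnnotation(table)


def generate_expression(
    truth: SyntheticTruth,
    annotation: GeneAnnotation,
    n_reps: int,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Linear-scale expression matrices for both species of the criss-cross.

    On the log2 scale each value is::

        baseline_g + tissue_g * [heart] + species_g * [species A]
        + batch_(block,g) + delta_g * [polyploid] + Normal(0, noise_sd)

    with the per-gene tissue/species terms drawn once from
    ``Normal(0, truth.tissue_effect)`` / ``Normal(0, truth.species_effect)``
    and one batch vector per (species, tissue) block. Ploidy follows the
    criss-cross table. Output is ``2 ** log2value`` (linear, nonnegative).
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 1]))
    genes = annotation.genes
    n = len(genes)

    baseline = rng.normal(baseline_mean, baseline_sd, n)
    tissue_vec = rng.normal(0.0, truth.tissue_effect, n)
    species_vec = rng.normal(0.0, truth.species_effect, n)
    delta = truth.delta(genes)

    matrices = {}
    for species in ("A", "B"):
        cols, meta_rows = {}, []
        for tissue in ("heart", "liver"):
            batch_vec = rng.normal(0.0, truth.batch_sd, n)
            is_poly = CRISSCROSS_PLOIDY[(species, tissue)] == "polyploid"
            block = (
                baseline
                + tissue_vec * (tissue == "heart")
                + species_vec * (species == "A")
                + batch_vec
                + delta * is_poly
            )
            for rep in range(1, n_reps + 1):
                sample = f"{species}_{tissue}_r{rep}"
                noise = rng.normal(0.0, truth.noise_sd, n) if truth.noise_sd > 0 else 0.0
                cols[sample] = np.exp2(block + noise)
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "species": species,
                        "tissue": tissue,
                        "ploidy": "polyploid" if is_poly else "diploid",
                        "batch": f"{species}_{tissue}",
                        "replicate": rep,
                    }
                )
        index = genes if species == "A" else pd.Index([species_b_id(g) for g in genes], name="gene_id")
        values = pd.DataFrame(cols, index=index)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        matrices[species] = ExpressionMatrix(values=values, sample_meta=meta)
    return matrices["A"], matrices["B"], truth


def orthology_for(annotation: GeneAnnotation) -> OrthologyMap:
    """The trivial one-to-one map between the two synthetic species."""
    pairs = pd.DataFrame(
        {"gene_a": annotation.genes, "gene_b": [species_b_id(g) for g in annotation.genes]}
    )
    return OrthologyMap(pairs)


def _draw_distinct(rng, total: int, count: int) -> np.ndarray:
    """``count`` distinct integers from ``range(total)``."""
    if count >= total:
        return np.arange(total)
    picked = np.unique(rng.integers(0, total, size=int(count * 1.2) + 16))
    while picked.size < count:
        more = rng.integers(0, total, size=count)
        picked = np.unique(np.concatenate([picked, more]))
    return rng.permutation(picked)[:count]


def _decode_triangle(idx: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices of the strict upper triangle of an m x m grid to (i, j)."""
    idx = idx.astype(np.int64)
    b = 2 * m - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    # guard against float rounding at row boundaries
    for _ in range(2):
        start = i * (b - i) // 2
        i = np.where(idx < start, i - 1, i)
        start = i * (b - i) // 2
        i = np.where(idx >= start + (m - 1 - i), i + 1, i)
    start = i * (b - i) // 2
    j = idx - start + i + 1
    return i, j


def generate_interactions(
    genes: Sequence[str],
    mean_degree: float,
    up_connectivity_boost: float,
    truth: SyntheticTruth,
    seed: int,
) -> nx.Graph:
    """Random simple graph with boosted connectivity for planted-up genes.

    The base edge probability is ``mean_degree / (n - 1)``; an edge's
    probability is multiplied by ``up_connectivity_boost`` once per planted-up
    endpoint. No self-loops, no duplicate edges.
    """
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise ValidationError("need at least 2 genes for an interaction graph")
    if mean_degree < 0 or mean_degree >= n - 1:
        raise ValidationError(f"mean_degree must be in [0, n-1), got {mean_degree} for n={n}")
    if up_connectivity_boost < 1:
        raise ValidationError("up_connectivity_boost must be >= 1")
    p = mean_degree / (n - 1)
    if p * up_connectivity_boost**2 > 1:
        raise ValidationError("mean_degree infeasible at this connectivity boost")

    rng = np.random.default_rng(seed)
    up_nodes = sorted(g for g in genes if g in truth.planted_up)
    other_nodes = sorted(g for g in genes if g not in truth.planted_up)
    graph = nx.Graph()
    graph.add_nodes_from(genes)

    def add_within(nodes, prob):
        m = len(nodes)
        total = m * (m - 1) // 2
        if total == 0 or prob <= 0:
            return
        count = rng.binomial(total, prob)
        i, j = _decode_triangle(_draw_distinct(rng, total, count), m)
        graph.add_edges_from((nodes[a], nodes[b]) for a, b in zip(i, j))

    def add_across(left, right, prob):
        total = len(left) * len(right)
        if total == 0 or prob <= 0:
            return
        count = rng.binomial(total, prob)
        idx = _draw_distinct(rng, total, count)
        graph.add_edges_from((left[k // len(right)], right[k % len(right)]) for k in idx)

    boost = up_connectivity_boost
    add_within(up_nodes, min(1.0, p * boost * boost))
    add_across(up_nodes, other_nodes, min(1.0, p * boost))
    add_within(other_nodes, p)
    return graph


def generate_ontology(
    genes: Sequence[str],
    n_terms: int = 30,
    mean_genes_per_term: int = 25,
    seed: int = 0,
) -> Ontology:
    """Small random DAG ontology with random direct gene-to-term assignments."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 if i < 3 else rng.integers(1, 3)
        for parent in rng.choice(i, size=min(int(n_parents), i), replace=False):
            edges.append((terms[i], terms[int(parent)]))
    term_genes = {}
    for t in terms:
        size = min(len(genes), max(1, int(rng.poisson(mean_genes_per_term))))
        term_genes[t] = set(rng.choice(genes, size=size, replace=False))
    labels = {t: f"synthetic module {t}" for t in terms}
    return Ontology(terms=set(terms), edges=edges, term_genes=term_genes, labels=labels)


@dataclass
class SimulatedStudy:
    """Everything one simulated run produces, ready for the pipeline."""

    params: SimulationParams
    truth: SyntheticTruth
    annotation: GeneAnnotation
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    orthology: OrthologyMap


def simulate_study(params: SimulationParams, seed: int) -> SimulatedStudy:
    """Generate annotation, planted truth and both expression matrices."""
    annotation = generate_annotation(
        params.n_genes, params.stratum_probs, params.bivalent_rate_background, params.driver_rates, seed
    )
    truth, annotation = plant_truth(annotation, params, seed)
    expr_a, expr_b, truth = generate_expression(
        truth, annotation, params.n_reps, params.baseline_mean, params.baseline_sd
    )
    return SimulatedStudy(
        params=params,
        truth=truth,
        annotation=annotation,
        expr_a=expr_a,
        expr_b=expr_b,
        orthology=orthology_for(annotation),
    )
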