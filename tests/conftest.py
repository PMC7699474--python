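"""Shared fixtures: small deterministic studies and oracle helpers."""

from __future__ import annotations

import math
from fractions import Fraction

import pandas as pd
import pytest

from ploidystrat import crisscross, ingest
from ploidystrat.datatypes import ExpressionMatrix, GeneAnnotation
from ploidystrat.pipeline import normalize_paired
from ploidystrat.synthetic import SimulationParams, noiseless_params, simulate_study

# ---------------------------------------------------------------------------
# independent oracles (arbitrary precision; never share code with the package)


def binom_tail_oracle(k: int, n: int, p0: Fraction, alternative: str = "greater") -> Fraction:
    """Exact binomial tail by rational-arithmetic summation."""
    p0 = Fraction(p0)
    ks = range(k, n + 1) if alternative == "greater" else range(0, k + 1)
    total = Fraction(0)
    for i in ks:
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return total


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int, alternative: str = "greater") -> Fraction:
    """Exact hypergeometric tail by rational-arithmetic summation."""
    lo, hi = max(0, n + K - N), min(n, K)
    ks = range(k, hi + 1) if alternative == "greater" else range(lo, k + 1)
    denom = math.comb(N, n)
    return Fraction(sum(math.comb(K, i) * math.comb(N - K, n - i) for i in ks), denom)


def log10_fraction(x: Fraction) -> float:
    """log10 of a positive Fraction without float underflow."""
    assert x > 0
    return math.log10(x.numerator) - math.log10(x.denominator)


@pytest.fixture(scope="session")
def oracles():
    return {
        "binom": binom_tail_oracle,
        "hypergeom": hypergeom_tail_oracle,
        "log10": log10_fraction,
    }


# ---------------------------------------------------------------------------
# synthetic studies


def small_params(**overrides) -> SimulationParams:
    params = SimulationParams(n_genes=400, n_up=40, n_down=50, n_reps=3)
    for key, value in overrides.items():
        setattr(params, key, value)
    return params


@pytest.fixture(scope="session")
def small_study():
    """A small noisy study for fast unit tests."""
    return simulate_study(small_params(), seed=7)


@pytest.fixture(scope="session")
def small_paired(small_study):
    paired = ingest.match_orthologs(
        small_study.expr_a, small_study.expr_b, small_study.orthology, small_study.annotation
    )
    return normalize_paired(paired)


@pytest.fixture(scope="session")
def noiseless_study():
    """Exact-recovery regime: no noise/batch/species terms, effects >= 1.1."""
    return simulate_study(noiseless_params(n_genes=400, n_up=40, n_down=50, n_reps=2), seed=3)


@pytest.fixture(scope="session")
def default_study():
    """One full-scale study at the default parameters."""
    return simulate_study(SimulationParams(), seed=11)


@pytest.fixture(scope="session")
def default_paired(default_study):
    paired = ingest.match_orthologs(
        default_study.expr_a, default_study.expr_b, default_study.orthology, default_study.annotation
    )
    return normalize_paired(paired)


def run_contrast_lists(study, fold=2.0, normalize=True):
    """Helper: paired matrix -> (contrasts, up, down) at a fold threshold."""
    paired = ingest.match_orthologs(study.expr_a, study.expr_b, study.orthology, study.annotation)
    if normalize:
        paired = normalize_paired(paired)
    else:
        paired = paired.with_values(ingest.log2_transform(paired.values))
    contrasts = crisscross.compute_ploidy_contrasts(paired)
    up, down = crisscross.select_concordant_genes(contrasts, fold)
    return contrasts, up, down


# ---------------------------------------------------------------------------
# tiny hand-built fixtures


@pytest.fixture()
def tiny_annotation():
    table = pd.DataFrame(
        {
            "phylostratum": [1, 1, 2, 5, 5, 5, 8, 16],
            "bivalent": [True, False, True, True, False, False, False, True],
            "driver_class": [
                "oncogene",
                "none",
                "none",
                "tumour_suppressor",
                "none",
                "oncogene",
                "none",
                "none",
            ],
        },
        index=pd.Index([f"g{i}" for i in range(8)], name="gene_id"),
    )
    return GeneAnnotation(table)


def make_expression(values: dict, meta_rows: list) -> ExpressionMatrix:
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(values=pd.DataFrame(values), sample_meta=meta)
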