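"""Generators: planted structure, determinism, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from ploidystrat.errors import ValidationError
from ploidystrat.synthetic import (
    DEFAULT_STRATUM_PROBS,
    SimulationParams,
    generate_annotation,
    generate_expression,
    generate_interactions,
    noiseless_params,
    plant_truth,
    simulate_study,
)

ONE_HOT_5 = [0.0] * 4 + [1.0] + [0.0] * 11


class TestGenerateAnnotation:
    def test_one_hot_stratum(self):
        ann = generate_annotation(16, ONE_HOT_5, 0.2, (0.0, 0.0), seed=0)
        assert (ann.table["phylostratum"] == 5).all()

    def test_zero_bivalent_rate(self):
        ann = generate_annotation(200, DEFAULT_STRATUM_PROBS, 0.0, (0.0, 0.0), seed=0)
        assert ann.table["bivalent"].sum() == 0

    def test_bivalent_count_binomial(self):
        # background rate mirroring 3024 bivalent of 14093: the realized count
        # must fall within 3 binomial standard deviations of the expectation
        n, rate = 14093, 3024 / 14093
        ann = generate_annotation(n, DEFAULT_STRATUM_PROBS, rate, (0.0, 0.0), seed=1)
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(ann.table["bivalent"].sum() - 3024) <= 3 * sd

    def test_driver_classes_mutually_exclusive(self):
        ann = generate_annotation(500, DEFAULT_STRATUM_PROBS, 0.2, (0.3, 0.3), seed=2)
        assert set(ann.table["driver_class"]) <= {"oncogene", "tumour_suppressor", "none"}
        # rates roughly respected
        assert (ann.table["driver_class"] == "oncogene").mean() == pytest.approx(0.3, abs=0.08)

    def test_probs_must_sum_to_one(self):
        bad = np.asarray(DEFAULT_STRATUM_PROBS) * 0.9
        with pytest.raises(ValidationError, match="sum"):
            generate_annotation(10, bad, 0.2, (0.0, 0.0), seed=0)

    def test_needs_positive_n(self):
        with pytest.raises(ValidationError):
            generate_annotation(0, DEFAULT_STRATUM_PROBS, 0.2, (0.0, 0.0), seed=0)

    def test_deterministic(self):
        a = generate_annotation(300, DEFAULT_STRATUM_PROBS, 0.25, (0.02, 0.02), seed=9)
        b = generate_annotation(300, DEFAULT_STRATUM_PROBS, 0.25, (0.02, 0.02), seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestPlantTruth:
    def test_disjoint_and_sized(self):
        params = SimulationParams(n_genes=400, n_up=40, n_down=50)
        ann = generate_annotation(400, params.stratum_probs, 0.2, (0.0, 0.0), seed=0)
        truth, ann2 = plant_truth(ann, params, seed=0)
        assert len(truth.planted_up) == 40 and len(truth.planted_down) == 50
        assert not truth.planted_up & truth.planted_down
        assert set(truth.effect_size) == truth.planted_up | truth.planted_down
        for size in truth.effect_size.values():
            assert params.effect_low <= size <= params.effect_high

    def test_bivalent_rate_up_calibrated(self):
        # realized bivalent fraction among planted_up within binomial 3-sigma
        params = SimulationParams(n_genes=14093, bivalent_rate_up=0.457)
        ann = generate_annotation(14093, params.stratum_probs, params.bivalent_rate_background,
                                  (0.0, 0.0), seed=4)
        truth, ann2 = plant_truth(ann, params, seed=4)
        up = sorted(truth.planted_up)
        frac = ann2.table.loc[up, "bivalent"].mean()
        sigma = math.sqrt(0.457 * (1 - 0.457) / len(up))
        assert abs(frac - 0.457) <= 3 * sigma

    def test_sign_probs_shape_lists(self):
        params = SimulationParams(n_genes=5000, n_up=500, n_down=500)
        ann = generate_annotation(5000, params.stratum_probs, 0.2, (0.0, 0.0), seed=5)
        truth, _ = plant_truth(ann, params, seed=5)
        strata = ann.table["phylostratum"]
        old_up = sum(1 for g in truth.planted_up if strata[g] <= 3)
        old_down = sum(1 for g in truth.planted_down if strata[g] <= 3)
        assert old_up > old_down  # old strata favour the up-set


class TestGenerateExpression:
    def _flat_truth(self, ann, **kw):
        params = noiseless_params(n_genes=len(ann), n_up=2, n_down=2,
                                  tissue_effect=0.0, **kw)
        return plant_truth(ann, params, seed=0)

    def test_all_effects_zero_constant_genes(self):
        ann = generate_annotation(20, DEFAULT_STRATUM_PROBS, 0.2, (0.0, 0.0), seed=0)
        params = noiseless_params(n_genes=20, n_up=0, n_down=0, tissue_effect=0.0,
                                  effect_low=0.0, effect_high=0.0)
        truth, ann = plant_truth(ann, params, seed=0)
        ea, eb, _ = generate_expression(truth, ann, n_reps=2)
        # each gene constant across all samples of both species
        assert (ea.values.nunique(axis=1) == 1).all()
        for g in ea.values.index:
            vals = set(ea.values.loc[g]) | set(eb.values.loc[str(g).replace("GA", "GB")])
            assert len(vals) == 1

    def test_planted_delta_appears_in_both_contrasts(self):
        ann = generate_annotation(30, DEFAULT_STRATUM_PROBS, 0.2, (0.0, 0.0), seed=1)
        params = noiseless_params(n_genes=30, n_up=1, n_down=0, tissue_effect=0.0,
                                  effect_low=1.0, effect_high=1.0)
        truth, ann = plant_truth(ann, params, seed=1)
        (g,) = truth.planted_up
        ea, eb, _ = generate_expression(truth, ann, n_reps=1)
        gb = str(g).replace("GA", "GB")
        # heart: A polyploid; liver: B polyploid -- both contrasts exactly +1 in log2
        lfc_heart = np.log2(ea.values.loc[g, "A_heart_r1"] / eb.values.loc[gb, "B_heart_r1"])
        lfc_liver = np.log2(eb.values.loc[gb, "B_liver_r1"] / ea.values.loc[g, "A_liver_r1"])
        assert lfc_heart == pytest.approx(1.0, abs=1e-12)
        assert lfc_liver == pytest.approx(1.0, abs=1e-12)

    def test_crisscross_ploidy_assignment(self):
        study = simulate_study(SimulationParams(n_genes=50, n_up=5, n_down=5, n_reps=2), seed=0)
        meta_a = study.expr_a.sample_meta
        assert (meta_a.loc[meta_a["tissue"] == "heart", "ploidy"] == "polyploid").all()
        assert (meta_a.loc[meta_a["tissue"] == "liver", "ploidy"] == "diploid").all()
        meta_b = study.expr_b.sample_meta
        assert (meta_b.loc[meta_b["tissue"] == "heart", "ploidy"] == "diploid").all()
        assert (meta_b.loc[meta_b["tissue"] == "liver", "ploidy"] == "polyploid").all()

    def test_reproducibility_contract(self):
        params = SimulationParams(n_genes=60, n_up=5, n_down=5, n_reps=2)
        s1 = simulate_study(params, seed=13)
        s2 = simulate_study(params, seed=13)
        s3 = simulate_study(params, seed=14)
        pd.testing.assert_frame_equal(s1.expr_a.values, s2.expr_a.values)
        assert not s1.expr_a.values.equals(s3.expr_a.values)

    def test_linear_scale_nonnegative(self):
        study = simulate_study(SimulationParams(n_genes=50, n_up=5, n_down=5, n_reps=2), seed=2)
        assert (study.expr_a.values >= 0).all().all()

    def test_n_reps_validated(self):
        ann = generate_annotation(10, DEFAULT_STRATUM_PROBS, 0.2, (0.0, 0.0), seed=0)
        truth, ann = self._flat_truth(ann)
        with pytest.raises(ValidationError):
            generate_expression(truth, ann, n_reps=0)


class TestGenerateInteractions:
    @staticmethod
    def _truth(up=(), down=()):
        params = noiseless_params(n_genes=4, n_up=0, n_down=0)
        from ploidystrat.synthetic import SyntheticTruth

        return SyntheticTruth(
            seed=0,
            planted_up=frozenset(up),
            planted_down=frozenset(down),
            effect_size={g: 1.5 for g in (*up, *down)},
            stratum_sign_probs={s: 0.5 for s in range(1, 17)},
            bivalent_rate_background=0.2,
            bivalent_rate_up=0.4,
            noise_sd=params.noise_sd,
            batch_sd=0.0,
            tissue_effect=0.0,
            species_effect=0.0,
        )

    def test_zero_mean_degree_empty(self):
        genes = [f"g{i}" for i in range(10)]
        graph = generate_interactions(genes, 0.0, 1.0, self._truth(), seed=0)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 10

    def test_simple_graph(self):
        genes = [f"g{i}" for i in range(60)]
        graph = generate_interactions(genes, 5.0, 2.0, self._truth(up=genes[:10]), seed=1)
        assert all(a != b for a, b in graph.edges())
        seen = {frozenset(e) for e in graph.edges()}
        assert len(seen) == graph.number_of_edges()

    def test_mean_degree_calibration(self):
        # Erdos-Renyi oracle: mean degree within 3 standard errors of target
        n, target = 500, 6.0
        genes = [f"g{i}" for i in range(n)]
        graph = generate_interactions(genes, target, 1.0, self._truth(), seed=3)
        total_pairs = n * (n - 1) // 2
        p = target / (n - 1)
        se = 2.0 * math.sqrt(total_pairs * p * (1 - p)) / n
        realized = 2.0 * graph.number_of_edges() / n
        assert abs(realized - target) <= 3 * se

    def test_boost_increases_up_degree(self):
        genes = [f"g{i}" for i in range(400)]
        up = genes[:100]
        graph = generate_interactions(genes, 6.0, 2.0, self._truth(up=up), seed=4)
        deg = dict(graph.degree())
        up_mean = np.mean([deg[g] for g in up])
        other_mean = np.mean([deg[g] for g in genes[100:]])
        assert up_mean > other_mean * 1.3

    def test_infeasible_mean_degree(self):
        genes = [f"g{i}" for i in range(10)]
        with pytest.raises(ValidationError):
            generate_interactions(genes, 9.5, 1.0, self._truth(), seed=0)

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(50)]
        g1 = generate_interactions(genes, 4.0, 1.5, self._truth(up=genes[:5]), seed=5)
        g2 = generate_interactions(genes, 4.0, 1.5, self._truth(up=genes[:5]), seed=5)
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))
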