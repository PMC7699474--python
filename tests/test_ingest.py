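"""Reading, validation, ortholog matching, quantile normalization."""

import numpy as np
import pandas as pd
import pytest

from ploidystrat import ingest
from ploidystrat.datatypes import ExpressionMatrix, GeneAnnotation, OrthologyMap
from ploidystrat.errors import ValidationError

META_4 = [
    {"sample_id": "A_heart_r1", "species": "A", "tissue": "heart", "ploidy": "polyploid",
     "batch": "b1", "replicate": 1},
    {"sample_id": "A_heart_r2", "species": "A", "tissue": "heart", "ploidy": "polyploid",
     "batch": "b1", "replicate": 2},
    {"sample_id": "A_liver_r1", "species": "A", "tissue": "liver", "ploidy": "diploid",
     "batch": "b2", "replicate": 1},
    {"sample_id": "A_liver_r2", "species": "A", "tissue": "liver", "ploidy": "diploid",
     "batch": "b2", "replicate": 2},
]


def write_fixture(tmp_path, table_text, meta_rows=META_4):
    table = tmp_path / "expr.tsv"
    table.write_text(table_text)
    meta = tmp_path / "meta.tsv"
    pd.DataFrame(meta_rows).to_csv(meta, sep="\t", index=False)
    return table, meta


WELL_FORMED = (
    "gene_id\tA_heart_r1\tA_heart_r2\tA_liver_r1\tA_liver_r2\n"
    "g1\t1\t2\t3\t4\n"
    "g2\t5\t6\t7\t8\n"
    "g3\t9\t10\t11\t12\n"
)


class TestReadExpression:
    def test_well_formed(self, tmp_path):
        table, meta = write_fixture(tmp_path, WELL_FORMED)
        matrix = ingest.read_expression(table, meta)
        assert len(matrix.genes) == 3
        assert list(matrix.samples) == [r["sample_id"] for r in META_4]

    def test_metadata_missing_sample_named(self, tmp_path):
        table, meta = write_fixture(tmp_path, WELL_FORMED, META_4[:3])
        with pytest.raises(ValidationError, match="A_liver_r2"):
            ingest.read_expression(table, meta)

    def test_na_row_dropped_with_warning(self, tmp_path, caplog):
        text = WELL_FORMED.replace("g2\t5\t6\t7\t8", "g2\t5\t\t7\t8")
        table, meta = write_fixture(tmp_path, text)
        with caplog.at_level("WARNING", logger="ploidystrat.ingest"):
            matrix = ingest.read_expression(table, meta)
        assert len(matrix.genes) == 2
        assert "g2" not in matrix.genes
        assert any("dropping 1 genes" in rec.getMessage() for rec in caplog.records)

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        text = WELL_FORMED.replace("g3", "g1")
        table, meta = write_fixture(tmp_path, text)
        with pytest.raises(ValidationError, match="duplicate"):
            ingest.read_expression(table, meta)

    def test_negative_values_rejected(self, tmp_path):
        text = WELL_FORMED.replace("g2\t5", "g2\t-5")
        table, meta = write_fixture(tmp_path, text)
        with pytest.raises(ValidationError, match="nonnegative"):
            ingest.read_expression(table, meta)

    def test_inconsistent_ploidy_rejected(self, tmp_path):
        bad_meta = [dict(r) for r in META_4]
        bad_meta[1]["ploidy"] = "diploid"  # same (species, tissue) cell as row 0
        table, meta = write_fixture(tmp_path, WELL_FORMED, bad_meta)
        with pytest.raises(ValidationError, match="ploidy"):
            ingest.read_expression(table, meta)


def _matrix(genes, samples, meta_rows, seed=0):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.random((len(genes), len(samples))) + 1.0, index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta)


def _meta(sample, species, tissue, ploidy):
    return {"sample_id": sample, "species": species, "tissue": tissue, "ploidy": ploidy,
            "batch": f"{species}_{tissue}", "replicate": 1}


def _annotation(genes, strata=None):
    strata = strata if strata is not None else [1] * len(genes)
    return GeneAnnotation(
        pd.DataFrame(
            {"phylostratum": strata, "bivalent": False, "driver_class": "none"},
            index=pd.Index(genes, name="gene_id"),
        )
    )


class TestMatchOrthologs:
    def setup_method(self):
        self.expr_a = _matrix(
            ["a1", "a2", "a3"],
            ["A_heart_r1", "A_liver_r1"],
            [_meta("A_heart_r1", "A", "heart", "polyploid"),
             _meta("A_liver_r1", "A", "liver", "diploid")],
        )
        self.expr_b = _matrix(
            ["b1"],
            ["B_heart_r1", "B_liver_r1"],
            [_meta("B_heart_r1", "B", "heart", "diploid"),
             _meta("B_liver_r1", "B", "liver", "polyploid")],
        )

    def test_single_shared_pair(self):
        orthology = OrthologyMap(pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]}))
        paired = ingest.match_orthologs(self.expr_a, self.expr_b, orthology, _annotation(["a1", "a2"]))
        assert list(paired.genes) == ["a1"]
        assert paired.values.shape == (1, 4)

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            ingest.match_orthologs(self.expr_a, self.expr_b, OrthologyMap(), _annotation(["a1"]))

    def test_unannotated_pairs_dropped(self):
        genes_a = [f"a{i}" for i in range(100)]
        genes_b = [f"b{i}" for i in range(100)]
        expr_a = _matrix(genes_a, self.expr_a.values.columns, self.expr_a.sample_meta.reset_index().to_dict("records"))
        expr_b = _matrix(genes_b, self.expr_b.values.columns, self.expr_b.sample_meta.reset_index().to_dict("records"))
        orthology = OrthologyMap(pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b}))
        annotation = _annotation(genes_a[:90])  # 10 pairs lack a stratum
        paired = ingest.match_orthologs(expr_a, expr_b, orthology, annotation)
        assert len(paired.genes) == 90

    def test_symmetry_of_row_set(self):
        orthology = OrthologyMap(pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]}))
        annotation = _annotation(["a1", "a2", "b1", "b2"])
        forward = ingest.match_orthologs(self.expr_a, self.expr_b, orthology, annotation)
        backward = ingest.match_orthologs(self.expr_b, self.expr_a, orthology.reversed(), annotation)
        assert forward.pairs() == backward.pairs()

    def test_orthology_must_be_one_to_one(self):
        with pytest.raises(ValidationError, match="one-to-one"):
            OrthologyMap(pd.DataFrame({"gene_a": ["a1", "a1"], "gene_b": ["b1", "b2"]}))


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        values = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = ingest.quantile_normalize(values, {"s1": "g", "s2": "g"})
        assert list(out["s1"]) == [2.5, 3.5, 4.5]
        assert list(out["s2"]) == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        values = pd.DataFrame({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]})
        out = ingest.quantile_normalize(values, {"s1": "g", "s2": "g"})
        pd.testing.assert_frame_equal(out, values)

    def test_sorted_columns_identical(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.random((50, 6)), columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": "heart" if i < 3 else "liver" for i in range(6)}
        out = ingest.quantile_normalize(values, groups)
        for group_cols in (["s0", "s1", "s2"], ["s3", "s4", "s5"]):
            sorted_cols = np.sort(out[group_cols].to_numpy(), axis=0)
            assert np.abs(sorted_cols - sorted_cols[:, [0]]).max() < 1e-12

    def test_rank_preserved_within_column(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.random((30, 3)), columns=["s0", "s1", "s2"])
        out = ingest.quantile_normalize(values, {c: "g" for c in values.columns})
        for c in values.columns:
            assert (np.argsort(values[c].to_numpy()) == np.argsort(out[c].to_numpy())).all()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.random((40, 4)), columns=list("abcd"))
        groups = {c: "g" for c in values.columns}
        once = ingest.quantile_normalize(values, groups)
        twice = ingest.quantile_normalize(once, groups)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12

    def test_ties_get_mean_reference(self):
        values = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]})
        out = ingest.quantile_normalize(values, {"s1": "g", "s2": "g"})
        # tied values in s1 share the mean of the two lowest reference values
        assert out.loc[0, "s1"] == out.loc[1, "s1"]
        ref = np.sort(values.to_numpy(), axis=0).mean(axis=1)
        assert out.loc[0, "s1"] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_single_sample_group_rejected(self):
        values = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]})
        with pytest.raises(ValidationError, match="fewer than 2"):
            ingest.quantile_normalize(values, {"s1": "g1", "s2": "g2"})
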