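"""End-to-end orchestration of all analysis stages.

``run_all`` sequences: data acquisition (simulation or ingest) -> ortholog
matching -> log2 + quantile normalization -> reciprocal contrasts at each
fold threshold -> PCA with factor assignment -> stratum-shift tests ->
bivalency statistics and driver panel -> module enrichment -> network
summaries. Every stage writes plain tab-separated outputs and contributes a
block to a single deterministic JSON summary.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import networkx
import numpy as np
import pandas as pd
import scipy

from . import __version__, bivalency, crisscross, ingest, network, pca, strata, synthetic
from .config import RunConfig
from .errors import StageError, ValidationError
from .ontology import Ontology, hypergeometric_enrichment, propagate_ontology

log = logging.getLogger(__name__)

PAIRED_TSV = "paired_log2_qnorm.tsv"
PAIRED_META_TSV = "paired_samples.tsv"
ANNOTATION_TSV = "annotation.tsv"
SUMMARY_JSON = "summary.json"


def _write_table(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ploidystrat {__version__} | {provenance}\n")
        df.to_csv(fh, sep="\t")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ValidationError:
                raise
            except StageError:
                raise
            except Exception as err:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, str(err)) from err

        return inner

    return wrap


def acquire_data(config: RunConfig):
    """Simulate a study or ingest the configured input files."""
    if config.simulate is not None:
        study = synthetic.simulate_study(config.simulate, config.seed)
        return study.expr_a, study.expr_b, study.orthology, study.annotation, study
    paths = config.inputs
    expr_a = ingest.read_expression(paths.expression_a, paths.meta_a)
    expr_b = ingest.read_expression(paths.expression_b, paths.meta_b)
    orthology = ingest.read_orthology(paths.orthology)
    annotation = ingest.read_annotation(paths.annotation)
    return expr_a, expr_b, orthology, annotation, None


def normalize_paired(paired, pseudocount: float = 1.0):
    """log2(x + pseudocount) then per-tissue-pair quantile normalization."""
    logged = ingest.log2_transform(paired.values, pseudocount)
    groups = paired.sample_meta["tissue"]
    return paired.with_values(ingest.quantile_normalize(logged, groups))


def _load_ontology(config: RunConfig, study, genes) -> Ontology | None:
    if study is not None:
        return synthetic.generate_ontology(list(genes), seed=config.seed)
    paths = config.inputs
    if paths.ontology_edges is None or paths.gene2term is None:
        return None
    edges = pd.read_csv(paths.ontology_edges, sep="\t", comment="#")
    gene2term = pd.read_csv(paths.gene2term, sep="\t", comment="#")
    labels = None
    if paths.term_labels is not None:
        labels = pd.read_csv(paths.term_labels, sep="\t", comment="#")
    return Ontology.from_tables(edges, gene2term, labels)


def _load_network(config: RunConfig, study, up: list, down: list):
    if study is not None:
        nodes = sorted(set(up) | set(down))
        if len(nodes) < 2:
            return None
        return synthetic.generate_interactions(
            nodes, mean_degree=6.0, up_connectivity_boost=1.5, truth=study.truth, seed=config.seed
        )
    if config.inputs.network is None:
        return None
    return network.read_edge_list(config.inputs.network)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written to outdir).

    Deterministic given the seed: rerunning the same config produces a
    byte-identical ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _configure_run_log(outdir, config)
    summary: dict = {"seed": config.seed, "fold_thresholds": list(config.fold_thresholds)}

    expr_a, expr_b, orthology, annotation, study = _stage("acquire")(acquire_data)(config)
    summary["data"] = {
        "mode": "simulate" if study is not None else "ingest",
        "n_genes_a": int(len(expr_a.genes)),
        "n_genes_b": int(len(expr_b.genes)),
        "n_ortholog_pairs": int(len(orthology)),
        "n_annotated": int(len(annotation)),
    }
    annotation.write(outdir / ANNOTATION_TSV)

    @_stage("normalize")
    def _normalize():
        paired = ingest.match_orthologs(expr_a, expr_b, orthology, annotation)
        return normalize_paired(paired, config.log2_pseudocount)

    paired = _normalize()
    paired.write(outdir / PAIRED_TSV, outdir / PAIRED_META_TSV)
    background = list(paired.genes)

    @_stage("crisscross")
    def _crisscross():
        contrasts = crisscross.compute_ploidy_contrasts(paired)
        block = {}
        lists = {}
        for fold in config.fold_thresholds:
            up, down = crisscross.select_concordant_genes(contrasts, fold)
            lists[fold] = (up, down)
            key = f"fold_{fold:g}"
            block[key] = {"n_up": len(up), "n_down": len(down)}
            table = contrasts.assign(call=crisscross.classify_calls(contrasts, fold))
            _write_table(table, outdir / f"contrasts_{key}.tsv", f"criss-cross contrasts, fold {fold:g}")
            pd.Series(up, name="gene_id").to_csv(outdir / f"up_{key}.tsv", sep="\t", index=False)
            pd.Series(down, name="gene_id").to_csv(outdir / f"down_{key}.tsv", sep="\t", index=False)
        return contrasts, lists, block

    contrasts, lists, summary["crisscross"] = _crisscross()
    primary_fold = config.fold_thresholds[0]
    up_list, down_list = lists[primary_fold]

    @_stage("pca")
    def _pca():
        components = pca.run_pca(paired.values)
        components = pca.assign_components(components, paired.sample_meta)
        block = {
            "variance_explained": {
                c: round(float(v), 6) for c, v in components.variance_explained.head(6).items()
            },
            "assignment": {k: v for k, v in sorted(components.assignment.items())},
        }
        if components.correlations is not None:
            block["correlations"] = {
                factor: {c: round(float(components.correlations.loc[factor, c]), 4)
                         for c in components.correlations.columns[:6]}
                for factor in components.correlations.index
            }
        try:
            pca_up, pca_down = pca.select_component_genes(components, config.pca_sd)
            block["n_up"] = len(pca_up)
            block["n_down"] = len(pca_down)
        except ValidationError as err:
            pca_up, pca_down = [], []
            block["note"] = str(err)
        _write_table(components.scores, outdir / "pca_scores.tsv", "standardized gene scores")
        _write_table(components.loadings, outdir / "pca_loadings.tsv", "component loadings")
        return components, pca_up, pca_down, block

    components, pca_up, pca_down, summary["pca"] = _pca()

    @_stage("strata")
    def _strata():
        shift = strata.stratum_shift_test(up_list, down_list, annotation)
        _write_table(shift, outdir / "stratum_shift.tsv", f"stratum shift at fold {primary_fold:g}")
        agg = strata.aggregate_shift(shift)
        return shift, {**{k: round(v, 4) for k, v in agg.items()}}

    shift, summary["strata"] = _strata()

    @_stage("bivalency")
    def _bivalency():
        block = {}
        for name, genes in (("up", up_list), ("down", down_list)):
            if genes:
                result = bivalency.bivalent_enrichment_test(genes, annotation, background)
                block[name] = result.as_dict()
            else:
                block[name] = None
        profile = bivalency.bivalent_by_stratum(up_list, down_list, annotation)
        _write_table(profile, outdir / "bivalency_by_stratum.tsv", "bivalent fractions per stratum")
        panel, comparisons = bivalency.driver_panel(up_list, down_list, annotation, contrasts)
        _write_table(panel.set_index("gene"), outdir / "driver_panel.tsv", "driver gene panel")
        block["drivers"] = {
            "n_panel": int(len(panel)),
            "comparisons": [c.as_dict() for c in comparisons],
        }
        return block

    summary["bivalency"] = _bivalency()

    @_stage("modules")
    def _modules():
        ontology = _load_ontology(config, study, background)
        if ontology is None or not up_list:
            return {"note": "no ontology configured" if ontology is None else "empty up list"}
        closed = propagate_ontology(ontology)
        block = {}
        for name, genes in (("up", up_list), ("down", down_list)):
            if not genes:
                block[name] = None
                continue
            table = hypergeometric_enrichment(genes, background, closed, ontology.labels)
            _write_table(
                table.set_index("term"), outdir / f"modules_{name}.tsv", f"module enrichment, {name} list"
            )
            block[name] = {
                "n_terms_tested": int(len(table)),
                "n_significant_q05": int((table["q"] < 0.05).sum()),
            }
        return block

    summary["modules"] = _modules()

    @_stage("network")
    def _network():
        graph = _load_network(config, study, up_list, down_list)
        if graph is None:
            return {"note": "no network configured"}
        network.write_edge_list(graph, outdir / "network_edges.tsv")
        comp = network.largest_component_summary(graph, hub_threshold=config.hub_degree)
        block = {"largest_component": comp.as_dict()}
        block["largest_component"]["hubs"] = block["largest_component"]["hubs"][:20]
        for name, genes in (("up", up_list), ("down", down_list)):
            if not genes:
                block[f"retention_{name}"] = None
                continue
            retention = network.component_retention(genes, graph)
            induced = graph.subgraph(set(genes) & set(graph.nodes))
            mean_deg = (
                2.0 * induced.number_of_edges() / induced.number_of_nodes()
                if induced.number_of_nodes()
                else 0.0
            )
            block[f"retention_{name}"] = retention.as_dict()
            block[f"mean_degree_{name}"] = round(mean_deg, 4)
        _write_table(network.degree_table(graph).set_index("gene"), outdir / "degree_table.tsv", "node degrees")
        return block

    summary["network"] = _network()

    with open(outdir / SUMMARY_JSON, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    log.info("run complete; summary written to %s", outdir / SUMMARY_JSON)
    return summary


def _configure_run_log(outdir: Path, config: RunConfig) -> None:
    """Append versions and parameters to the run log (kept out of the summary
    so reruns stay byte-identical)."""
    with open(outdir / "run.log", "a") as fh:
        fh.write(
            "ploidystrat %s | python %s | numpy %s scipy %s pandas %s networkx %s | seed=%s folds=%s\n"
            % (
                __version__,
                platform.python_version(),
                np.__version__,
                scipy.__version__,
                pd.__version__,
                networkx.__version__,
                config.seed,
                list(config.fold_thresholds),
            )
        )
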