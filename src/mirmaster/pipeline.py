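"""End-to-end orchestration of the master-regulator discovery pipeline.

Stage order: differential expression -> (optional) subtype classifier ->
network inference -> master-regulator analysis -> preranked GSEA ->
survival analysis -> target prioritization. One root seed drives every
stochastic stage through fixed offsets, so the whole run and each stage in
isolation are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import diffexp, gsea, mra, network, survival, targets
from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneSetCollection,
    TargetPredictionTable,
    ValidationError,
    write_json,
    write_results_table,
    znormalize,
)

logger = logging.getLogger("mirmaster")

# per-stage seed offsets from the root seed (recorded in the report)
STAGE_SEEDS = {"classifier_cv": 10, "network": 20, "gsea": 30}


@dataclass
class PipelineReport:
    config: dict
    seed: int
    stage_seeds: dict
    gene_de: pd.DataFrame
    mirna_de: pd.DataFrame
    classifier_genes: list[str] | None
    classifier_model: "clf.ShrunkenCentroidModel | None"
    posteriors: pd.DataFrame | None
    network: "network.RegulatoryNetwork"
    mra_table: pd.DataFrame
    gsea_table: pd.DataFrame
    survival_results: dict
    target_table: pd.DataFrame
    prioritized_targets: list[str]
    top_master_regulator: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def run_full_pipeline(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    samples: pd.DataFrame,
    signature,
    predictions: list[TargetPredictionTable] | None = None,
    config: AnalysisConfig | None = None,
    extra_gene_sets: GeneSetCollection | None = None,
    run_classifier: bool = True,
    outdir=None,
) -> PipelineReport:
    """Run every stage on a paired cohort and return the collected report.

    ``samples`` must be indexed by sample id and carry a ``subtype`` column
    (labels may instead be produced upstream by ``classifier.predict_nsc``);
    survival columns (time/event and age/stage/grade covariates) are used
    when present.
    """
    cfg = config or AnalysisConfig()
    seed = cfg.rng_seed
    stage_seeds = {k: seed + off for k, off in STAGE_SEEDS.items()}

    mismatch = set(gene_expr.sample_ids) ^ set(mirna_expr.sample_ids)
    if mismatch:
        raise ValidationError(
            f"gene and miRNA matrices disagree on samples: {sorted(mismatch)[:10]}"
        )
    mirna_expr = mirna_expr.subset_samples(gene_expr.sample_ids)
    missing = [s for s in gene_expr.sample_ids if s not in samples.index]
    if missing:
        raise ValidationError(f"samples missing annotations: {missing[:10]}")
    samples = samples.loc[gene_expr.sample_ids]
    if "subtype" not in samples.columns or samples["subtype"].isna().any():
        raise ValidationError(
            "subtype labels are required (provide them or classify upstream "
            "with a trained model and posterior > %.2f)" % cfg.posterior_threshold
        )
    mes_mask = (samples["subtype"] == "mesenchymal").to_numpy()
    signature = set(signature)

    _stage("differential expression")
    gene_de = diffexp.differential_expression_table(gene_expr, mes_mask, "welch_t")
    mirna_de = diffexp.differential_expression_table(mirna_expr, mes_mask, "welch_t")

    classifier_genes = None
    model = None
    posteriors = None
    if run_classifier:
        _stage("subtype classifier")
        gene_z = znormalize(gene_expr)
        classifier_genes = clf.two_step_feature_selection(gene_z, mes_mask, cfg)
        labels = np.where(mes_mask, "mesenchymal", "rest")
        model = clf.train_nsc(gene_z.subset_features(classifier_genes), labels,
                              seed=stage_seeds["classifier_cv"])
        posteriors = clf.predict_nsc(model, gene_z, cfg.posterior_threshold)

    _stage("network inference")
    net_cfg = dataclasses.replace(cfg, rng_seed=stage_seeds["network"])
    net = network.infer_network(gene_expr, mirna_expr, mes_mask, net_cfg)
    regulons = {r: set(t) for r, t in net.regulons().items()}
    if not regulons:
        raise ValidationError(
            "network stage produced no regulons; relax thresholds "
            "(bootstrap_consensus, target_fdr) or check the input cohort"
        )

    _stage("master regulator analysis")
    mra_table = mra.rank_master_regulators(
        mra.mra_enrichment(regulons, signature, universe=net.targets)
    )
    top = mra_table.iloc[0]
    top_mr = {"regulator_id": top["regulator_id"], "adj_p": float(top["adj_p"]),
              "proportion": float(top["proportion"])}

    _stage("preranked GSEA")
    ranked = gsea.RankedList.from_scores(gene_de.set_index("feature_id")["log2fc"])
    sets = {"SIGNATURE": ("phenotype signature", frozenset(signature))}
    if extra_gene_sets is not None:
        sets.update(extra_gene_sets.sets)
    gsea_table = gsea.gsea_run(
        ranked, GeneSetCollection(sets), n_permutations=cfg.n_permutations,
        seed=stage_seeds["gsea"],
        min_size=min(5, len(signature)),
    )

    _stage("survival analysis")
    surv_results: dict = {}
    if {"time", "event"}.issubset(samples.columns) and samples["event"].notna().all():
        time = samples["time"].to_numpy(dtype=float)
        event = samples["event"].to_numpy(dtype=int)
        group = np.where(mes_mask, "mesenchymal", "rest")
        lr = survival.logrank_test(time, event, group)
        surv_results["logrank_subtype"] = {
            "chi_square": lr.chi_square, "p": lr.p,
            "observed": lr.observed, "expected": lr.expected,
        }
        surv_results["km_mesenchymal"] = survival.km_estimate(time[mes_mask], event[mes_mask])
        surv_results["km_rest"] = survival.km_estimate(time[~mes_mask], event[~mes_mask])
        cov = pd.DataFrame({"mesenchymal": mes_mask.astype(float)},
                           index=samples.index)
        uni = survival.cox_fit(time, event, cov)
        surv_results["cox_univariate"] = uni.summary()
        extra = [c for c in ("age", "stage", "grade")
                 if c in samples.columns and samples[c].notna().all()]
        if extra:
            multi = survival.cox_fit(
                time, event, pd.concat([cov, samples[extra].astype(float)], axis=1))
            surv_results["cox_multivariate"] = multi.summary()
        # stratification by the top regulator's mean expression
        mr_id = top_mr["regulator_id"]
        strata = survival.stratify_by_mean(
            mirna_expr.data.loc[mr_id].to_numpy(), samples.index)
        lr_mr = survival.logrank_test(time, event, strata.to_numpy())
        surv_results["logrank_top_regulator_stratified"] = {
            "regulator_id": mr_id, "chi_square": lr_mr.chi_square, "p": lr_mr.p,
        }
    else:
        logger.info("no usable survival columns; survival stage skipped")

    _stage("target prioritization")
    prioritized: list[str] = []
    target_table = pd.DataFrame()
    if predictions:
        prioritized, target_table = targets.intersect_target_evidence(
            regulons.get(top_mr["regulator_id"], set()), signature, predictions,
            top_mr["regulator_id"], gene_expr=gene_expr, mirna_expr=mirna_expr,
        )
    else:
        logger.info("no prediction sources supplied; prioritization limited to "
                    "regulon-signature overlap")
        reg = regulons.get(top_mr["regulator_id"], set())
        prioritized = sorted(reg & signature)

    report = PipelineReport(
        config=dataclasses.asdict(cfg),
        seed=seed,
        stage_seeds=stage_seeds,
        gene_de=gene_de,
        mirna_de=mirna_de,
        classifier_genes=classifier_genes,
        classifier_model=model,
        posteriors=posteriors,
        network=net,
        mra_table=mra_table,
        gsea_table=gsea_table,
        survival_results=surv_results,
        target_table=target_table,
        prioritized_targets=prioritized,
        top_master_regulator=top_mr,
    )
    if outdir is not None:
        _write_bundle(report, Path(outdir))
    return report


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bundle(report: PipelineReport, outdir: Path) -> None:
    """Serialize every stage output plus a JSON report with file hashes."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_results_table(report.gene_de, outdir / "gene_de.tsv", sort_by="feature_id")
    write_results_table(report.mirna_de, outdir / "mirna_de.tsv", sort_by="feature_id")
    write_results_table(report.network.edges, outdir / "network_edges.tsv")
    write_results_table(report.mra_table, outdir / "mra.tsv")
    gsea_out = report.gsea_table.copy()
    gsea_out["leading_edge"] = gsea_out["leading_edge"].map(",".join)
    write_results_table(gsea_out, outdir / "gsea.tsv")
    if report.posteriors is not None:
        write_results_table(report.posteriors.reset_index(),
                            outdir / "posteriors.tsv", sort_by="sample_id")
    if report.classifier_model is not None:
        report.classifier_model.to_json(outdir / "classifier_model.json")
    if len(report.target_table):
        write_results_table(report.target_table, outdir / "target_evidence.tsv",
                            sort_by="gene_id")
    surv_json = {}
    for key, val in report.survival_results.items():
        if isinstance(val, survival.KMCurve):
            surv_json[key] = {
                "event_times": val.event_times.tolist(),
                "survival": val.survival.tolist(),
                "at_risk": val.at_risk.tolist(),
            }
        elif isinstance(val, pd.DataFrame):
            surv_json[key] = val.to_dict(orient="records")
        else:
            surv_json[key] = val
    write_json(surv_json, outdir / "survival.json")

    for f in sorted(outdir.iterdir()):
        if f.name != "report.json":
            report.output_hashes[f.name] = _hash_file(f)
    write_json(
        {
            "config": report.config,
            "seed": report.seed,
            "stage_seeds": report.stage_seeds,
            "classifier_genes": report.classifier_genes,
            "top_master_regulator": report.top_master_regulator,
            "prioritized_targets": report.prioritized_targets,
            "n_kept_edges": int(len(report.network.kept_edges)),
            "output_hashes": report.output_hashes,
        },
        outdir / "report.json",
    )
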