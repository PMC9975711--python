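"""End-to-end orchestration: discovery (subtype -> score -> fibrosis ->
LAFSAA -> panel) and validation (centroid assignment -> panel ROC).

Each stage derives its own RNG seed from the global seed and the stage
name, so stages are individually reproducible; all artifacts are written
as TSV/JSON.  A stage failure aborts with a stage-named error and leaves
a ``FAILED`` marker next to the partial outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import fibrosis as fib
from . import io as isio
from . import lafsaa as laf
from . import panel as pnl
from . import scoring, subtyping
from .data_model import (
    ExpressionMatrix,
    FractionMatrix,
    LafsaaResult,
    PanelModel,
    RocCurve,
    ScoreMatrix,
    SubtypeModel,
)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    expr: str
    fractions: str
    meta: str
    gmt: str
    secretory: str
    outdir: str = "results"
    val_expr: Optional[str] = None
    val_fractions: Optional[str] = None
    val_meta: Optional[str] = None
    tgs_name: str = "HALLMARK_EMT"
    alpha: float = 0.05
    k: Union[int, str] = "auto"
    k_max: int = 6
    seed: int = 0
    panel_padj_max: float = 0.05
    auc_drop_tol: float = 0.01
    top_frac: float = 0.3
    tune_frac: float = 0.3
    lasso_folds: int = 10

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require_validation: bool = False) -> None:
        needed = {"expr": self.expr, "fractions": self.fractions, "meta": self.meta,
                  "gmt": self.gmt, "secretory": self.secretory}
        if require_validation:
            needed.update({"val_expr": self.val_expr, "val_fractions": self.val_fractions})
        for name, p in needed.items():
            if p is None:
                raise ValueError(f"config is missing the {name} path")
            if not Path(p).exists():
                raise ValueError(f"config path for {name} does not exist: {p}")


@dataclass
class ResultsBundle:
    subtype_model: SubtypeModel
    silhouette_by_k: Dict[int, float]
    scores: ScoreMatrix
    fibrosis_scores: pd.Series
    fibrosis_levels: pd.Series
    partition: fib.PartitionReport
    lafsaa: LafsaaResult
    panel: PanelModel
    roc_discovery: RocCurve
    seed: int
    labels_validation: Optional[pd.Series] = None
    panel_scores_validation: Optional[pd.Series] = None
    roc_validation: Optional[RocCurve] = None
    log: List[dict] = field(default_factory=list)


class StageError(RuntimeError):
    pass


class _Runner:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.log: List[dict] = []

    def run(self, name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            (self.outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        self.log.append({"stage": name, "status": "ok"})
        return result


def _model_to_json(model: SubtypeModel) -> dict:
    return {
        "k": model.k,
        "cell_types": model.cell_types,
        "centroids": model.centroids.to_numpy().tolist(),
        "seed": model.seed,
        "silhouette_by_k": {str(k): v for k, v in model.silhouette_by_k.items()},
    }


def model_from_json(obj: dict) -> SubtypeModel:
    """Rebuild a centroid model from its JSON form (training labels are not
    serialized; a placeholder label vector stands in)."""
    centroids = pd.DataFrame(obj["centroids"], index=range(1, obj["k"] + 1),
                             columns=obj["cell_types"])
    placeholder = pd.Series(range(1, obj["k"] + 1))
    return SubtypeModel(k=obj["k"], centroids=centroids, labels=placeholder,
                        seed=obj.get("seed", 0))


def _lafsaa_to_json(res: LafsaaResult) -> dict:
    return {
        "records": [
            {"set": r.set_name, "subtype": r.subtype, "rho_in": r.rho_in,
             "p_in": r.p_in, "rho_out": r.rho_out, "p_out": r.p_out,
             "validated": r.validated, "enrichment_p": r.enrichment_p}
            for r in res.records
        ],
        "clusters": res.clusters,
        "ics": res.ics,
        "representatives": res.representatives,
        "fibrosis_specific": res.fibrosis_specific,
    }


def _stratified_split(labels: pd.Series, tune_frac: float, seed: int):
    rng = np.random.default_rng(seed)
    train_ids, tune_ids = [], []
    for val in sorted(labels.unique()):
        ids = np.array(labels.index[labels == val])
        rng.shuffle(ids)
        n_tune = max(1, int(round(tune_frac * len(ids))))
        tune_ids.extend(ids[:n_tune])
        train_ids.extend(ids[n_tune:])
    return sorted(train_ids), sorted(tune_ids)


def run_discovery(config: PipelineConfig) -> ResultsBundle:
    """Execute the discovery arm of the pipeline and write all artifacts."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _Runner(outdir)

    def load():
        expr = isio.read_matrix_tsv(config.expr, "expression")
        fractions = isio.read_matrix_tsv(config.fractions, "fractions")
        meta = isio.read_meta_tsv(config.meta)
        collection = isio.read_gmt(config.gmt)
        secretory = isio.read_gene_list(config.secretory)
        if config.tgs_name not in collection:
            raise ValueError(f"TGS {config.tgs_name!r} not in the gene-set collection")
        return expr, fractions, meta, collection, secretory

    expr, fractions, meta, collection, secretory = runner.run("load_inputs", load)
    failing = [m.sample_id for m in meta if m.status == "failing"]
    expr_f = expr.subset_samples([s for s in expr.sample_ids if s in set(failing)])
    frac_f = fractions.subset_samples([s for s in fractions.sample_ids if s in set(failing)])

    def do_subtype():
        seed = stage_seed(config.seed, "subtype")
        if config.k == "auto":
            k_best, sil = subtyping.select_k_silhouette(
                frac_f, range(2, config.k_max + 1), seed=seed)
        else:
            k_best, sil = int(config.k), {}
        model = subtyping.cluster_kmeans(frac_f, k_best, seed=seed)
        model.silhouette_by_k = sil
        return model

    model = runner.run("subtype", do_subtype)
    labels = model.labels

    scores = runner.run("score_collection", lambda: scoring.score_collection(expr_f, collection))
    tgs = scores.data[config.tgs_name].rename(config.tgs_name)

    def do_fibrosis():
        fs = fib.fibrosis_score(expr_f)
        levels = fib.median_split(fs)
        report = fib.group_partition_report(labels.loc[fs.index], levels)
        return fs, levels, report

    fscores, flevels, partition = runner.run("fibrosis", do_fibrosis)

    def do_de():
        out: Dict[int, List[str]] = {}
        for sub in range(1, model.k + 1):
            ids = list(labels.index[labels == sub])
            hi = [s for s in ids if flevels[s] == "high"]
            lo = [s for s in ids if flevels[s] == "low"]
            if len(hi) < 2 or len(lo) < 2:
                out[sub] = []
                continue
            de = fib.differential_expression(expr_f, hi, lo)
            out[sub] = list(de.index[(de["padj"] < config.alpha) & (de["log2fc"] > 0)])
        return out

    de_genes = runner.run("differential_expression", do_de)

    def do_lafsaa():
        records_fib = laf.screen_subtype_specific(scores, fscores.rename("fibrosis"),
                                                  labels, alpha=config.alpha)
        return laf.run_lafsaa(
            scores, tgs, labels, alpha=config.alpha,
            de_genes_by_subtype=de_genes, collection=collection,
            universe=expr_f.gene_ids, top_frac=config.top_frac,
            records_fibrosis=records_fib,
        )

    lafsaa_res = runner.run("lafsaa", do_lafsaa)

    def do_panel():
        seed = stage_seed(config.seed, "panel")
        train_ids, tune_ids = _stratified_split(labels, config.tune_frac, seed)
        panel = pnl.build_panel(
            expr_f.subset_samples(train_ids), labels.loc[train_ids], secretory,
            seed=seed, padj_max=config.panel_padj_max, n_folds=config.lasso_folds,
            expr_tune=expr_f.subset_samples(tune_ids), labels_tune=labels.loc[tune_ids],
            auc_drop_tol=config.auc_drop_tol,
        )
        ps = pnl.panel_score(expr_f, panel)
        roc = pnl.roc_auc(ps.to_numpy(), labels.loc[ps.index].to_numpy() == 1)
        panel.discovery_auc = roc.auc
        return panel, roc

    panel, roc_disc = runner.run("panel", do_panel)

    bundle = ResultsBundle(
        subtype_model=model, silhouette_by_k=model.silhouette_by_k, scores=scores,
        fibrosis_scores=fscores, fibrosis_levels=flevels, partition=partition,
        lafsaa=lafsaa_res, panel=panel, roc_discovery=roc_disc, seed=config.seed,
        log=runner.log,
    )
    _write_bundle(bundle, outdir)
    return bundle


def run_validation(config: PipelineConfig, bundle: ResultsBundle) -> ResultsBundle:
    """Assign a validation cohort by centroid distance, score the panel and
    append the validation ROC to the bundle."""
    config.validate(require_validation=True)
    outdir = Path(config.outdir)
    runner = _Runner(outdir)

    def load():
        expr = isio.read_matrix_tsv(config.val_expr, "expression")
        fractions = isio.read_matrix_tsv(config.val_fractions, "fractions")
        meta = isio.read_meta_tsv(config.val_meta) if config.val_meta else None
        return expr, fractions, meta

    expr, fractions, meta = runner.run("load_validation", load)
    if meta is not None:
        failing = {m.sample_id for m in meta if m.status == "failing"}
        fractions = fractions.subset_samples([s for s in fractions.sample_ids if s in failing])
        expr = expr.subset_samples([s for s in expr.sample_ids if s in failing])
    if not fractions.sample_ids:
        raise StageError("stage 'assign_validation' failed: empty validation cohort")

    labels_val = runner.run("assign_validation",
                            lambda: subtyping.assign_by_centroid(bundle.subtype_model, fractions))

    def do_roc():
        ps = pnl.panel_score(expr, bundle.panel)
        y = labels_val.reindex(ps.index).to_numpy() == 1
        return ps, pnl.roc_auc(ps.to_numpy(), y)

    ps_val, roc_val = runner.run("panel_validation", do_roc)
    bundle.labels_validation = labels_val
    bundle.panel_scores_validation = ps_val
    bundle.roc_validation = roc_val
    bundle.panel.validation_auc = roc_val.auc
    bundle.log.extend(runner.log)
    _write_bundle(bundle, outdir)
    return bundle


def _write_roc(roc: RocCurve, path: Path) -> None:
    pd.DataFrame({"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
                 ).to_csv(path, sep="\t", index=False)


def _write_bundle(bundle: ResultsBundle, outdir: Path) -> None:
    (outdir / "subtype_model.json").write_text(
        json.dumps(_model_to_json(bundle.subtype_model), indent=1, sort_keys=True))
    bundle.subtype_model.labels.rename("subtype").to_csv(outdir / "labels.tsv", sep="\t")
    bundle.scores.data.to_csv(outdir / "scores.tsv", sep="\t")
    pd.DataFrame({"fibrosis_score": bundle.fibrosis_scores,
                  "fibrosis_level": bundle.fibrosis_levels}
                 ).to_csv(outdir / "fibrosis_scores.tsv", sep="\t")
    (outdir / "partition.json").write_text(json.dumps({
        "counts": {str(k): v for k, v in
                   bundle.partition.counts.to_dict(orient="index").items()},
        "percent_of_total": {str(k): v for k, v in
                             bundle.partition.percent_of_total.to_dict(orient="index").items()},
    }, indent=1, sort_keys=True))
    (outdir / "lafsaa.json").write_text(
        json.dumps(_lafsaa_to_json(bundle.lafsaa), indent=1, sort_keys=True))
    (outdir / "panel.json").write_text(json.dumps({
        "up_genes": bundle.panel.up_genes,
        "down_genes": bundle.panel.down_genes,
        "lambda_selected": bundle.panel.lambda_selected,
        "discovery_auc": bundle.panel.discovery_auc,
        "validation_auc": bundle.panel.validation_auc,
    }, indent=1, sort_keys=True))
    _write_roc(bundle.roc_discovery, outdir / "roc_discovery.tsv")
    if bundle.roc_validation is not None:
        _write_roc(bundle.roc_validation, outdir / "roc_validation.tsv")
        bundle.labels_validation.rename("subtype").to_csv(
            outdir / "labels_validation.tsv", sep="\t")
    (outdir / "run_log.json").write_text(json.dumps(
        {"seed": bundle.seed, "stages": bundle.log}, indent=1, sort_keys=True))
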