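"""Orchestration of the two workflows.

(A) *marker discovery*: informative-gene filtering -> batch merge ->
    nearest-shrunken-centroid threshold selection -> marker extraction ->
    reference signature -> moderated-t differential expression ->
    hypergeometric enrichment -> module eigengene correlations.
(B) *cohort scoring*: log2(x+1) -> ercDC score -> cutpoint search ->
    KM / log-rank / Cox -> score-grade trend test.

Both take a flat configuration mapping (YAML-friendly), write TSV/JSON
artifacts plus a manifest recording the config hash, seed, package version,
per-stage row counts and artifact checksums.  Every constant of the
published analysis (informative quantile 0.5, FPR bound 0.20, DEG adjusted
p < 0.05, enrichment p < 0.001, split alpha 0.1, minimum group 10, grade
scores 1/2/3) surfaces as a named key defaulting to that value.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, de, io, nsc, scoring, survival as surv
from .modules import ModuleDefinition, correlate_modules_celltypes, module_eigengene
from .batch import combat_merge
from .preprocess import filter_informative, log_transform, median_by_group
from .sim import (SimConfig, config_to_dict, generate_bulk_cohort,
                  generate_reference_profiles, generate_survival)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


DEFAULT_CONFIG: dict = {
    "seed": None,  # mandatory for any stochastic stage
    "outdir": "ercdc_run",
    "target_class": "ercDC",
    # preprocessing
    "informative_quantile": 0.5,
    # marker selection
    "fpr_max": 0.20,
    "fpr_mode": "one_vs_rest",
    "cv_folds": 10,
    "threshold_grid_size": 30,
    # differential expression / enrichment
    "deg_alpha": 0.05,
    "enrichment_p_max": 0.001,
    "gmt_file": None,
    # survival
    "min_group": 10,
    "split_alpha": 0.1,
    "n_perm": 9999,
    "grade_scores": [1, 2, 3],
    # stage toggles
    "run_deg": True,
    "run_enrichment": True,
    "run_modules": True,
    # synthetic-data conditions (used when no input files are given)
    "sim": {},
    # optional file inputs
    "expr_files": None,
    "annotation_file": None,
    "cohort_file": None,
    "survival_file": None,
    "signature_file": None,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    if cfg["seed"] is None:
        raise PipelineError("config error: a seed is mandatory (no silent defaults)")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, cfg: dict, stage_rows: dict, name: str) -> Path:
    manifest = {
        "workflow": name,
        "package_version": __version__,
        "seed": cfg["seed"],
        "config_sha256": _config_hash(cfg),
        "stage_rows": stage_rows,
        "artifacts": {
            p.name: _file_sha256(p)
            for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json"))
            if p.name != f"manifest_{name}.json"
        },
    }
    path = outdir / f"manifest_{name}.json"
    io.write_json(manifest, path)
    return path


def _sim_config(cfg: dict) -> SimConfig:
    sim_kwargs = dict(cfg.get("sim") or {})
    sim_kwargs.setdefault("seed", cfg["seed"])
    return SimConfig(**sim_kwargs)


def _load_reference(cfg: dict):
    """Reference expression + annotation, from files or the generator."""
    if cfg["expr_files"]:
        mats = [io.read_expression(p) for p in cfg["expr_files"]]
        ann = io.read_annotation(cfg["annotation_file"])
        return mats, ann, None
    expr, ann, truth = generate_reference_profiles(_sim_config(cfg))
    return [expr], ann, truth


def run_marker_discovery(cfg: dict) -> dict:
    """Workflow A.  Returns the manifest dict; writes artifacts to outdir."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stage_rows: dict[str, int] = {}

    try:
        mats, ann, truth = _load_reference(cfg)
        filtered = [filter_informative(m, cfg["informative_quantile"]) for m in mats]
        stage_rows["informative_genes"] = int(sum(len(m) for m in filtered))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage preprocess failed: {exc}") from exc

    try:
        merged = combat_merge(filtered, ann)
        stage_rows["merged_genes"] = len(merged)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage combat_merge failed: {exc}") from exc

    target = cfg["target_class"]
    try:
        labels = ann.loc[merged.columns, "cell_type"]
        model = nsc.train_centroids(merged, labels)
        grid = nsc.default_threshold_grid(model, cfg["threshold_grid_size"])
        cv = nsc.cross_validate(merged, labels, grid, cfg["cv_folds"], cfg["seed"])
        delta_star = nsc.select_threshold(cv, target, cfg["fpr_max"],
                                          cfg["fpr_mode"])
        markers = nsc.extract_markers(model, delta_star, target)
        stage_rows["marker_genes"] = len(markers)
        markers_out = markers.copy()
        markers_out.index.name = "gene_id"
        markers_out.to_csv(outdir / "markers.tsv", sep="\t",
                           float_format="%.10g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage nsc_markers failed: {exc}") from exc

    try:
        ref_cols = merged.columns[(labels == target).to_numpy()]
        signature = scoring.build_reference_signature(merged[ref_cols], markers)
        sig_out = pd.DataFrame({"r_g": signature,
                                "direction": markers["direction"]})
        sig_out.index.name = "gene_id"
        sig_out.to_csv(outdir / "signature.tsv", sep="\t", float_format="%.10g")
        stage_rows["signature_genes"] = len(signature)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage signature failed: {exc}") from exc

    degs = None
    if cfg["run_deg"]:
        try:
            group = pd.Series(
                np.where(labels == target, "target", "control"),
                index=merged.columns,
            )
            degs = de.moderated_t_test(merged, group, target="target")
            degs.index.name = "gene_id"
            degs.to_csv(outdir / "degs.tsv", sep="\t", float_format="%.10g")
            stage_rows["degs_significant"] = int(
                (degs["p_adj"] < cfg["deg_alpha"]).sum())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage diff_expression failed: {exc}") from exc

    collection = None
    if cfg["gmt_file"]:
        collection = io.read_gmt(cfg["gmt_file"])
    elif truth is not None:
        # planted signatures double as gene sets for the synthetic workflow
        collection = {}
        for gene, ct in truth.signature_gene_assignment.items():
            collection.setdefault(f"planted_{ct}", []).append(gene)

    if cfg["run_enrichment"] and degs is not None and collection:
        try:
            hits = set(degs.index[degs["p_adj"] < cfg["deg_alpha"]])
            enr = de.hypergeom_enrichment(hits, collection, set(degs.index),
                                          cfg["enrichment_p_max"])
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.10g")
            stage_rows["enriched_sets"] = len(enr)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage enrichment failed: {exc}") from exc
    else:
        stage_rows["enriched_sets"] = -1  # stage skipped

    if cfg["run_modules"] and collection:
        try:
            medians = median_by_group(merged, ann, "cell_type")
            results = []
            for name, genes in collection.items():
                try:
                    results.append(module_eigengene(
                        medians, ModuleDefinition(name, genes)))
                except ValueError as err:
                    logger.warning("module %s skipped: %s", name, err)
            if results:
                corr = correlate_modules_celltypes(results)
                corr.to_csv(outdir / "me_corr.tsv", sep="\t",
                            float_format="%.10g")
                stage_rows["modules"] = len(results)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage polarization_modules failed: {exc}") from exc

    manifest_path = _write_manifest(outdir, cfg, stage_rows, "marker_discovery")
    return json.loads(manifest_path.read_text())


def run_cohort_scoring(cfg: dict) -> dict:
    """Workflow B.  Returns the manifest dict; writes artifacts to outdir."""
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stage_rows: dict[str, int] = {}

    sig_path = cfg["signature_file"] or outdir / "signature.tsv"
    if not Path(sig_path).exists():
        raise PipelineError(f"stage scoring failed: signature file {sig_path} "
                            "does not exist (run marker discovery first)")
    sig_tbl = pd.read_csv(sig_path, sep="\t").set_index("gene_id")
    signature = sig_tbl["r_g"]

    try:
        if cfg["cohort_file"]:
            cohort = io.read_expression(cfg["cohort_file"])
            cohort = log_transform(cohort)
            surv_tbl = io.read_survival(cfg["survival_file"])
        else:
            sim_cfg = _sim_config(cfg)
            _, _, ref_truth = generate_reference_profiles(sim_cfg)
            bulk, _, truth = generate_bulk_cohort(sim_cfg, ref_truth)
            cohort = bulk  # generator output is already log2 scale
            if cohort.shape[1] < 2:
                raise ValueError(f"insufficient cohort size n={cohort.shape[1]}")
            surv_tbl = generate_survival(sim_cfg, truth)
        if cohort.shape[1] < 2:
            raise ValueError(f"insufficient cohort size n={cohort.shape[1]}")

    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage cohort input failed: {exc}") from exc

    try:
        scores = scoring.ercdc_score(cohort, signature)
        scores.to_csv(outdir / "scores.tsv", sep="\t", float_format="%.10g")
        stage_rows["scored_samples"] = len(scores)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage scoring failed: {exc}") from exc

    try:
        tbl = surv_tbl.join(scores["score"], how="inner")
        report: dict = {"n_subjects": len(tbl),
                        "n_events": int(tbl["event"].sum())}
        cut = surv.cutpoint_search(tbl, "score", cfg["min_group"],
                                   cfg["split_alpha"], cfg["n_perm"],
                                   cfg["seed"])
        if cut is None:
            report["cutpoint"] = None
        else:
            group = np.where(tbl["score"] > cut.cutpoint, "high", "low")
            tbl["risk_group"] = group
            chi2, p_lr = surv.logrank_test(tbl, "risk_group")
            cox = surv.cox_univariate(
                tbl.assign(high=(tbl["risk_group"] == "high").astype(float)),
                "high")
            km = {g: surv.km_estimator(tbl[tbl["risk_group"] == g])
                  for g in ("low", "high")}
            report["cutpoint"] = {
                "value": cut.cutpoint, "n_low": cut.n_low, "n_high": cut.n_high,
                "p_adjusted": cut.p_adjusted,
            }
            report["logrank"] = {"chi2": chi2, "p": p_lr}
            report["cox_high_vs_low"] = {
                "hr": cox.hr, "beta": cox.beta, "se": cox.se,
                "ci": [cox.ci_lower, cox.ci_upper], "p": cox.p_value,
            }
            report["km"] = {
                g: km[g].table.reset_index().round(6).to_dict(orient="list")
                for g in km
            }
        if "grade" in tbl.columns and tbl["grade"].notna().all():
            stat, p_trend = surv.trend_test(tbl["score"], tbl["grade"],
                                            cfg["n_perm"], cfg["seed"])
            report["trend"] = {"statistic": stat, "p": p_trend}
        io.write_json(report, outdir / "survival_report.json")
        stage_rows["survival_report"] = 1
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage survival_analysis failed: {exc}") from exc

    manifest_path = _write_manifest(outdir, cfg, stage_rows, "cohort_scoring")
    return json.loads(manifest_path.read_text())


def simulate_to_dir(cfg: dict, outdir: str | Path) -> None:
    """Write the full synthetic data set (reference, bulk, survival, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = _sim_config(cfg)
    expr, ann, ref_truth = generate_reference_profiles(sim_cfg)
    bulk, cohort_ann, truth = generate_bulk_cohort(sim_cfg, ref_truth)
    surv_tbl = generate_survival(sim_cfg, truth)
    io.write_expression(expr, outdir / "reference.tsv")
    io.write_annotation(ann, outdir / "reference_annotation.tsv")
    io.write_expression(bulk, outdir / "bulk.tsv")
    io.write_annotation(cohort_ann, outdir / "cohort_annotation.tsv")
    surv_tbl.round(10).to_csv(outdir / "survival.tsv", sep="\t")
    io.write_json({"config": config_to_dict(sim_cfg),
                   "truth": truth.to_json_dict()}, outdir / "truth.json")
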