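"""End-to-end orchestration: simulate/load -> QC -> impute -> GRM -> FA1 fit
-> check model -> selection index -> classification -> evaluation -> decisions.

Every stage writes its documented CSV artifact into the run directory and a
``manifest.json`` records the configuration, seeds, package versions, and a
checksum per artifact so a run can be reproduced from the manifest alone.
A stage failure halts the run with the stage name and cause; artifacts
already written are retained.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import CVProtocol, ModelSpec, run_repeated_cv, train_final_model
from .evaluation import (apply_decision_rule, diversity_diagnostic,
                         pooled_probabilities, report_frames)
from .gxe import FitOptions, fit_check_model, fit_fa1_gblup, predict_gblups
from .io import (read_marker_csv, read_phenotypes, read_vcf, write_grm_csv,
                 write_marker_csv, write_phenotypes, write_vcf)
from .markers import compute_grm, impute_markers, pca_markers, qc_filter
from .selection_index import ClassThresholds, compute_msi
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full run.

    Either ``sim`` is given (synthetic data are generated) or ``marker_path``
    / ``pheno_path`` point at existing inputs (numeric CSV or VCF for
    markers, tidy CSV for phenotypes).
    """

    out_dir: str | Path = "run"
    sim: SimConfig | None = None
    marker_path: str | Path | None = None
    pheno_path: str | Path | None = None
    thresholds: ClassThresholds = dataclasses.field(default_factory=ClassThresholds)
    protocol: CVProtocol = dataclasses.field(default_factory=CVProtocol)
    model_specs: list = dataclasses.field(
        default_factory=lambda: [ModelSpec("elastic_net_multinomial"), ModelSpec("random_forest")])
    fit_options: FitOptions = dataclasses.field(default_factory=FitOptions)
    decision_threshold: float = 0.70
    msi_observed_only: bool = False
    qc_max_missing: float = 0.20
    impute_max_iter: int = 10
    impute_trees: int = 100
    pca_components: int = 2
    write_vcf_copy: bool = True
    train_final: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and (self.marker_path is None or self.pheno_path is None):
            raise ValueError("provide either a SimConfig or marker_path + pheno_path")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.ndarray, list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage_log: list[dict] = []

    def save(df: pd.DataFrame, name: str, **kw) -> Path:
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = _checksum(path)
        return path

    def run_stage(name, fn):
        logger.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:  # halt with stage name, keep partial outputs
            raise PipelineStageError(name, exc) from exc
        stage_log.append({"stage": name, "ok": True})
        return result

    # ---- input -----------------------------------------------------------
    def _input():
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.sim.seed or config.seed)
            data = simulate_dataset(sim)
            write_marker_csv(data.markers, out / "markers.csv")
            artifacts["markers.csv"] = _checksum(out / "markers.csv")
            if config.write_vcf_copy:
                write_vcf(data.markers, out / "markers.vcf")
                artifacts["markers.vcf"] = _checksum(out / "markers.vcf")
            write_phenotypes(data.pheno, out / "phenotypes.csv")
            artifacts["phenotypes.csv"] = _checksum(out / "phenotypes.csv")
            save(data.truth.to_frame(), "sim_truth.csv", index=False)
            meta = data.markers.genotype_meta
            return data.markers, data.pheno, meta
        mp = str(config.marker_path)
        markers = read_vcf(mp) if mp.endswith(".vcf") else read_marker_csv(mp)
        pheno = read_phenotypes(config.pheno_path)
        meta = pheno.drop_duplicates("genotype").set_index("genotype")[
            ["maturity_group", "is_check"]]
        if markers.genotype_meta is None:
            markers.genotype_meta = meta.reindex(markers.genotype_ids)
        return markers, pheno, markers.genotype_meta

    markers, pheno, gmeta = run_stage("input", _input)
    is_check = gmeta["is_check"].astype(bool)
    line_ids = [g for g in markers.genotype_ids if not is_check.get(g, False)]
    line_markers = markers.subset_genotypes(np.asarray(line_ids, dtype=object))

    # ---- marker QC / imputation / GRM / PCA ------------------------------
    def _qc():
        filtered, log = qc_filter(line_markers, config.qc_max_missing)
        path = out / "qc_removed.tsv"
        log.to_csv(path, sep="\t", index=False)
        artifacts["qc_removed.tsv"] = _checksum(path)
        logger.info("qc: %d markers in, %d out", line_markers.n_markers, filtered.n_markers)
        return filtered

    filtered = run_stage("qc", _qc)

    imputed = run_stage("impute", lambda: impute_markers(
        filtered, max_iter=config.impute_max_iter, seed=config.seed,
        n_trees=config.impute_trees))
    run_stage("write-imputed", lambda: write_marker_csv(imputed, out / "markers_imputed.csv"))
    artifacts["markers_imputed.csv"] = _checksum(out / "markers_imputed.csv")

    grm = run_stage("grm", lambda: compute_grm(imputed))
    write_grm_csv(grm, out / "grm.csv")
    artifacts["grm.csv"] = _checksum(out / "grm.csv")

    pca = run_stage("pca", lambda: pca_markers(imputed, config.pca_components))
    save(pd.DataFrame(pca.scores, index=pca.genotype_ids,
                      columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]),
         "pca_scores.csv")

    # ---- mixed models ----------------------------------------------------
    pheno_lines = pheno[~pheno["is_check"]]
    pheno_checks = pheno[pheno["is_check"]]

    fit = run_stage("fit-gxe", lambda: fit_fa1_gblup(pheno_lines, grm, config.fit_options))
    (out / "fit_summary.json").write_text(json.dumps({
        "mu": fit.mu, "sigma2_g": fit.sigma2_g, "sigma2_e": fit.sigma2_e,
        "loadings": fit.loadings.to_dict(), "psi": fit.psi.to_dict(),
        "location_effects": fit.location_effects.to_dict(),
        "loglik": fit.loglik, "converged": fit.converged, "n_iter": fit.n_iter,
        "loglik_trace": fit.loglik_trace, "boundary": fit.boundary,
    }, indent=2, default=float))
    artifacts["fit_summary.json"] = _checksum(out / "fit_summary.json")

    gblups = run_stage("predict-gblups", lambda: predict_gblups(fit, grm))
    save(gblups.to_frame(), "gblups.csv")
    save(gblups.observed_mask.astype(int), "gblups_mask.csv")

    checks = run_stage("check-model", lambda: fit_check_model(pheno_checks, config.fit_options))
    save(checks.table, "check_reference.csv")

    # ---- selection index -------------------------------------------------
    mg_map = gmeta["maturity_group"].to_dict()
    msi = run_stage("msi", lambda: compute_msi(
        gblups, checks, mg_map, thresholds=config.thresholds,
        observed_only=config.msi_observed_only))
    save(msi, "msi.csv", index=False)

    # ---- classification + evaluation + decisions ------------------------
    for spec in config.model_specs:
        tag = "glmnet" if spec.family == "elastic_net_multinomial" else "rf"

        preds = run_stage(f"classify-{tag}", lambda spec=spec: run_repeated_cv(
            imputed, msi, spec, config.protocol))
        save(preds, f"cv_predictions_{tag}.csv", index=False)

        def _evaluate(preds=preds, tag=tag):
            frames = report_frames(preds)
            for name, df in frames.items():
                save(df, f"{name}_{tag}.csv")
            return frames

        run_stage(f"evaluate-{tag}", _evaluate)

        def _decide(preds=preds, tag=tag):
            pooled = pooled_probabilities(preds)
            decisions = apply_decision_rule(pooled, config.decision_threshold)
            save(decisions.table, f"decisions_{tag}.csv", index=False)
            div = diversity_diagnostic(pca, decisions)
            (out / f"diversity_{tag}.json").write_text(json.dumps({
                "centroids": div.centroids.to_dict(),
                "dispersion": div.dispersion.to_dict(),
                "overlap_coefficient": div.overlap_coefficient,
                "discard_fraction": decisions.discard_fraction,
                "flags": div.flags,
            }, indent=2, default=float))
            artifacts[f"diversity_{tag}.json"] = _checksum(out / f"diversity_{tag}.json")
            return decisions

        run_stage(f"decide-{tag}", _decide)

        if config.train_final:
            final = run_stage(f"final-model-{tag}", lambda spec=spec: train_final_model(
                imputed, msi, spec, config.protocol))
            (out / f"model_card_{tag}.json").write_text(
                json.dumps(final.model_card(), indent=2))
            artifacts[f"model_card_{tag}.json"] = _checksum(out / f"model_card_{tag}.json")

    # ---- manifest --------------------------------------------------------
    import sklearn

    manifest = {
        "soyclass_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": stage_log,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
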