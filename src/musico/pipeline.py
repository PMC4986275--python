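"""End-to-end pipeline driver: simulate/load -> preprocess -> model ->
evaluate -> network, with structured reporting.

The driver reproduces the three-block design of the analysis: (1) multigene
qPCR profiling (here: synthetic Ct tables run through ddCt preprocessing),
(2) penalized multivariable survival modelling with nested cross-validation
and model comparison, and (3) co-expression network reconstruction for the
top-ranked target genes.  A single master seed is expanded into per-stage
seeds by a stable stage-name hash, so every stage is independently
reproducible and identical configurations yield identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import signature as sig
from .coxph import (
    SurvivalOutcome,
    cross_validated_predictors,
    fit_penalized_cox,
    rank_variables,
    tune_lambda_loocv,
)
from .evaluate import (
    compare_models,
    evaluate_model,
    km_estimate,
    logrank_test,
    permutation_control,
)
from .network import (
    build_mixed_list,
    fisher_enrich,
    hkg_quality_check,
    rank_algorithm_I,
    rank_algorithm_II,
    read_gmt,
    select_extreme_samples,
    top_coexpressed,
)
from .qpcr import CtTable, compute_rq, filter_detected, log2_and_impute
from .synthetic_data import (
    CohortSpec,
    CtSpec,
    TissueMatrixSpec,
    generate_cohort,
    generate_ct_table,
    generate_gene_sets,
    generate_tissue_matrix,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report", "stage_seed"]

log = logging.getLogger("musico")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed (stable name hash)."""
    return int((master_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    With all paths left ``None`` the pipeline runs on synthetic data
    generated from the packaged cohort defaults.  ``inner_cv`` is ``"loo"``
    for full-fidelity leave-one-out tuning or an integer K for K-fold.
    """

    ct_path: str | None = None
    clinical_path: str | None = None
    matrix_path: str | None = None
    gmt_path: str | None = None
    endpoint: str = "OS"
    penalties: tuple = ("ridge", "lasso")
    n_lambda: int = 20
    inner_cv: object = 10
    n_permutations: int = 20
    stdbeta_cutpoint: float = sig.STDBETA_CUTPOINT
    detection_limit_ct: float = 35.0
    seed: int = 0
    outdir: str | None = None
    run_network: bool = True
    run_permutation: bool = True
    ct_noise_sd: float = 0.10
    n_patients: int = 186

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunReport:
    """All pipeline outputs plus per-stage status and seeds."""

    config: dict
    stage_status: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    excluded_genes: list = field(default_factory=list)
    model_comparison: pd.DataFrame | None = None
    variable_rankings: dict = field(default_factory=dict)
    risk_strata: dict = field(default_factory=dict)
    km_curves: dict = field(default_factory=dict)
    logrank: dict = field(default_factory=dict)
    permutation: dict | None = None
    target_genes: list = field(default_factory=list)
    network: dict = field(default_factory=dict)


def _synthetic_ct_inputs(config: PipelineConfig):
    """Generate a cohort plus a matching 24-gene Ct table.

    The three low-expression panel genes get vanishingly small true
    quantities so their Cts always exceed the undetermined cutoff and the
    detection filter removes exactly those genes, as in real tissue.
    """
    cohort = generate_cohort(
        CohortSpec(n_patients=config.n_patients, seed=stage_seed(config.seed, "cohort"))
    )
    rq = cohort.expression_rq.copy()
    rq.index = [f"P{i + 1:03d}" for i in range(len(rq))]
    for g in sig.LOW_EXPRESSION_GENES:
        rq[g] = 2.0**-30
    rq = rq[list(sig.SIGNATURE_GENES)]
    cal = pd.DataFrame(1.0, index=["CAL"], columns=rq.columns)
    true_rq = pd.concat([cal, rq])
    ct, _ = generate_ct_table(
        CtSpec(
            gene_names=tuple(sig.SIGNATURE_GENES),
            hkg_names=tuple(sig.TISSUE_HKGS),
            calibrator_id="CAL",
            true_rq=true_rq,
            ct_noise_sd=config.ct_noise_sd,
            seed=stage_seed(config.seed, "ct"),
        )
    )
    return cohort, ct


def _load_ct(path: str, hkgs, calibrator: str) -> CtTable:
    ct = pd.read_csv(path, sep="\t", index_col=0)
    return CtTable(ct=ct, hkg_names=tuple(hkgs), calibrator_id=calibrator)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and return the structured report."""
    report = RunReport(config=vars(config).copy())
    t0 = _time.time()

    def stage_done(name, **extra):
        report.stage_status[name] = {"status": "ok", "elapsed_s": round(_time.time() - t0, 2), **extra}
        log.info("stage %s done (%.1fs)", name, _time.time() - t0)

    # ---- stage 1: inputs -------------------------------------------------
    seed_cohort = stage_seed(config.seed, "cohort")
    report.stage_seeds["cohort"] = seed_cohort
    synthetic = config.ct_path is None
    if synthetic:
        cohort, ct = _synthetic_ct_inputs(config)
        outcome = cohort.outcome
        clinical = cohort.clinical
    else:
        ct = _load_ct(config.ct_path, sig.TISSUE_HKGS, "CAL")
        clin = pd.read_csv(config.clinical_path, sep="\t", index_col=0)
        outcome = SurvivalOutcome(
            clin["time"].to_numpy(), clin["event"].to_numpy(), config.endpoint
        )
        clinical = clin[list(sig.CLINICAL_VARIABLES)]
        cohort = None
    stage_done("inputs", synthetic=synthetic)

    # ---- stage 2: preprocess --------------------------------------------
    rq = compute_rq(ct, detection_limit_ct=config.detection_limit_ct)
    rq.values.drop(index=[ct.calibrator_id], inplace=True, errors="ignore")
    filtered, excluded = filter_detected(rq, list(sig.SIGNATURE_GENES))
    expr = log2_and_impute(filtered, method="median")
    expr_df = expr.values.reset_index(drop=True)
    report.excluded_genes = excluded
    stage_done("preprocess", n_genes=expr_df.shape[1], excluded=excluded)

    # ---- stage 3: models + evaluation -----------------------------------
    clinical = clinical.reset_index(drop=True)
    matrices = {
        "Clinics": clinical,
        "AID/APOBEC": expr_df,
        "Combined": pd.concat([clinical, expr_df], axis=1),
    }
    seed_model = stage_seed(config.seed, "model")
    report.stage_seeds["model"] = seed_model
    reports = []
    for penalty in config.penalties:
        preds_clinics = None
        for label, X in matrices.items():
            preds = cross_validated_predictors(
                X,
                outcome,
                penalty,
                inner_cv=config.inner_cv,
                n_lambda=config.n_lambda,
                seed=seed_model,
                label=label,
            )
            if label == "Clinics":
                preds_clinics = preds
            mrep = evaluate_model(
                preds, outcome, preds_clinics=None if label == "Clinics" else preds_clinics
            )
            reports.append(mrep)
            if mrep.available and mrep.risk_groups is not None:
                key = f"{penalty}:{label}"
                report.risk_strata[key] = mrep.risk_groups
                chi2, df_, p = logrank_test(outcome, mrep.risk_groups.to_numpy())
                report.logrank[key] = {"chi2": chi2, "df": df_, "p": p}
                for grp in ("low", "intermediate", "high"):
                    mask = (mrep.risk_groups == grp).to_numpy()
                    if mask.sum():
                        report.km_curves[f"{key}:{grp}"] = km_estimate(
                            outcome.subset(mask), label=grp
                        ).to_frame()
            # full-data fit for the variable ranking
            tun = tune_lambda_loocv(
                X, outcome, penalty, cv=config.inner_cv, seed=seed_model
            )
            if not tun.no_model:
                fit = fit_penalized_cox(X, outcome, penalty, tun.lam_opt)
                try:
                    report.variable_rankings[f"{penalty}:{label}"] = rank_variables(
                        fit, outcome, cutpoint=config.stdbeta_cutpoint
                    )
                except ValueError as err:  # e.g. follow-up short of 36 months
                    report.warnings.append(f"ranking {penalty}:{label}: {err}")
    report.model_comparison = compare_models(reports)
    stage_done("model")

    # ---- stage 4: permutation control -----------------------------------
    if config.run_permutation:
        seed_perm = stage_seed(config.seed, "permutation")
        report.stage_seeds["permutation"] = seed_perm
        perm = permutation_control(
            expr_df,
            clinical,
            outcome,
            n_replicates=config.n_permutations,
            seed=seed_perm,
            inner_cv=5,
            n_lambda=10,
        )
        report.permutation = {
            "replicates": perm.replicates,
            "frac_with_model": perm.frac_with_model,
        }
        stage_done("permutation", frac_with_model=perm.frac_with_model)

    # ---- stage 5: target genes ------------------------------------------
    ranking_key = "ridge:Combined"
    targets: list[str] = []
    if ranking_key in report.variable_rankings:
        rk = report.variable_rankings[ranking_key]
        targets = [
            v
            for v in rk.index[rk["selected"]]
            if v in expr_df.columns  # genes only, not clinical covariates
        ]
    if not targets:
        targets = [g for g in sig.DEFAULT_TARGET_GENES if g in expr_df.columns]
        report.warnings.append(
            "no genes passed the STDBETA cutpoint; default target genes used"
        )
    report.target_genes = targets
    stage_done("targets", targets=targets)

    # ---- stage 6: network reconstruction --------------------------------
    if not config.run_network:
        stage_done("network", skipped=True)
        return report
    seed_net = stage_seed(config.seed, "network")
    report.stage_seeds["network"] = seed_net
    if config.matrix_path is not None:
        tissue = pd.read_csv(config.matrix_path, sep="\t", index_col=0)
        tissue_spec = None
    else:
        tissue_spec = TissueMatrixSpec(target_genes=tuple(targets), seed=seed_net)
        tissue = generate_tissue_matrix(tissue_spec).values
    if config.gmt_path is not None:
        collection = read_gmt(config.gmt_path)
    elif tissue_spec is not None:
        planted = [g for t in targets for g in tissue_spec.planted_genes(t)]
        collection = generate_gene_sets(
            universe=list(tissue.columns),
            n_sets=50,
            planted_set=planted,
            seed=seed_net,
        )
    else:
        report.warnings.append("no gene-set collection given; network stage skipped")
        report.stage_status["network"] = {"status": "skipped", "reason": "no GMT"}
        return report

    hkg_cols = [c for c in tissue.columns if c.startswith("HKG")]
    qc = hkg_quality_check(tissue, hkg_cols) if len(hkg_cols) >= 2 else None

    universe = set(tissue.columns) | collection.universe()
    coex = {}
    enrich_ind = {}
    for target in targets:
        subset = select_extreme_samples(tissue, target)
        cl = top_coexpressed(tissue, subset, target)
        coex[target] = cl
        enrich_ind[target] = fisher_enrich(cl.genes, collection, universe)
    mixed_list = build_mixed_list(list(coex.values()))
    enrich_mixed = fisher_enrich(mixed_list, collection, universe)
    report.network = {
        "hkg_qc": qc,
        "coexpression": {t: c.table for t, c in coex.items()},
        "mixed_list": mixed_list,
        "enrichment_mixed": enrich_mixed,
        "enrichment_individual": enrich_ind,
        "algorithm_I": rank_algorithm_I(enrich_mixed, enrich_ind),
        "algorithm_II": rank_algorithm_II(enrich_mixed, enrich_ind),
    }
    stage_done("network")
    return report


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: RunReport, outdir) -> dict:
    """Write the JSON master report plus TSV tables; return the manifest.

    Unavailable models render as the string "n.a." (never as zeros).  The
    manifest lists every produced file with its sha256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, index=False):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        files.append(path)

    if report.model_comparison is not None:
        save_tsv(report.model_comparison, "model_comparison.tsv")
    for key, rk in report.variable_rankings.items():
        save_tsv(rk, f"ranking_{key.replace(':', '_').replace('/', '-')}.tsv", index=True)
    for key, strata in report.risk_strata.items():
        save_tsv(
            strata.rename("risk_group").to_frame(),
            f"strata_{key.replace(':', '_').replace('/', '-')}.tsv",
            index=True,
        )
    for key, km in report.km_curves.items():
        save_tsv(km, f"km_{key.replace(':', '_').replace('/', '-')}.tsv")
    if report.permutation is not None:
        save_tsv(report.permutation["replicates"], "permutation_replicates.tsv")
    if report.network:
        for t, tab in report.network["coexpression"].items():
            save_tsv(tab, f"coexpression_{t}.tsv")
        save_tsv(report.network["enrichment_mixed"], "enrichment_mixed.tsv")
        for t, tab in report.network["enrichment_individual"].items():
            save_tsv(tab, f"enrichment_{t}.tsv")
        save_tsv(report.network["algorithm_I"], "algorithm_I.tsv")
        save_tsv(report.network["algorithm_II"], "algorithm_II.tsv")

    # timings are excluded from the master report so identical runs are
    # byte-identical on disk
    stage_status = {
        name: {k: v for k, v in info.items() if k != "elapsed_s"}
        for name, info in report.stage_status.items()
    }
    master = {
        "config": _jsonable(report.config),
        "stage_status": _jsonable(stage_status),
        "stage_seeds": _jsonable(report.stage_seeds),
        "warnings": report.warnings,
        "excluded_genes": report.excluded_genes,
        "model_comparison": _jsonable(report.model_comparison),
        "logrank": _jsonable(report.logrank),
        "target_genes": report.target_genes,
        "permutation_frac_with_model": None
        if report.permutation is None
        else report.permutation["frac_with_model"],
        "network_present": bool(report.network),
    }
    master_path = outdir / "report.json"
    with open(master_path, "w") as fh:
        json.dump(master, fh, indent=2, sort_keys=True)
    files.append(master_path)

    manifest = {}
    for path in files:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[path.name] = digest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
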