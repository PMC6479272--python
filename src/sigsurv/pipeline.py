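"""End-to-end orchestration: from expression + clinical data (real or
synthetic) to stratification, the seven prognostic models, importance and
risk-group summaries, and a single machine-readable JSON report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cox import cox_penalized, importance_s36, select_lambda_loocv
from .data import ClinicalTable, CohortDataset, CtTable, ExpressionMatrix
from .evaluate import (
    VARIABLE_SETS,
    compare_models,
    design_matrix,
    risk_groups_km,
)
from .qpcr import impute_chained, log2_transform, normalize_qpcr
from .signature import default_signature
from .simulate import SyntheticConfig, generate_cohort
from .stratify import assign_subtypes, chi_square_2xk, compare_groups, correlation_matrix

logger = logging.getLogger("sigsurv")

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Input is either a synthetic-cohort configuration or paths to an
    expression (or raw Ct) TSV plus a clinical TSV.  Every stage derives
    its randomness from ``seed``.
    """

    synthetic: SyntheticConfig | None = None
    expression_tsv: str | None = None
    clinical_tsv: str | None = None
    ct_tsv: str | None = None
    hkg: tuple[str, ...] = ("ACTB", "TOP1", "UBC", "YWHAZ")
    calibrator_id: str = "CALIBRATOR"
    variable_sets: tuple[str, ...] = VARIABLE_SETS
    penalty: str = "ridge"
    outcomes: tuple[str, ...] = ("OS",)
    impute_cycles: int = 10
    subtype_k: int = 3
    min_separation: float = 0.5
    n_lambda: int | None = None
    seed: int = 0
    outdir: str = "sigsurv_run"

    def validate(self) -> None:
        has_files = self.expression_tsv or self.ct_tsv
        if (self.synthetic is None) == (not has_files):
            if self.synthetic is None:
                raise ValueError("provide either a synthetic config or input files")
        if has_files and not self.clinical_tsv:
            raise ValueError("file input requires a clinical table")
        for f in (self.expression_tsv, self.clinical_tsv, self.ct_tsv):
            if f and not Path(f).exists():
                raise FileNotFoundError(f)


def _load_dataset(config: RunConfig) -> CohortDataset:
    if config.synthetic is not None:
        logger.info("generating synthetic cohort (n=%d, seed=%d)",
                    config.synthetic.n_samples, config.synthetic.seed)
        return generate_cohort(config.synthetic)
    sig = default_signature()
    if config.ct_tsv:
        ct = CtTable.from_tsv(config.ct_tsv, config.hkg, config.calibrator_id)
        expr = log2_transform(normalize_qpcr(ct))
        expr = ExpressionMatrix(
            values=expr.values.drop(index=config.calibrator_id, errors="ignore"),
            scale="log2",
        )
    else:
        expr = ExpressionMatrix.from_tsv(config.expression_tsv, scale="log2")
    clinical = ClinicalTable.from_tsv(config.clinical_tsv)
    expr = ExpressionMatrix(
        values=expr.values.loc[clinical.sample_ids], scale="log2"
    )
    return CohortDataset(expression=expr, clinical=clinical, signature=sig)


def run_full(config: RunConfig) -> dict:
    """Execute the full analysis sequence and return the report dict.

    Stages: preprocessing/imputation -> correlation & subtype
    stratification -> penalized survival models over the configured
    variable sets with nested-LOO validation -> variable importance ->
    quartile risk groups.  Per-stage TSVs and a ``report.json`` land in
    ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_json(config), "stages": {}}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # stage 1: data
    try:
        dataset = _load_dataset(config)
    except Exception as exc:
        fail("load", exc)
    logger.info("dataset: %d samples x %d genes", dataset.n,
                len(dataset.expression.gene_ids))

    # stage 2: imputation
    n_missing = dataset.expression.n_missing
    if n_missing:
        logger.info("imputing %d missing cells", n_missing)
        expr = impute_chained(
            dataset.expression, n_cycles=config.impute_cycles, seed=config.seed + 1
        )
        dataset = CohortDataset(
            expression=expr, clinical=dataset.clinical,
            signature=dataset.signature, true_subtype=dataset.true_subtype,
        )
    report["stages"]["preprocess"] = {
        "n_samples": dataset.n,
        "n_genes": len(dataset.expression.gene_ids),
        "n_missing_imputed": int(n_missing),
    }
    dataset.expression.to_tsv(outdir / "expression_imputed.tsv")

    # stage 3: stratification
    corr = correlation_matrix(dataset.expression)
    corr.r.to_csv(outdir / "correlation_r.tsv", sep="\t")
    corr.p_adj.to_csv(outdir / "correlation_p_holm.tsv", sep="\t")
    subtypes = assign_subtypes(
        dataset.expression, dataset.signature,
        k=config.subtype_k, min_separation=config.min_separation,
    )
    subtypes.labels.to_csv(outdir / "subtypes.tsv", sep="\t")
    counts = subtypes.labels.value_counts().to_dict()
    strat_report = {
        "subtype_counts": {k: int(v) for k, v in counts.items()},
        "cluster_core_means": {str(k): v for k, v in subtypes.cluster_means.items()},
        "n_strong_correlations": int(
            ((corr.r.abs() > 0.5) & (corr.p_adj < 0.001)).to_numpy().sum() // 2
        ),
    }
    two_groups = subtypes.labels.isin(["immune_low", "immune_high"])
    if two_groups.sum() >= 4 and subtypes.labels[two_groups].nunique() == 2:
        cmp_res = compare_groups(
            ExpressionMatrix(dataset.expression.values.loc[two_groups], "log2"),
            subtypes.labels[two_groups],
        )
        cmp_res.table.to_csv(outdir / "group_comparison.tsv", sep="\t")
        strat_report["n_genes_significant_raw"] = int(
            (cmp_res.table["p_raw"] < 0.05).sum()
        )
        resp = dataset.clinical.table["response"]
        tab = pd.crosstab(subtypes.labels[two_groups], resp[two_groups])
        if tab.shape == (2, 2) and (tab.to_numpy().sum(axis=1) > 0).all():
            try:
                chi2, df, p = chi_square_2xk(tab.to_numpy())
                strat_report["response_association"] = {
                    "chi2": chi2, "df": df, "p": p,
                    "table": tab.to_dict(),
                }
            except ValueError:
                pass
    report["stages"]["stratification"] = strat_report

    # stage 4: prognostic models
    models_report = {}
    risk_report = {}
    importance_report = {}
    for outcome in config.outcomes:
        tbl, preds = compare_models(
            dataset, outcome=outcome, penalty=config.penalty,
            variable_sets=config.variable_sets, n_lambda=config.n_lambda,
        )
        tbl.to_csv(outdir / f"models_{outcome.lower()}.tsv", sep="\t", index=False)
        models_report[outcome] = tbl.to_dict(orient="records")

        # importance + risk groups for the richest model evaluated
        best_vs = config.variable_sets[-1]
        X, names = design_matrix(dataset, best_vs)
        path = select_lambda_loocv(
            X, dataset.clinical.outcome(outcome), penalty=config.penalty,
            n_lambda=config.n_lambda or 100,
        )
        fit = cox_penalized(
            X, dataset.clinical.outcome(outcome), penalty=config.penalty,
            lambda_=path.chosen_lambda, variables=names,
        )
        imp = importance_s36(fit)
        imp.to_csv(outdir / f"importance_{outcome.lower()}.tsv", sep="\t", index=False)
        importance_report[outcome] = {
            "model": best_vs,
            "lambda": path.chosen_lambda,
            "top10": imp.head(10)["variable"].tolist(),
        }
        strat = risk_groups_km(preds[best_vs].eta, dataset.clinical.outcome(outcome))
        for g, curve in strat.km_curves.items():
            curve.to_csv(outdir / f"km_{outcome.lower()}_{g}.tsv", sep="\t", index=False)
        risk_report[outcome] = {
            "model": best_vs,
            "thresholds": list(strat.thresholds),
            "group_sizes": strat.groups.value_counts().to_dict(),
            "logrank_chi2": strat.logrank_chi2,
            "logrank_df": strat.logrank_df,
            "logrank_p": strat.logrank_p,
        }
    report["stages"]["models"] = models_report
    report["stages"]["importance"] = importance_report
    report["stages"]["risk_groups"] = risk_report

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    logger.info("report written to %s", outdir / "report.json")
    return report


def _config_json(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = config.synthetic.to_json()
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
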