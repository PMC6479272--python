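"""qPCR preprocessing: relative quantification and imputation.

Relative expression follows the comparative-Ct scheme: each gene's Ct is
normalized within a sample to the arithmetic mean of the housekeeping-gene
Cts (equivalently, the geometric mean of the housekeeping quantities on the
linear scale) and expressed relative to a calibrator sample,

    R(g, s) = 2 ** -(dCt(g, s) - dCt(g, calibrator)),
    dCt(g, s) = Ct(g, s) - mean_h Ct(h, s).

Amplification efficiency is fixed at 2 per cycle.  Downstream analysis works
on log2(R).  Missing log2 values are completed by chained equations with
predictive mean matching.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import CtTable, ExpressionMatrix

__all__ = ["normalize_qpcr", "log2_transform", "impute_chained"]


def normalize_qpcr(ct: CtTable) -> ExpressionMatrix:
    """Comparative-Ct relative quantification against a calibrator sample.

    Housekeeping columns are dropped from the output.  A sample with any
    missing housekeeping Ct has no defined normalization for any gene; its
    row is emitted as missing with a warning.  A missing calibrator Ct is an
    error naming the gene.
    """
    targets = ct.target_genes
    if not targets:
        raise ValueError("Ct table has no target genes beyond the housekeeping set")
    hkg = ct.ct.loc[:, list(ct.hkg_genes)].astype(float)
    target_ct = ct.ct.loc[:, targets].astype(float)

    cal_targets = target_ct.loc[ct.calibrator_id]
    missing_cal = cal_targets.index[cal_targets.isna()].tolist()
    if hkg.loc[ct.calibrator_id].isna().any():
        missing_cal += hkg.columns[hkg.loc[ct.calibrator_id].isna()].tolist()
    if missing_cal:
        raise ValueError(f"calibrator sample misses Ct values for: {missing_cal}")

    hkg_mean = hkg.mean(axis=1, skipna=False)  # arithmetic mean on Ct scale
    no_hkg = hkg_mean.isna()
    if no_hkg.any():
        warnings.warn(
            f"{int(no_hkg.sum())} sample(s) lack a complete housekeeping set; "
            "their relative expression is undefined and emitted as missing "
            f"(first: {hkg_mean.index[no_hkg][0]!r})",
            stacklevel=2,
        )

    dct = target_ct.sub(hkg_mean, axis=0)
    ddct = dct.sub(dct.loc[ct.calibrator_id], axis=1)
    rel = np.exp2(-ddct)
    return ExpressionMatrix(values=rel, scale="linear")


def log2_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a linear-scale matrix; missing cells preserved."""
    if expr.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    arr = expr.values.to_numpy(dtype=float)
    bad = np.argwhere(np.nan_to_num(arr, nan=1.0) <= 0)
    if bad.size:
        cells = [
            (expr.values.index[i], expr.values.columns[j]) for i, j in bad[:10]
        ]
        raise ValueError(f"non-positive expression values at {cells}")
    return ExpressionMatrix(values=np.log2(expr.values), scale="log2")


def impute_chained(
    expr: ExpressionMatrix,
    n_cycles: int = 10,
    seed: int = 1,
    k_donors: int = 5,
) -> ExpressionMatrix:
    """Single imputation by chained equations with predictive mean matching.

    Missing cells are initialized with column means.  Then, for ``n_cycles``
    sweeps, each column with missingness is regressed (least squares) on all
    other columns using its observed rows, and each missing entry is
    replaced by the observed value of one of the ``k_donors`` donors whose
    predicted values lie nearest to the missing entry's prediction (the
    donor is chosen at random, deterministically given ``seed``).  Observed
    cells are never modified; the returned matrix has no missing cells.
    """
    if expr.scale != "log2":
        raise ValueError("impute_chained expects a log2-scale matrix")
    values = expr.values.to_numpy(dtype=float).copy()
    n, p = values.shape
    miss = np.isnan(values)
    if not miss.any():
        return ExpressionMatrix(values=expr.values.copy(), scale="log2")
    frac = miss.mean(axis=0)
    if (frac >= 0.5).any():
        worst = expr.values.columns[int(np.argmax(frac))]
        raise ValueError(
            f"column {worst!r} has {frac.max():.0%} missing; imputation "
            "requires < 50% missingness per column"
        )
    if (frac == 1.0).any():
        raise ValueError("a column is entirely missing")

    rng = np.random.default_rng(seed)
    col_means = np.nanmean(values, axis=0)
    filled = values.copy()
    for j in range(p):
        filled[miss[:, j], j] = col_means[j]

    order = [j for j in range(p) if miss[:, j].any()]
    for _ in range(n_cycles):
        for j in order:
            obs = ~miss[:, j]
            mis = miss[:, j]
            X = np.delete(filled, j, axis=1)
            Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
            Xm = np.column_stack([np.ones(mis.sum()), X[mis]])
            beta, *_ = np.linalg.lstsq(Xo, values[obs, j], rcond=None)
            pred_obs = Xo @ beta
            pred_mis = Xm @ beta
            # predictive mean matching against the k nearest observed donors
            dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
            k = min(k_donors, obs.sum())
            donor_pool = np.argpartition(dist, k - 1, axis=1)[:, :k]
            pick = rng.integers(0, k, size=mis.sum())
            donors = donor_pool[np.arange(mis.sum()), pick]
            filled[mis, j] = values[obs, j][donors]

    out = pd.DataFrame(filled, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values=out, scale="log2")
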