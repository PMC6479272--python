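"""Model validation: nested cross-validated predictors and their metrics.

The validation protocol wraps an outer leave-one-out (LOO) loop around the
entire model-development process: for each held-out patient the remaining
data are standardized, the penalty weight is chosen by inner LOO
cross-validated partial deviance, the penalized Cox model is fitted, and
the held-out patient's linear predictor is computed from that model.  Every
performance measure -- Harrell's c-index, the Schemper-Henderson proportion
of explained variation (PEV), the global p-value and the added-value test --
is then computed from these cross-validated predictors only, never from a
model refitted on the full data.  This guards against attributing predictive
value to uninformative gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .cox import (
    cox_univariate,
    lambda_grid,
    logistic_penalized,
    standardize,
    _sorted_arrays,
)
from .data import CohortDataset, SurvivalOutcome

__all__ = [
    "ModelSpec",
    "VARIABLE_SETS",
    "CVPredictions",
    "PerformanceReport",
    "RiskStratification",
    "loocv_predictors",
    "c_index",
    "pev",
    "global_p",
    "added_value_test",
    "risk_groups_km",
    "repeated_kfold_response",
    "evaluate_model",
    "compare_models",
]

#: The seven variable sets: clinical covariates, the two gene categories,
#: and all their combinations.
VARIABLE_SETS: tuple[str, ...] = (
    "clinics",
    "sphingo",
    "immune",
    "sphingo+immune",
    "clinics+sphingo",
    "clinics+immune",
    "clinics+sphingo+immune",
)


@dataclass(frozen=True)
class ModelSpec:
    variable_set: str = "clinics+sphingo+immune"
    penalty: str = "ridge"
    outcome: str = "OS"

    def __post_init__(self) -> None:
        if self.variable_set not in VARIABLE_SETS:
            raise ValueError(f"variable_set must be one of {VARIABLE_SETS}")
        if self.penalty not in ("ridge", "lasso"):
            raise ValueError("penalty must be 'ridge' or 'lasso'")
        if self.outcome.upper() not in ("OS", "PFS", "RESPONSE"):
            raise ValueError("outcome must be OS, PFS or response")


def design_matrix(dataset: CohortDataset, variable_set: str) -> tuple[np.ndarray, list[str]]:
    """Covariate matrix and names for one of the seven variable sets."""
    parts = variable_set.split("+")
    names: list[str] = []
    cols: list[np.ndarray] = []
    for part in parts:
        if part == "clinics":
            cov = dataset.clinical.covariates()
            names += list(cov.columns)
            cols += [cov[c].to_numpy(dtype=float) for c in cov.columns]
        elif part == "sphingo":
            genes = [g for g in dataset.signature.sphingo_lpa
                     if g in dataset.expression.values.columns]
            names += genes
            cols += [dataset.expression.values[g].to_numpy(dtype=float) for g in genes]
        elif part == "immune":
            genes = [g for g in dataset.signature.immune
                     if g in dataset.expression.values.columns]
            names += genes
            cols += [dataset.expression.values[g].to_numpy(dtype=float) for g in genes]
        else:
            raise ValueError(f"unknown variable set component {part!r}")
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute first")
    return X, names


@dataclass
class CVPredictions:
    """Per-sample cross-validated linear predictors from the outer LOO loop."""

    eta: pd.Series
    spec: ModelSpec
    fold_scheme: str = "loo"
    chosen_lambdas: np.ndarray | None = None
    n_fold_failures: int = 0


def loocv_predictors(
    dataset: CohortDataset,
    spec: ModelSpec,
    n_lambda: int | None = None,
    tol: float = 1e-5,
) -> CVPredictions:
    """Outer-LOO cross-validated linear predictors.

    For each patient i: drop i, standardize the remaining data, select the
    penalty by inner LOO cross-validated partial deviance, fit, and compute
    eta_i for the held-out patient on the training-fold standardization.
    Deterministic given the data.
    """
    from .cox import N_LAMBDA

    nlam = n_lambda or N_LAMBDA
    X, names = design_matrix(dataset, spec.variable_set)
    outcome = dataset.clinical.outcome(spec.outcome)
    n = outcome.n
    if n < 20:
        raise ValueError("outer LOO validation needs n >= 20")
    if outcome.n_events < 10:
        raise ValueError("outer LOO validation needs >= 10 events")

    order, ts, Xs_raw, _, delta, first, last = _sorted_arrays(outcome, X)
    pos_of = np.empty(n, dtype=int)
    pos_of[order] = np.arange(n)

    eta = np.zeros(n)
    lams = np.zeros(n)
    failures = 0
    l1 = spec.penalty == "lasso"
    for i in range(n):
        w = np.ones(n)
        w[pos_of[i]] = 0.0
        train = np.ones(n, dtype=bool)
        train[i] = False
        center = X[train].mean(axis=0)
        scale = X[train].std(axis=0, ddof=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        Xs = np.ascontiguousarray((Xs_raw - center) / scale)
        XsT = np.ascontiguousarray(Xs.T)
        try:
            lam_max = _engine.null_score_max(Xs, XsT, delta, w, first, last)
            grid = lambda_grid(lam_max, spec.penalty, n_lambda=nlam)
            dev = _engine.cv_deviance_loo(
                Xs, XsT, delta, w, first, last, grid, l1, tol, 100
            )
            lam = float(grid[int(np.argmin(dev))])
            if l1:
                beta, _, conv = _engine.cox_lasso_cd(
                    Xs, delta, w, first, last, lam, np.zeros(X.shape[1]), 1e-7, 200
                )
            else:
                beta, _, conv, _ = _engine.newton_ridge(
                    Xs, XsT, delta, w, first, last, lam, np.zeros(X.shape[1]), 1e-7, 200
                )
            if not conv:
                raise FloatingPointError("fold fit did not converge")
            eta[i] = float((X[i] - center) / scale @ beta)
            lams[i] = lam
        except (FloatingPointError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures += 1
            eta[i] = 0.0  # training-mean linear predictor
            lams[i] = np.nan
            warnings.warn(f"outer fold {i} failed ({exc}); using training mean",
                          stacklevel=2)
    return CVPredictions(
        eta=pd.Series(eta, index=dataset.sample_ids, name="cv_linear_predictor"),
        spec=spec,
        chosen_lambdas=lams,
        n_fold_failures=failures,
    )


def c_index(eta: np.ndarray, outcome: SurvivalOutcome) -> float:
    """Harrell's concordance over usable pairs.

    A pair is usable when the shorter observed time ends in an event (ties
    between two events are unusable; an event tied with a censoring time is
    compared, the censored subject having survived at least as long).  Tied
    predictions count 1/2.
    """
    eta = np.asarray(eta, dtype=float)
    t, e = outcome.time, outcome.event
    # pair (i, j): t_i < t_j, e_i = 1   or   t_i == t_j, e_i = 1, e_j = 0
    ti = t[:, None]
    tj = t[None, :]
    usable = ((ti < tj) | ((ti == tj) & (outcome.event[None, :] == 0))) & (e[:, None] == 1)
    np.fill_diagonal(usable, False)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    di = eta[:, None] - eta[None, :]
    concordant = (di > 0) & usable
    tied = (di == 0) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def _km_curve(time: np.ndarray, event: np.ndarray):
    """Product-limit estimate; returns (distinct event times, S(t) steps)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return uniq, np.array(surv)


def _step_eval(times: np.ndarray, values: np.ndarray, t: float, start: float = 1.0) -> float:
    idx = np.searchsorted(times, t, side="right") - 1
    return float(values[idx]) if idx >= 0 else start


@dataclass
class _SurvCurves:
    """Per-subject survival curves S(t | eta_i) over the event-time grid."""

    times: np.ndarray  # distinct event times
    surv: np.ndarray  # (n_subjects, n_times)


def _cox_subject_curves(eta: np.ndarray, outcome: SurvivalOutcome) -> _SurvCurves:
    """Cox model with eta as single covariate; Breslow baseline."""
    _, ts, Xs, XsT, delta, first, last = _sorted_arrays(outcome, eta[:, None])
    Xstd, center, scale = standardize(eta[:, None])
    _, _, Xss, XssT, _, _, _ = _sorted_arrays(outcome, Xstd)
    w = np.ones(outcome.n)
    beta, _, conv, _ = _engine.newton_ridge(
        Xss, XssT, delta, w, first, last, 0.0, np.zeros(1), 1e-9, 100
    )
    idx, h0 = _engine.breslow_cumhaz(Xss, delta, w, first, last, beta)
    ev_times = ts[idx]
    risk = np.exp((eta - center[0]) / scale[0] * beta[0])
    surv = np.exp(-np.outer(risk, h0))
    return _SurvCurves(times=ev_times, surv=surv)


def _km_subject_curves(outcome: SurvivalOutcome) -> _SurvCurves:
    t_ev, s_km = _km_curve(outcome.time, outcome.event)
    surv = np.tile(s_km, (outcome.n, 1))
    return _SurvCurves(times=t_ev, surv=surv)


def _mean_abs_error(curves: _SurvCurves, outcome: SurvivalOutcome) -> np.ndarray:
    """Schemper-Henderson mean absolute prediction error D(t_j) per event
    time: per subject 1-S(t) if known alive at t, S(t) if dead by t, and the
    censoring-conditional mixture if censored before t."""
    t_ev = curves.times
    n = outcome.n
    errs = np.zeros(t_ev.size)
    for j, tj in enumerate(t_ev):
        s_t = curves.surv[:, j]
        m = np.empty(n)
        alive = outcome.time > tj
        m[alive] = 1.0 - s_t[alive]
        dead = (outcome.time <= tj) & (outcome.event == 1)
        m[dead] = s_t[dead]
        cens = (outcome.time <= tj) & (outcome.event == 0)
        if cens.any():
            idxs = np.flatnonzero(cens)
            for i in idxs:
                s_ci = _step_eval(t_ev, curves.surv[i], outcome.time[i])
                ratio = s_t[i] / s_ci if s_ci > 0 else 0.0
                ratio = min(ratio, 1.0)
                m[i] = ratio * (1.0 - s_t[i]) + (1.0 - ratio) * s_t[i]
        errs[j] = m.mean()
    return errs


def pev(eta: np.ndarray, outcome: SurvivalOutcome) -> float:
    """Schemper-Henderson proportion of explained variation.

    V = (D - D_x) / D, where D is the time-averaged absolute prediction
    error of the marginal Kaplan-Meier and D_x that of the Cox model on
    ``eta`` as single covariate.  Event times are weighted by the number of
    events over the Kaplan-Meier estimate of the censoring distribution.
    Negative estimates (a predictor worse than the marginal) are truncated
    to 0.
    """
    eta = np.asarray(eta, dtype=float)
    if outcome.n_events < 5:
        raise ValueError("PEV needs at least 5 events")
    km = _km_subject_curves(outcome)
    t_ev = km.times
    d_j = np.array([np.sum((outcome.time == u) & (outcome.event == 1)) for u in t_ev])
    # censoring-distribution KM (left-continuous at t)
    tc, sc = _km_curve(outcome.time, 1 - outcome.event)
    g_minus = np.array([
        _step_eval(tc, sc, tj - 1e-12) if tc.size else 1.0 for tj in t_ev
    ])
    g_minus = np.where(g_minus <= 0, np.nan, g_minus)
    wts = d_j / g_minus
    wts = np.where(np.isnan(wts), 0.0, wts)
    if wts.sum() <= 0:
        raise ValueError("degenerate censoring weights")

    d_marg = _mean_abs_error(km, outcome)
    if np.ptp(eta) == 0:
        return 0.0  # constant predictor: the model curve is the marginal
    cox = _cox_subject_curves(eta, outcome)
    d_model = _mean_abs_error(cox, outcome)
    D = float((wts * d_marg).sum() / wts.sum())
    Dx = float((wts * d_model).sum() / wts.sum())
    v = (D - Dx) / D
    return float(max(v, 0.0))


def global_p(eta: np.ndarray, outcome: SurvivalOutcome) -> float:
    """Two-sided Wald p of a univariate Cox fit on the cross-validated
    predictor as single covariate; constant predictors give p = 1."""
    eta = np.asarray(eta, dtype=float)
    if np.ptp(eta) == 0:
        warnings.warn("constant predictor: global p set to 1", stacklevel=2)
        return 1.0
    res = cox_univariate(eta, outcome)
    return res.p if res.converged else 1.0


def added_value_test(
    eta_clinical: np.ndarray, eta_omics: np.ndarray, outcome: SurvivalOutcome
) -> float:
    """Likelihood-ratio test of the gene-derived predictor in a bivariable
    Cox model over the clinical predictor alone (both cross-validated).

    Near-collinear predictors (|r| > 0.999) fall back to the Wald test with
    a warning.
    """
    e1 = np.asarray(eta_clinical, dtype=float)
    e2 = np.asarray(eta_omics, dtype=float)
    if np.ptp(e2) == 0:
        return 1.0
    X2 = np.column_stack([e1, e2])
    Xstd, _, _ = standardize(X2)
    _, _, Xs, XsT, delta, first, last = _sorted_arrays(outcome, Xstd)
    w = np.ones(outcome.n)
    collinear = np.ptp(e1) > 0 and abs(np.corrcoef(e1, e2)[0, 1]) > 0.999
    beta2, _, conv2, _ = _engine.newton_ridge(
        Xs, XsT, delta, w, first, last, 0.0, np.zeros(2), 1e-9, 100
    )
    if collinear or not conv2:
        warnings.warn(
            "clinical and omics predictors nearly collinear; Wald fallback",
            stacklevel=2,
        )
        grad = np.zeros(2)
        hess = np.zeros((2, 2))
        _engine._loglik_grad_hess(Xs, XsT, delta, w, first, last, beta2, grad, hess)
        # a (near-)singular information matrix correctly blows up the
        # variance, so an exact duplicate yields p ~ 1
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.inv(hess + 1e-12 * np.eye(2))
        se = np.sqrt(max(cov[1, 1], 1e-300))
        z = beta2[1] / se
        return float(2.0 * stats.norm.sf(abs(z)))
    l2 = _engine.cox_loglik(Xs, delta, w, first, last, beta2)
    if np.ptp(e1) == 0:
        l1 = _engine.cox_loglik(Xs, delta, w, first, last, np.zeros(2))
    else:
        beta1, _, _, _ = _engine.newton_ridge(
            np.ascontiguousarray(Xs[:, :1]),
            np.ascontiguousarray(Xs[:, :1].T),
            delta, w, first, last, 0.0, np.zeros(1), 1e-9, 100,
        )
        l1 = _engine.cox_loglik(
            np.ascontiguousarray(Xs[:, :1]), delta, w, first, last, beta1
        )
    lr = max(2.0 * (l2 - l1), 0.0)
    return float(stats.chi2.sf(lr, df=1))


@dataclass
class RiskStratification:
    """Quartile risk groups of the cross-validated predictor with KM curves."""

    thresholds: tuple[float, float]  # (Q1, Q3)
    groups: pd.Series  # 'low' / 'intermediate' / 'high'
    km_curves: dict  # group -> DataFrame(time, survival)
    logrank_chi2: float
    logrank_df: int
    logrank_p: float


def risk_groups_km(eta: pd.Series | np.ndarray, outcome: SurvivalOutcome) -> RiskStratification:
    """Stratify by the quartiles of eta (linear-interpolation quantiles):
    low risk below Q1, high risk above Q3, intermediate otherwise
    (boundary values are intermediate); Kaplan-Meier per group and the
    k-group log-rank test."""
    from lifelines.statistics import multivariate_logrank_test

    if isinstance(eta, pd.Series):
        index = eta.index
        vals = eta.to_numpy(dtype=float)
    else:
        vals = np.asarray(eta, dtype=float)
        index = pd.RangeIndex(vals.size)
    if vals.size < 8:
        raise ValueError("risk stratification needs n >= 8")
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation (type 7)
    labels = np.where(vals < q1, "low", np.where(vals > q3, "high", "intermediate"))
    groups = pd.Series(labels, index=index, name="risk_group")

    km_curves = {}
    for g in ("low", "intermediate", "high"):
        sel = labels == g
        if sel.sum() == 0:
            warnings.warn(f"risk group {g!r} is empty", stacklevel=2)
            continue
        tt, ss = _km_curve(outcome.time[sel], outcome.event[sel])
        km_curves[g] = pd.DataFrame({"time": tt, "survival": ss})

    present = [g for g in ("low", "intermediate", "high") if (labels == g).any()]
    res = multivariate_logrank_test(outcome.time, labels, outcome.event)
    return RiskStratification(
        thresholds=(float(q1), float(q3)),
        groups=groups,
        km_curves=km_curves,
        logrank_chi2=float(res.test_statistic),
        logrank_df=len(present) - 1,
        logrank_p=float(res.p_value),
    )


@dataclass
class PerformanceReport:
    """Cross-validated performance of one model specification."""

    spec: ModelSpec
    pev: float
    c_index: float
    global_p: float
    added_value_p: float | None
    n: int
    n_events: int
    n_fold_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "variable_set": self.spec.variable_set,
            "penalty": self.spec.penalty,
            "outcome": self.spec.outcome,
            "pev_percent": round(100.0 * self.pev, 2),
            "c_index": round(self.c_index, 3),
            "global_p": self.global_p,
            "added_value_p": self.added_value_p,
            "n": self.n,
            "n_events": self.n_events,
        }


def evaluate_model(
    dataset: CohortDataset,
    spec: ModelSpec,
    eta_clinical: pd.Series | None = None,
    n_lambda: int | None = None,
) -> tuple[PerformanceReport, CVPredictions]:
    """Full validation of one spec: outer-LOO predictors, then PEV, c-index
    and global p; the added-value test against ``eta_clinical`` when the
    spec includes gene variables and a clinical predictor is supplied."""
    cvp = loocv_predictors(dataset, spec, n_lambda=n_lambda)
    outcome = dataset.clinical.outcome(spec.outcome)
    eta = cvp.eta.to_numpy()
    report = PerformanceReport(
        spec=spec,
        pev=pev(eta, outcome),
        c_index=c_index(eta, outcome),
        global_p=global_p(eta, outcome),
        added_value_p=(
            added_value_test(eta_clinical.to_numpy(), eta, outcome)
            if eta_clinical is not None and spec.variable_set != "clinics"
            else None
        ),
        n=outcome.n,
        n_events=outcome.n_events,
        n_fold_failures=cvp.n_fold_failures,
    )
    return report, cvp


def compare_models(
    dataset: CohortDataset,
    outcome: str = "OS",
    penalty: str = "ridge",
    variable_sets: tuple[str, ...] = VARIABLE_SETS,
    n_lambda: int | None = None,
) -> tuple[pd.DataFrame, dict[str, CVPredictions]]:
    """Evaluate every variable set; gene-containing models also get the
    added-value test on top of the clinical predictor."""
    eta_clin = None
    reports = []
    predictions: dict[str, CVPredictions] = {}
    sets = list(variable_sets)
    if "clinics" in sets:  # evaluate first to have the clinical predictor
        sets.remove("clinics")
        sets.insert(0, "clinics")
    for vs in sets:
        spec = ModelSpec(variable_set=vs, penalty=penalty, outcome=outcome)
        rep, cvp = evaluate_model(
            dataset, spec, eta_clinical=eta_clin, n_lambda=n_lambda
        )
        if vs == "clinics":
            eta_clin = cvp.eta
        reports.append(rep.to_dict())
        predictions[vs] = cvp
    return pd.DataFrame(reports), predictions


@dataclass
class ResponseCVReport:
    """Repeated stratified k-fold validation of a response model."""

    spec: ModelSpec
    auc_mean: float
    auc_sd: float
    deviance_mean: float
    deviance_sd: float
    auc_per_repeat: np.ndarray
    added_auc_mean: float | None = None
    added_auc_sd: float | None = None


def repeated_kfold_response(
    dataset: CohortDataset,
    spec: ModelSpec,
    k: int = 5,
    repeats: int = 40,
    seed: int = 0,
    compare_clinics: bool = False,
    n_lambda: int | None = None,
) -> ResponseCVReport:
    """Repeated stratified k-fold CV of the penalized logistic response
    model; per-repeat out-of-fold AUC and binomial deviance, summarized as
    mean +/- SD across repeats.  With ``compare_clinics`` the AUC difference
    to the clinics-only model is reported analogously."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    from .cox import N_LAMBDA

    nlam = n_lambda or N_LAMBDA
    X, names = design_matrix(dataset, spec.variable_set)
    y = dataset.clinical.table["response"].to_numpy(dtype=float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        X, y = X[keep], y[keep]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < k:
        raise ValueError("both response classes must have at least k members")
    Xc = design_matrix(dataset, "clinics")[0] if compare_clinics else None
    if Xc is not None and Xc.shape[0] != y.size:
        Xc = Xc[~np.isnan(dataset.clinical.table["response"].to_numpy(dtype=float))]

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]
    aucs, devs, added = [], [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seeds[r])
        prob = np.zeros(y.size)
        prob_c = np.zeros(y.size)
        for tr, te in skf.split(X, y):
            w = np.zeros(y.size)
            w[tr] = 1.0
            fit = logistic_penalized(
                X, y, penalty=spec.penalty, weights=w, n_lambda=nlam
            )
            prob[te] = fit.predict_proba(X[te])
            if Xc is not None:
                fit_c = logistic_penalized(
                    Xc, y, penalty=spec.penalty, weights=w, n_lambda=nlam
                )
                prob_c[te] = fit_c.predict_proba(Xc[te])
        aucs.append(roc_auc_score(y, prob))
        p_clip = np.clip(prob, 1e-12, 1 - 1e-12)
        devs.append(float(-2 * np.mean(y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip))))
        if Xc is not None:
            added.append(aucs[-1] - roc_auc_score(y, prob_c))
    aucs = np.array(aucs)
    devs = np.array(devs)
    return ResponseCVReport(
        spec=spec,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if repeats > 1 else 0.0,
        deviance_mean=float(devs.mean()),
        deviance_sd=float(devs.std(ddof=1)) if repeats > 1 else 0.0,
        auc_per_repeat=aucs,
        added_auc_mean=float(np.mean(added)) if added else None,
        added_auc_sd=float(np.std(added, ddof=1)) if len(added) > 1 else None,
    )
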