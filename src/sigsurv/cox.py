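"""Survival and logistic model engines.

Univariate Cox regression, ridge/LASSO-penalized Cox and logistic models
with leave-one-out cross-validated penalty selection (Verweij-van
Houwelingen partial deviance for the Cox case), Breslow baseline hazards,
and the 36-month survival-probability importance transform.

Ties are handled with the Breslow approximation throughout (Efron is
available behind a flag on :func:`cox_univariate`).  Penalized fits
standardize covariates internally to zero mean and unit population SD;
coefficients are reported both per original unit (``beta``) and per SD
(``beta_std``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .data import SurvivalOutcome

__all__ = [
    "UnivariateCoxResult",
    "CoxFit",
    "LambdaPath",
    "LogisticFit",
    "cox_univariate",
    "cox_penalized",
    "select_lambda_loocv",
    "logistic_penalized",
    "importance_s36",
]

PENALTIES = ("none", "ridge", "lasso")

#: lambda-grid defaults: 100 log-spaced points spanning 4 decades below the
#: all-zero bound, with the ridge grid shifted up three decades.
N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4
RIDGE_GRID_FACTOR = 1000.0


def _sorted_arrays(outcome: SurvivalOutcome, X: np.ndarray):
    """Sort by ascending time; build tie-group index arrays."""
    time = outcome.time
    order = np.argsort(time, kind="stable")
    ts = time[order]
    Xs = np.ascontiguousarray(X[order], dtype=np.float64)
    delta = outcome.event[order].astype(np.float64)
    n = ts.size
    first = np.zeros(n, dtype=np.int64)
    last = np.zeros(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        first[i : j + 1] = i
        last[i : j + 1] = j
        i = j + 1
    XsT = np.ascontiguousarray(Xs.T)
    return order, ts, Xs, XsT, delta, first, last


def standardize(X: np.ndarray, weights: np.ndarray | None = None):
    """Column-wise centering and scaling by the population SD (1/n).

    Constant columns get scale 1 (their coefficient is then 0 under any
    penalty).  With ``weights``, moments use only the weighted rows."""
    X = np.asarray(X, dtype=np.float64)
    if weights is None:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
    else:
        w = weights / weights.sum()
        center = w @ X
        scale = np.sqrt(w @ (X - center) ** 2)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return (X - center) / scale, center, scale


def lambda_grid(lam_max: float, penalty: str, n_lambda: int = N_LAMBDA,
                min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    """Descending log-spaced grid anchored at the all-zero lasso bound."""
    lam_max = max(lam_max, 1e-8)
    if penalty == "ridge":
        lam_max = lam_max * RIDGE_GRID_FACTOR
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


@dataclass
class UnivariateCoxResult:
    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p: float
    converged: bool
    n: int
    n_events: int


def cox_univariate(
    x: np.ndarray, outcome: SurvivalOutcome, ties: str = "breslow"
) -> UnivariateCoxResult:
    """Univariate Cox regression: HR, Wald 95% CI and two-sided Wald p.

    Uses Newton-Raphson on the Breslow-ties partial likelihood.  A monotone
    likelihood (perfect separation) is flagged as non-convergence; no
    estimate is reported silently (HR and p come back NaN).
    """
    x = np.asarray(x, dtype=np.float64)
    if outcome.n_events < 2:
        raise ValueError("univariate Cox needs at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if ties == "efron":
        # delegate the Efron variant; our own engine is Breslow-only
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"x": x, "T": outcome.time, "E": outcome.event})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
    else:
        _, _, Xs, XsT, delta, first, last = _sorted_arrays(outcome, x[:, None])
        w = np.ones(Xs.shape[0])
        beta_v, n_iter, converged, _ = _engine.newton_ridge(
            Xs, XsT, delta, w, first, last, 0.0, np.zeros(1), 1e-9, 100
        )
        beta = float(beta_v[0])
        grad = np.zeros(1)
        hess = np.zeros((1, 1))
        _engine._loglik_grad_hess(Xs, XsT, delta, w, first, last, beta_v, grad, hess)
        if not converged or hess[0, 0] <= 0 or abs(beta) * (np.std(x) or 1.0) > 15:
            warnings.warn(
                "univariate Cox did not converge (monotone likelihood?)",
                stacklevel=2,
            )
            return UnivariateCoxResult(
                beta=np.nan, se=np.nan, hr=np.nan, ci95=(np.nan, np.nan),
                p=np.nan, converged=False, n=outcome.n, n_events=outcome.n_events,
            )
        se = float(np.sqrt(1.0 / hess[0, 0]))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return UnivariateCoxResult(
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.959963984540054 * se)),
              float(np.exp(beta + 1.959963984540054 * se))),
        p=float(p),
        converged=True,
        n=outcome.n,
        n_events=outcome.n_events,
    )


@dataclass
class CoxFit:
    """A (penalized) multivariable Cox fit.

    ``beta`` is per original covariate unit; ``beta_std`` per population SD
    (the scale the penalty acts on).  ``baseline_times``/``baseline_cumhaz``
    give the Breslow cumulative hazard step function for the reference
    subject with every covariate at its sample mean.
    """

    variables: list[str]
    beta: np.ndarray
    beta_std: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    penalty: str
    lambda_: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def excluded(self) -> list[str]:
        """Variables dropped by the lasso (coefficient exactly zero)."""
        if self.penalty != "lasso":
            return []
        return [v for v, b in zip(self.variables, self.beta_std) if b == 0.0]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """eta for new covariate rows, on the training standardization."""
        Xc = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Xc @ self.beta_std

    def baseline_survival(self, t: float) -> float:
        """S0(t) = exp(-H0(t)) via the step-function convention (value at
        the last event time <= t)."""
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(np.exp(-self.baseline_cumhaz[idx]))


def cox_penalized(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    penalty: str = "ridge",
    lambda_: float = 0.0,
    variables: list[str] | None = None,
    tol: float = 1e-8,
    maxit: int = 200,
) -> CoxFit:
    """Penalized Cox fit at a fixed ``lambda_``.

    Maximizes ``l(beta) - lambda * P(beta)`` on the standardized scale with
    P the ridge (``sum(beta^2)/2``) or lasso (``sum|beta|``) penalty, via
    Newton-Raphson (ridge/none) or IRLS plus coordinate descent with soft
    thresholding (lasso).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != outcome.n:
        raise ValueError("X rows must match outcome length")
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if variables is None:
        variables = [f"x{j}" for j in range(X.shape[1])]
    Xstd, center, scale = standardize(X)
    _, ts, Xs, XsT, delta, first, last = _sorted_arrays(outcome, Xstd)
    w = np.ones(Xs.shape[0])
    if penalty == "lasso" and lambda_ > 0:
        beta_std, n_iter, converged = _engine.cox_lasso_cd(
            Xs, delta, w, first, last, lambda_, np.zeros(X.shape[1]), tol, maxit
        )
    else:
        lam = lambda_ if penalty == "ridge" else 0.0
        beta_std, n_iter, converged, _ = _engine.newton_ridge(
            Xs, XsT, delta, w, first, last, lam, np.zeros(X.shape[1]), tol, maxit
        )
    if not converged:
        warnings.warn("penalized Cox fit did not converge", stacklevel=2)
    loglik = float(_engine.cox_loglik(Xs, delta, w, first, last, beta_std))
    idx, h0 = _engine.breslow_cumhaz(Xs, delta, w, first, last, beta_std)
    return CoxFit(
        variables=list(variables),
        beta=beta_std / scale,
        beta_std=np.asarray(beta_std),
        center=center,
        scale=scale,
        penalty=penalty,
        lambda_=float(lambda_),
        baseline_times=ts[idx],
        baseline_cumhaz=np.asarray(h0),
        loglik=loglik,
        converged=bool(converged),
        n_iter=int(n_iter),
    )


@dataclass
class LambdaPath:
    """CV partial-deviance curve over a descending lambda grid."""

    grid: np.ndarray
    cv_deviance: np.ndarray
    penalty: str

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) < 0):
            raise ValueError("lambda grid must be strictly decreasing")

    @property
    def chosen_index(self) -> int:
        return int(np.argmin(self.cv_deviance))

    @property
    def chosen_lambda(self) -> float:
        return float(self.grid[self.chosen_index])


def select_lambda_loocv(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    penalty: str = "ridge",
    n_lambda: int = N_LAMBDA,
    tol: float = 1e-5,
    maxit: int = 100,
    weights: np.ndarray | None = None,
) -> LambdaPath:
    """Choose lambda by minimizing the leave-one-out cross-validated partial
    deviance (Verweij-van Houwelingen).

    ``weights`` (0/1) restricts the procedure to a training subset without
    re-sorting; used by the outer cross-validation loop.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if penalty not in ("ridge", "lasso"):
        raise ValueError("lambda selection applies to ridge or lasso penalties")
    w = np.ones(outcome.n) if weights is None else np.asarray(weights, dtype=float)
    n_active = int((w > 0).sum())
    n_ev = int(outcome.event[w > 0].sum())
    if n_active < 10:
        raise ValueError("need at least 10 subjects for LOO lambda selection")
    if n_ev < 5:
        raise ValueError("need at least 5 events for LOO lambda selection")
    Xstd, _, _ = standardize(X, weights=w)
    _, _, Xs, XsT, delta, first, last = _sorted_arrays(outcome, Xstd)
    order = np.argsort(outcome.time, kind="stable")
    ws = np.ascontiguousarray(w[order])
    lam_max = _engine.null_score_max(Xs, XsT, delta, ws, first, last)
    grid = lambda_grid(lam_max, penalty, n_lambda=n_lambda)
    dev = _engine.cv_deviance_loo(
        Xs, XsT, delta, ws, first, last, grid, penalty == "lasso", tol, maxit
    )
    if not np.all(np.isfinite(dev)):
        raise FloatingPointError("non-finite CV deviance encountered")
    return LambdaPath(grid=grid, cv_deviance=np.asarray(dev), penalty=penalty)


@dataclass
class LogisticFit:
    variables: list[str]
    beta: np.ndarray
    beta_std: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    penalty: str
    lambda_: float
    converged: bool

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.center) / self.scale
        eta = self.intercept + Xc @ self.beta_std
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def logistic_penalized(
    X: np.ndarray,
    y: np.ndarray,
    penalty: str = "ridge",
    lambda_: float | None = None,
    variables: list[str] | None = None,
    n_lambda: int = N_LAMBDA,
    tol: float = 1e-8,
    maxit: int = 200,
    weights: np.ndarray | None = None,
) -> LogisticFit:
    """Penalized logistic regression; lambda LOO-CV-selected when omitted.

    The intercept is never penalized; with an overwhelming penalty the fit
    collapses to the intercept-only model (predicted probability = class
    prevalence).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    yy = y[w > 0]
    if yy.min() == yy.max():
        raise ValueError("response has a single class")
    if variables is None:
        variables = [f"x{j}" for j in range(X.shape[1])]
    Xstd, center, scale = standardize(X, weights=w)
    Xc = np.ascontiguousarray(Xstd)
    if lambda_ is None:
        if penalty == "none":
            lambda_ = 0.0
        else:
            ybar = float(np.average(y, weights=w))
            lam_max = float(np.max(np.abs((w * (y - ybar)) @ Xc)))
            grid = lambda_grid(lam_max, penalty, n_lambda=n_lambda)
            dev = _engine.logistic_cv_deviance_loo(
                Xc, y, w, grid, penalty == "lasso", 1e-6, 100
            )
            lambda_ = float(grid[int(np.argmin(dev))])
    if penalty == "lasso" and lambda_ > 0:
        beta, b0, _, conv = _engine.logistic_lasso_cd(
            Xc, y, w, lambda_, np.zeros(X.shape[1]), 0.0, tol, maxit
        )
    else:
        lam = lambda_ if penalty == "ridge" else 0.0
        beta, b0, _, conv = _engine.logistic_ridge(
            Xc, y, w, lam, np.zeros(X.shape[1]), 0.0, tol, maxit
        )
    return LogisticFit(
        variables=list(variables),
        beta=np.asarray(beta) / scale,
        beta_std=np.asarray(beta),
        intercept=float(b0),
        center=center,
        scale=scale,
        penalty=penalty,
        lambda_=float(lambda_),
        converged=bool(conv),
    )


def importance_s36(fit: CoxFit, horizon: float = 36.0) -> pd.DataFrame:
    """Variable importance as the change in predicted survival at ``horizon``.

    S = S0(horizon) is the survival probability of the reference subject
    (all covariates at their sample means).  For variable j the importance
    is ``S ** exp(beta_std_j) - S``: the survival change for a subject one
    SD above the mean on that variable alone.  Ranking by |beta_std| and by
    |delta_s| coincide for a fixed S.
    """
    s_ref = fit.baseline_survival(horizon)
    if fit.baseline_times.size == 0 or fit.baseline_times[0] > horizon:
        warnings.warn(
            f"no events observed before horizon={horizon}; importances are 0",
            stacklevel=2,
        )
        s_ref = 1.0
    delta = s_ref ** np.exp(fit.beta_std) - s_ref
    tbl = pd.DataFrame(
        {
            "variable": fit.variables,
            "beta_std": fit.beta_std,
            "s_horizon_ref": s_ref,
            "delta_s": delta,
        }
    )
    tbl["rank"] = (
        tbl["beta_std"].abs().rank(ascending=False, method="first").astype(int)
    )
    return tbl.sort_values("rank").reset_index(drop=True)
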