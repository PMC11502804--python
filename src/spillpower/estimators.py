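"""Scikit-learn style estimators for the registered analysis plan.

Each estimator follows the usual conventions: hyperparameters in
``__init__`` (inherited ``get_params``/``set_params``), data only in
``fit``, fitted attributes with a trailing underscore.  The module-level
functions in :mod:`spillpower.estimation` are thin wrappers over these
classes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from . import _core
from .results import BootstrapSettings, CoefficientEstimate, SpilloverDecomposition

__all__ = [
    "LinearProbabilityModel",
    "ProbitRegression",
    "TwoStageLeastSquares",
    "RiversVuongProbit",
    "SpilloverDecomposer",
    "CollinearityError",
    "IdentificationError",
    "SeparationError",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


class IdentificationError(ValueError):
    """The first stage is numerically singular (weak-rank instruments)."""


class SeparationError(RuntimeError):
    """Probit likelihood unbounded due to perfect separation."""


def _as_matrix(X, fit_intercept: bool):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j}" for j in range(arr.shape[1])]
    if fit_intercept:
        arr = np.column_stack([np.ones(arr.shape[0]), arr])
        names = ["const"] + names
    return arr, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    offending = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            offending.append(names[j])
    raise CollinearityError(f"collinear design columns: {offending}")


def _wrap_statsmodels(res, names) -> list[CoefficientEstimate]:
    ci = res.conf_int()
    ci = ci.to_numpy() if hasattr(ci, "to_numpy") else np.asarray(ci)
    return [
        CoefficientEstimate(
            name=names[j],
            value=float(res.params[j]),
            robust_se=float(res.bse[j]),
            t_stat=float(res.tvalues[j]),
            p_two_sided=float(res.pvalues[j]),
            ci95=(float(ci[j, 0]), float(ci[j, 1])),
        )
        for j in range(len(names))
    ]


class LinearProbabilityModel(BaseEstimator):
    """OLS on a (typically binary) outcome with HC1-robust inference.

    Parameters
    ----------
    fit_intercept:
        Prepend a constant column.  Pass ``False`` when the design already
        contains one.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64)
        M, names = _as_matrix(X, self.fit_intercept)
        if M.shape[0] <= M.shape[1]:
            raise ValueError("need more observations than regressors")
        _check_full_rank(M, names)
        res = sm.OLS(y, M).fit(cov_type="HC1", use_t=False)
        self.feature_names_in_ = names
        self.results_ = _wrap_statsmodels(res, names)
        self.coef_ = np.asarray(res.params, dtype=np.float64)
        self.n_obs_ = M.shape[0]
        self._design_names = names
        return self

    def predict(self, X):
        M, _ = _as_matrix(X, self.fit_intercept)
        return M @ self.coef_


class ProbitRegression(BaseEstimator):
    """Maximum-likelihood probit fitted by Newton iterations."""

    def __init__(self, fit_intercept: bool = True, maxiter: int = 100):
        self.fit_intercept = fit_intercept
        self.maxiter = maxiter

    def fit(self, X, y):
        y = np.asarray(y, dtype=np.float64)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("probit outcome must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("probit outcome must contain both classes")
        M, names = _as_matrix(X, self.fit_intercept)
        _check_full_rank(M, names)
        try:
            res = sm.Probit(y, M).fit(method="newton", maxiter=self.maxiter, disp=0)
        except PerfectSeparationError as err:  # pragma: no cover - data dependent
            raise SeparationError(str(err)) from err
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(
                f"probit Newton iterations did not converge: {res.mle_retvals}"
            )
        self.feature_names_in_ = names
        self.results_ = _wrap_statsmodels(res, names)
        self.coef_ = np.asarray(res.params, dtype=np.float64)
        self.n_obs_ = M.shape[0]
        return self

    def predict_proba(self, X):
        from scipy.stats import norm

        M, _ = _as_matrix(X, self.fit_intercept)
        p1 = norm.cdf(M @ self.coef_)
        return np.column_stack([1 - p1, p1])


def _first_stage_wald_F(endog_col, Z, inst_idx) -> float:
    """HC1-robust Wald F of the excluded instruments in one first stage."""
    n, kz = Z.shape
    A = Z.T @ Z
    beta = np.linalg.solve(A, Z.T @ endog_col)
    e = endog_col - Z @ beta
    meat = (Z * (e**2)[:, None]).T @ Z
    cov = np.linalg.solve(A, np.linalg.solve(A, meat).T) * n / (n - kz)
    R = np.zeros((len(inst_idx), kz))
    for i, j in enumerate(inst_idx):
        R[i, j] = 1.0
    rb = R @ beta
    rvr = R @ cov @ R.T
    try:
        stat = rb @ np.linalg.solve(rvr, rb)
    except np.linalg.LinAlgError as err:
        raise IdentificationError("singular first-stage covariance") from err
    return float(stat / len(inst_idx))


class TwoStageLeastSquares(BaseEstimator):
    """Classical 2SLS with HC1-robust second-stage inference.

    ``X`` passed to :meth:`fit` must contain the endogenous regressors, the
    excluded instruments and any exogenous regressors as named columns; the
    instruments are excluded from the structural equation.  The robust
    covariance uses residuals computed at the *original* endogenous values,
    as required for consistent 2SLS standard errors.

    Parameters
    ----------
    endogenous:
        Column names of the endogenous regressors (one or two).
    instruments:
        Column names of the excluded instruments (at least as many).
    fit_intercept:
        Prepend a constant to the exogenous block.
    """

    def __init__(
        self,
        endogenous: Sequence[str] = ("PEB1",),
        instruments: Sequence[str] = ("IV",),
        fit_intercept: bool = True,
    ):
        self.endogenous = endogenous
        self.instruments = instruments
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named columns")
        y = np.asarray(y, dtype=np.float64)
        endo = list(self.endogenous)
        inst = list(self.instruments)
        if len(inst) < len(endo):
            raise IdentificationError(
                f"{len(endo)} endogenous regressors need >= {len(endo)} instruments"
            )
        exo = [c for c in X.columns if c not in endo + inst]
        n = len(X)
        ones = [np.ones(n)] if self.fit_intercept else []
        ones_names = ["const"] if self.fit_intercept else []
        Xs = np.column_stack(
            ones + [X[c].to_numpy(np.float64) for c in exo + endo]
        )
        x_names = ones_names + exo + endo
        Z = np.column_stack(
            ones + [X[c].to_numpy(np.float64) for c in exo + inst]
        )
        z_names = ones_names + exo + inst
        _check_full_rank(Z, z_names)
        _check_full_rank(Xs, x_names)

        # projection of the structural regressors on the instrument space
        coef_proj, *_ = np.linalg.lstsq(Z, Xs, rcond=None)
        Xhat = Z @ coef_proj
        A = Xhat.T @ Xhat
        if np.linalg.matrix_rank(A, tol=1e-10 * max(np.abs(A).max(), 1e-300)) < A.shape[0]:
            raise IdentificationError("projected design is numerically singular")
        theta = np.linalg.solve(A, Xhat.T @ y)
        e = y - Xs @ theta
        k = Xs.shape[1]
        meat = (Xhat * (e**2)[:, None]).T @ Xhat
        cov = np.linalg.solve(A, np.linalg.solve(A, meat).T) * n / (n - k)
        se = np.sqrt(np.diag(cov))

        self.feature_names_in_ = x_names
        self.results_ = [
            CoefficientEstimate.from_value_se(x_names[j], theta[j], se[j])
            for j in range(k)
        ]
        self.coef_ = theta
        self.n_obs_ = n
        inst_idx = [z_names.index(c) for c in inst]
        self.first_stage_F_ = tuple(
            _first_stage_wald_F(X[c].to_numpy(np.float64), Z, inst_idx) for c in endo
        )
        return self

    def estimate(self, name: str) -> CoefficientEstimate:
        return self.results_[self.feature_names_in_.index(name)]


class RiversVuongProbit(BaseEstimator):
    """Two-step control-function probit for a continuous endogenous regressor.

    Step 1 regresses the endogenous variable on instruments plus exogenous
    regressors by OLS; step 2 fits a probit of the outcome on the
    endogenous variable, the exogenous block and the first-stage residual.
    The z-test on the residual coefficient is the exogeneity diagnostic.
    """

    def __init__(
        self,
        endogenous: str = "PEB1",
        instruments: Sequence[str] = ("IV",),
        fit_intercept: bool = True,
    ):
        self.endogenous = endogenous
        self.instruments = instruments
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named columns")
        inst = list(self.instruments)
        exo = [c for c in X.columns if c != self.endogenous and c not in inst]
        n = len(X)
        ones = [np.ones(n)] if self.fit_intercept else []
        Z = np.column_stack(ones + [X[c].to_numpy(np.float64) for c in exo + inst])
        endog_col = X[self.endogenous].to_numpy(np.float64)
        beta1, *_ = np.linalg.lstsq(Z, endog_col, rcond=None)
        resid = endog_col - Z @ beta1

        names = (["const"] if self.fit_intercept else []) + exo + [
            self.endogenous,
            "first_stage_residual",
        ]
        M = np.column_stack(
            ones
            + [X[c].to_numpy(np.float64) for c in exo]
            + [endog_col, resid]
        )
        probit = ProbitRegression(fit_intercept=False).fit(M, y)
        self.feature_names_in_ = names
        self.results_ = [
            CoefficientEstimate(
                name=names[j],
                value=est.value,
                robust_se=est.robust_se,
                t_stat=est.t_stat,
                p_two_sided=est.p_two_sided,
                ci95=est.ci95,
            )
            for j, est in enumerate(probit.results_)
        ]
        self.coef_ = probit.coef_
        self.residual_test_ = self.results_[-1]
        self.n_obs_ = n
        return self


class SpilloverDecomposer(BaseEstimator):
    """Decompose a treatment's spillover into direct and indirect parts.

    Fits the three registered equations on a table with columns ``T``,
    ``IV``, ``PEB1``, ``PEB2`` (plus an optional exogenous block):

    - total effect ``tau``: OLS of PEB2 on T;
    - direct effect ``delta'`` and behavior effect ``beta'``: 2SLS of PEB2
      on instrumented PEB1 and T;
    - indirect effect: ``tau - delta'`` with a studentized bootstrap CI
      (``n_resamples`` resamples, stacked-sandwich inner SE).

    Parameters
    ----------
    n_resamples, level, seed:
        Bootstrap settings; the effect is significant iff the CI at
        ``level`` excludes zero.
    exog_cols:
        Names of extra exogenous columns entering every equation.
    """

    def __init__(
        self,
        n_resamples: int = 10_000,
        level: float = 0.95,
        seed: Optional[int] = None,
        exog_cols: Sequence[str] = (),
    ):
        self.n_resamples = n_resamples
        self.level = level
        self.seed = seed
        self.exog_cols = exog_cols

    def fit(self, df: pd.DataFrame, y=None):
        t = df["T"].to_numpy(np.float64)
        iv = df["IV"].to_numpy(np.float64)
        p1 = df["PEB1"].to_numpy(np.float64)
        p2 = df["PEB2"].to_numpy(np.float64)
        exog = (
            df[list(self.exog_cols)].to_numpy(np.float64)
            if len(self.exog_cols)
            else None
        )
        if len(np.unique(p1)) < 2:
            raise _core.DegenerateSampleError("PEB1 does not vary")
        point = _core.decompose_point(t, iv, p1, p2, exog=exog)
        theta_hat = point["tau"] - point["delta_prime"]
        se_hat = point["se_stacked"]

        rng = np.random.default_rng(self.seed)
        theta_star, se_star = _core.bootstrap_indirect(
            t, iv, p1, p2, self.n_resamples, rng, exog=exog
        )
        lo, hi = _studentized_interval(
            theta_hat, se_hat, theta_star, se_star, self.level
        )

        self.decomposition_ = SpilloverDecomposition(
            tau=CoefficientEstimate.from_value_se("tau", point["tau"], point["tau_se"]),
            delta_prime=CoefficientEstimate.from_value_se(
                "delta_prime", point["delta_prime"], point["delta_se"]
            ),
            beta_prime=CoefficientEstimate.from_value_se(
                "beta_prime", point["beta_prime"], point["beta_se"]
            ),
            indirect=float(theta_hat),
            indirect_se=float(se_hat),
            indirect_ci95=(float(lo), float(hi)),
            first_stage_F=float(point["first_stage_F"]),
            n=int(point["n"]),
            n_bootstrap=int(theta_star.size),
        )
        return self


def _studentized_interval(theta_hat, se_hat, theta_star, se_star, level):
    """Percentile-t interval from the bootstrap pivot distribution."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = (theta_star - theta_hat) / se_star
    t_star = np.where(
        np.isnan(t_star) & (theta_star == theta_hat), 0.0, t_star
    )
    a = (1 - level) / 2
    q_lo, q_hi = np.quantile(t_star, [a, 1 - a])
    return theta_hat - se_hat * q_hi, theta_hat - se_hat * q_lo
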