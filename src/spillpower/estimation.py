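"""Functional surface of the analysis plan.

Thin wrappers over the scikit-learn style estimators in
:mod:`spillpower.estimators`, plus the step-up multiple-testing adjustment
and the standalone studentized bootstrap interval.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _core
from .estimators import (
    LinearProbabilityModel,
    ProbitRegression,
    RiversVuongProbit,
    SpilloverDecomposer,
    TwoStageLeastSquares,
    _studentized_interval,
)
from .results import (
    BootstrapSettings,
    CoefficientEstimate,
    ModeratedDecomposition,
    SpilloverDecomposition,
)

__all__ = [
    "fit_lpm",
    "fit_2sls",
    "fit_probit",
    "rivers_vuong_cf",
    "decompose_spillover",
    "studentized_bootstrap_ci",
    "fit_moderated_2sls",
    "bh_adjust",
]


def fit_lpm(y, design) -> list[CoefficientEstimate]:
    """OLS with HC1 robust SEs on a design that already includes the intercept."""
    return LinearProbabilityModel(fit_intercept=False).fit(design, y).results_


def fit_probit(y, design) -> list[CoefficientEstimate]:
    """Newton-fitted probit on a design that already includes the intercept."""
    return ProbitRegression(fit_intercept=False).fit(design, y).results_


def fit_2sls(
    y,
    endogenous,
    instruments,
    exogenous=None,
) -> tuple[list[CoefficientEstimate], tuple[float, ...]]:
    """Classical 2SLS; returns (estimates, first-stage robust F per endogenous).

    ``endogenous`` and ``instruments`` are arrays/DataFrames of one or two
    columns; ``exogenous`` (if given) must include its own intercept column,
    otherwise an intercept is added.
    """
    endo = _to_frame(endogenous, "endog")
    inst = _to_frame(instruments, "iv")
    parts = [endo, inst]
    fit_intercept = True
    if exogenous is not None:
        exo = _to_frame(exogenous, "exog")
        parts.append(exo)
        # keep a user-supplied constant column rather than adding a second one
        fit_intercept = not any(
            np.ptp(exo[c].to_numpy()) == 0 for c in exo.columns
        )
    X = pd.concat(parts, axis=1)
    model = TwoStageLeastSquares(
        endogenous=list(endo.columns),
        instruments=list(inst.columns),
        fit_intercept=fit_intercept,
    ).fit(X, y)
    return model.results_, model.first_stage_F_


def _to_frame(x, stem: str) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x.reset_index(drop=True)
    if isinstance(x, pd.Series):
        return x.rename(x.name or stem).reset_index(drop=True).to_frame()
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = [stem if arr.shape[1] == 1 else f"{stem}{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def rivers_vuong_cf(y, endogenous, instruments, exogenous=None) -> list[CoefficientEstimate]:
    """Control-function probit (first-stage OLS residual as extra regressor)."""
    endo = _to_frame(endogenous, "endog")
    inst = _to_frame(instruments, "iv")
    parts = [endo, inst]
    if exogenous is not None:
        parts.append(_to_frame(exogenous, "exog"))
    X = pd.concat(parts, axis=1)
    model = RiversVuongProbit(
        endogenous=endo.columns[0], instruments=list(inst.columns)
    ).fit(X, y)
    return model.results_


def decompose_spillover(
    sample,
    settings: BootstrapSettings | None = None,
    exog_cols: Sequence[str] = (),
) -> SpilloverDecomposition:
    """Total/direct/indirect spillover decomposition with bootstrap CI.

    ``sample`` is a DataFrame with columns T, IV, PEB1, PEB2 (or a
    :class:`~spillpower.dgp.SimulatedSample`).
    """
    settings = settings or BootstrapSettings()
    df = sample if isinstance(sample, pd.DataFrame) else sample.to_frame()
    dec = SpilloverDecomposer(
        n_resamples=settings.n_resamples,
        level=settings.level,
        seed=settings.seed,
        exog_cols=exog_cols,
    ).fit(df)
    return dec.decomposition_


def studentized_bootstrap_ci(
    sample,
    settings: BootstrapSettings | None = None,
    exog_cols: Sequence[str] = (),
) -> tuple[float, float]:
    """Studentized bootstrap CI for the indirect effect ``tau - delta'``.

    Per resample the pivot ``t* = (theta* - theta_hat) / se*`` is formed
    with ``se*`` from the heteroskedasticity-robust sandwich of the stacked
    moment conditions of the three analysis-plan regressions; the interval
    is ``[theta_hat - se * q_hi(t*), theta_hat - se * q_lo(t*)]``.
    """
    settings = settings or BootstrapSettings()
    df = sample if isinstance(sample, pd.DataFrame) else sample.to_frame()
    t = df["T"].to_numpy(np.float64)
    iv = df["IV"].to_numpy(np.float64)
    p1 = df["PEB1"].to_numpy(np.float64)
    p2 = df["PEB2"].to_numpy(np.float64)
    exog = df[list(exog_cols)].to_numpy(np.float64) if len(exog_cols) else None
    point = _core.decompose_point(t, iv, p1, p2, exog=exog)
    theta_hat = point["tau"] - point["delta_prime"]
    rng = np.random.default_rng(settings.seed)
    theta_star, se_star = _core.bootstrap_indirect(
        t, iv, p1, p2, settings.n_resamples, rng, exog=exog
    )
    lo, hi = _studentized_interval(
        theta_hat, point["se_stacked"], theta_star, se_star, settings.level
    )
    return float(lo), float(hi)


def fit_moderated_2sls(
    sample: pd.DataFrame,
    moderator: str,
    contract: str = "study2",
) -> ModeratedDecomposition:
    """Moderated decomposition with two endogenous regressors.

    The endogenous block is {PEB1, PEB1 x moderator}, instrumented by
    {IV, IV x moderator} (just-identified).  ``contract`` selects which
    exogenous treatment terms enter: ``study2`` keeps T only; ``study3``
    adds T x moderator (whose coefficient tests the moderation of the
    direct effect).
    """
    if contract not in ("study2", "study3"):
        raise ValueError("contract must be 'study2' or 'study3'")
    m = sample[moderator].to_numpy(np.float64)
    if np.ptp(m) == 0:
        raise ValueError(f"moderator {moderator!r} is constant")
    df = pd.DataFrame(
        {
            "PEB1": sample["PEB1"].to_numpy(np.float64),
            "PEB1_x_mod": sample["PEB1"].to_numpy(np.float64) * m,
            "IV": sample["IV"].to_numpy(np.float64),
            "IV_x_mod": sample["IV"].to_numpy(np.float64) * m,
            "T": sample["T"].to_numpy(np.float64),
        }
    )
    if contract == "study3":
        df["T_x_mod"] = df["T"] * m
    model = TwoStageLeastSquares(
        endogenous=["PEB1", "PEB1_x_mod"], instruments=["IV", "IV_x_mod"]
    ).fit(df, sample["PEB2"].to_numpy(np.float64))
    return ModeratedDecomposition(
        beta1_prime=model.estimate("PEB1"),
        beta2_prime=model.estimate("PEB1_x_mod"),
        delta1_prime=model.estimate("T"),
        delta2_prime=model.estimate("T_x_mod") if contract == "study3" else None,
        first_stage_Fs=model.first_stage_F_,
        moderator_name=moderator,
        n=model.n_obs_,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
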