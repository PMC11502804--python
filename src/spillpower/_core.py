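"""Batched weighted least-squares kernels for the spillover decomposition.

Everything here operates on arrays of shape ``(B, m)``: ``B`` parallel
datasets (bootstrap resamples, or a single dataset with ``B = 1``) of ``m``
design points with nonnegative weights.  Weights are multiplicities, so a
bootstrap resample of a binary table can be represented as a multinomial
count vector over the 16 distinct (T, IV, PEB1, PEB2) cell types instead of
``n`` physical rows — the distribution of every statistic is identical to
resampling rows with replacement, but the computation is ~n/16 times
cheaper.

The three estimating equations are the registered analysis plan:

    stage 1 : PEB1 = alpha + beta*IV + delta*T            (OLS)
    stage 2 : PEB2 = alpha' + beta'*PEB1_hat + delta'*T   (2SLS second stage)
    total   : PEB2 = gamma' + tau*T                       (OLS)

plus the sandwich variance of ``tau - delta'`` from the stacked moment
conditions of the three equations sharing observations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["decompose_weighted", "decompose_point", "bootstrap_indirect"]

_DET_RTOL = 1e-12


class DegenerateSampleError(ValueError):
    """Raised when T, IV or PEB1 does not vary in a sample."""


class BootstrapFailureError(RuntimeError):
    """Raised when too few bootstrap resamples are estimable."""


def _stack(cols):
    return np.stack(cols, axis=-1)


def _wvar(x, w, W):
    mu = (w * x).sum(axis=-1) / W
    return (w * (x - mu[..., None]) ** 2).sum(axis=-1) / W


def _atwb(w, A, B):
    return np.einsum("bm,bmi,bmj->bij", w, A, B, optimize=True)


def _atwy(w, A, y):
    return np.einsum("bm,bmi,bm->bi", w, A, y, optimize=True)


def _fitted(X, beta):
    return np.einsum("bmi,bi->bm", X, beta, optimize=True)


def _patch_singular(A, valid):
    """Replace singular systems by the identity so batched solve succeeds."""
    det = np.linalg.det(A)
    scale = np.abs(A).max(axis=(1, 2)) ** A.shape[-1]
    ok = np.abs(det) > _DET_RTOL * np.maximum(scale, 1e-300)
    valid &= ok
    if not ok.all():
        A = A.copy()
        A[~ok] = np.eye(A.shape[-1])
    return A, valid


def _solve_vec(A, b):
    """Batched solve with a vector right-hand side: (B,k,k), (B,k) -> (B,k)."""
    return np.linalg.solve(A, b[..., None])[..., 0]


def _sandwich(A, meat):
    """A^{-1} meat A^{-T} for batched (possibly asymmetric) A, symmetric meat."""
    inner = np.linalg.solve(A, meat)
    return np.linalg.solve(A, inner.transpose(0, 2, 1)).transpose(0, 2, 1)


def decompose_weighted(t, iv, p1, p2, w, exog=None):
    """Fit the three-equation spillover system on ``B`` weighted datasets.

    Parameters
    ----------
    t, iv, p1, p2 : ndarray, shape (B, m)
        Treatment, instrument, first and second behavior values.
    w : ndarray, shape (B, m)
        Nonnegative multiplicities; the effective sample size is ``w.sum()``
        per row.
    exog : ndarray of shape (B, m, q), optional
        Extra exogenous regressors added to every equation.

    Returns
    -------
    dict of ndarrays of shape (B,) with keys ``tau``, ``tau_se``,
    ``delta_prime``, ``delta_se``, ``beta_prime``, ``beta_se``,
    ``stage1_beta_iv``, ``stage1_delta``, ``first_stage_F``,
    ``se_stacked`` (sandwich SE of ``tau - delta_prime``) and a boolean
    ``valid`` mask flagging degenerate datasets.  Reported SEs are HC1
    except ``se_stacked`` which is the unscaled (HC0) stacked sandwich.
    """
    t = np.asarray(t, dtype=np.float64)
    iv = np.asarray(iv, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)

    one = np.ones(t.shape, dtype=np.float64)
    extra = [] if exog is None else [exog[..., j] for j in range(exog.shape[-1])]
    X3 = _stack([one, t] + extra)
    Z = _stack([one, iv, t] + extra)
    X2 = _stack([one, p1, t] + extra)
    k3, kz = X3.shape[-1], Z.shape[-1]

    W = w.sum(axis=-1)
    valid = (W > kz) & (_wvar(t, w, W) > 0) & (_wvar(iv, w, W) > 0) & (
        _wvar(p1, w, W) > 0
    )

    A3 = _atwb(w, X3, X3)
    A1 = _atwb(w, Z, Z)
    C = _atwb(w, Z, X2)
    A3, valid = _patch_singular(A3, valid)
    A1, valid = _patch_singular(A1, valid)
    C, valid = _patch_singular(C, valid)

    theta3 = _solve_vec(A3, _atwy(w, X3, p2))
    theta1 = _solve_vec(A1, _atwy(w, Z, p1))
    theta2 = _solve_vec(C, _atwy(w, Z, p2))

    e3 = p2 - _fitted(X3, theta3)
    e1 = p1 - _fitted(Z, theta1)
    # stage-2 residuals at the *original* endogenous values
    e2 = p2 - _fitted(X2, theta2)

    hc1_3 = W / np.maximum(W - k3, 1.0)
    hc1_z = W / np.maximum(W - kz, 1.0)

    cov3 = _sandwich(A3, _atwb(w * e3**2, X3, X3))
    cov1 = _sandwich(A1, _atwb(w * e1**2, Z, Z))
    cov2 = _sandwich(C, _atwb(w * e2**2, Z, Z))

    with np.errstate(invalid="ignore"):
        tau_se = np.sqrt(hc1_3 * cov3[:, 1, 1])
        beta_iv_se = np.sqrt(hc1_z * cov1[:, 1, 1])
        beta_se = np.sqrt(hc1_z * cov2[:, 1, 1])
        delta_se = np.sqrt(hc1_z * cov2[:, 2, 2])
        first_stage_F = np.where(
            beta_iv_se > 0, (theta1[:, 1] / beta_iv_se) ** 2, 0.0
        )

    # stacked sandwich for tau - delta': influence functions of the two
    # coefficients share observations, so their covariance is kept.
    B = t.shape[0]
    e_delta = np.zeros((B, kz))
    e_delta[:, 2] = 1.0
    r_delta = _solve_vec(C.transpose(0, 2, 1), e_delta)
    e_tau = np.zeros((B, k3))
    e_tau[:, 1] = 1.0
    r_tau = _solve_vec(A3, e_tau)  # A3 symmetric
    psi_delta = _fitted(Z, r_delta) * e2
    psi_tau = _fitted(X3, r_tau) * e3
    se_stacked = np.sqrt((w * (psi_tau - psi_delta) ** 2).sum(axis=-1))

    return {
        "tau": theta3[:, 1],
        "tau_intercept": theta3[:, 0],
        "tau_se": tau_se,
        "beta_prime": theta2[:, 1],
        "beta_se": beta_se,
        "delta_prime": theta2[:, 2],
        "delta_se": delta_se,
        "stage2_intercept": theta2[:, 0],
        "stage1_beta_iv": theta1[:, 1],
        "stage1_beta_iv_se": beta_iv_se,
        "stage1_delta": theta1[:, 2],
        "first_stage_F": first_stage_F,
        "se_stacked": se_stacked,
        "n": W,
        "valid": valid,
    }


def decompose_point(t, iv, p1, p2, exog=None, weights=None):
    """Single-dataset convenience wrapper; raises on degenerate input."""
    t = np.asarray(t, dtype=np.float64)
    w = np.ones((1, t.shape[0])) if weights is None else weights[None, :]
    ex = None if exog is None else np.asarray(exog, dtype=np.float64)[None, ...]
    res = decompose_weighted(
        t[None, :],
        np.asarray(iv, dtype=np.float64)[None, :],
        np.asarray(p1, dtype=np.float64)[None, :],
        np.asarray(p2, dtype=np.float64)[None, :],
        w,
        exog=ex,
    )
    if not res["valid"][0]:
        raise DegenerateSampleError(
            "T, IV and PEB1 must all vary (and the design must be non-singular)"
        )
    return {k: v[0] for k, v in res.items()}


def _is_binary(x):
    return np.isin(x, (0.0, 1.0)).all()


def bootstrap_indirect(
    t,
    iv,
    p1,
    p2,
    n_resamples,
    rng,
    exog=None,
    max_redraw=100,
):
    """Bootstrap distribution of (tau - delta', stacked-sandwich SE).

    Resamples units with replacement.  When both behaviors are binary and no
    exogenous block is present, resamples are drawn as multinomial counts
    over the 16 cell types (distributionally identical, far cheaper);
    otherwise rows are gathered explicitly in memory-bounded chunks.
    Degenerate resamples (constant T, IV or PEB1, or singular design) are
    redrawn up to ``max_redraw`` rounds and dropped afterwards.

    Returns ``(theta_star, se_star)`` arrays over the valid resamples.
    """
    t = np.asarray(t, dtype=np.float64)
    iv = np.asarray(iv, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    n = t.shape[0]

    fast = exog is None and _is_binary(p1) and _is_binary(p2) and _is_binary(t) and _is_binary(iv)
    theta_parts, se_parts = [], []

    if fast:
        codes = (8 * t + 4 * iv + 2 * p1 + p2).astype(np.intp)
        counts = np.bincount(codes, minlength=16).astype(np.float64)
        grid = np.arange(16)
        cell = {
            "t": (grid // 8 % 2).astype(np.float64),
            "iv": (grid // 4 % 2).astype(np.float64),
            "p1": (grid // 2 % 2).astype(np.float64),
            "p2": (grid % 2).astype(np.float64),
        }
        need = n_resamples
        for _ in range(max_redraw):
            if need == 0:
                break
            w = rng.multinomial(n, counts / n, size=need).astype(np.float64)
            tb = np.broadcast_to(cell["t"], (need, 16))
            vb = np.broadcast_to(cell["iv"], (need, 16))
            p1b = np.broadcast_to(cell["p1"], (need, 16))
            p2b = np.broadcast_to(cell["p2"], (need, 16))
            res = decompose_weighted(tb, vb, p1b, p2b, w)
            ok = res["valid"] & np.isfinite(res["se_stacked"])
            theta_parts.append((res["tau"] - res["delta_prime"])[ok])
            se_parts.append(res["se_stacked"][ok])
            need -= int(ok.sum())
    else:
        ex = None if exog is None else np.asarray(exog, dtype=np.float64)
        chunk = max(1, min(n_resamples, 2_000_000 // max(n, 1)))
        need = n_resamples
        rounds = 0
        while need > 0 and rounds < max_redraw:
            bc = min(chunk, need)
            idx = rng.integers(0, n, size=(bc, n))
            exb = None if ex is None else ex[idx]
            res = decompose_weighted(
                t[idx], iv[idx], p1[idx], p2[idx], np.ones((bc, n)), exog=exb
            )
            ok = res["valid"] & np.isfinite(res["se_stacked"])
            theta_parts.append((res["tau"] - res["delta_prime"])[ok])
            se_parts.append(res["se_stacked"][ok])
            got = int(ok.sum())
            if got < bc:
                rounds += 1
            need -= got

    theta_star = np.concatenate(theta_parts) if theta_parts else np.empty(0)
    se_star = np.concatenate(se_parts) if se_parts else np.empty(0)
    if theta_star.size < n_resamples / 2:
        raise BootstrapFailureError(
            f"only {theta_star.size} of {n_resamples} resamples were estimable"
        )
    return theta_star[:n_resamples], se_star[:n_resamples]
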