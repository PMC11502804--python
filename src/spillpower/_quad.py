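"""Gauss-Hermite helpers for logistic-normal expectations."""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

_NODES, _WEIGHTS = np.polynomial.hermite.hermgauss(80)


def logistic_normal_mean(mu: float, sigma: float) -> float:
    """E[expit(mu + sigma * Z)] for Z ~ N(0, 1), by 80-node Gauss-Hermite."""
    z = np.sqrt(2.0) * _NODES
    return float((_WEIGHTS * expit(mu + sigma * z)).sum() / np.sqrt(np.pi))


def solve_logit_intercept(target: float, sigma: float, shift: float = 0.0) -> float:
    """Intercept a with E[expit(a + shift + sigma * Z)] = target."""
    if not 0 < target < 1:
        raise ValueError("target probability must be in (0, 1)")
    return brentq(
        lambda a: logistic_normal_mean(a + shift, sigma) - target, -30.0, 30.0
    )
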