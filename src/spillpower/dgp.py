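"""Sampling from the structural spillover model.

Both observation models share the latent chain

    T, IV ~ Bernoulli(1/2) independently
    U1 | T        ~ Normal(phi1 * T, sigma_u1)
    U2 | U1, PEB1 ~ Normal(phi21 * U1 + phi22 * PEB1, sigma_u2)

with PEB1 entering U2 as the *realized* draw.  In the binary version the
behaviors are Bernoulli with logit-linear success probabilities; in the
continuous version they are Gaussian with the same linear predictors.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import DGPVersion, GenerativeParams

__all__ = ["SimulatedSample", "sample_dataset", "closed_form_effects", "SampleSizeError"]


class SampleSizeError(ValueError):
    """Raised when a requested sample is too small to be usable."""


class UnsupportedVersionError(ValueError):
    """Raised when an operation is defined for one observation model only."""


@dataclasses.dataclass
class SimulatedSample:
    """Unit-level draws from the structural model.

    ``p_peb1``/``p_peb2`` hold the underlying Bernoulli probabilities and are
    ``None`` in the continuous version.
    """

    n: int
    T: np.ndarray
    IV: np.ndarray
    U1: np.ndarray
    U2: np.ndarray
    PEB1: np.ndarray
    PEB2: np.ndarray
    version: DGPVersion
    p_peb1: Optional[np.ndarray] = None
    p_peb2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("T", "IV", "U1", "U2", "PEB1", "PEB2"):
            if len(getattr(self, name)) != self.n:
                raise ValueError(f"field {name} has length != n")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "unit_id": np.arange(self.n),
            "T": self.T.astype(int),
            "IV": self.IV.astype(int),
            "U1": self.U1,
            "PEB1": self.PEB1,
            "U2": self.U2,
            "PEB2": self.PEB2,
        }
        if self.version is DGPVersion.BINARY:
            data["p_peb1"] = self.p_peb1
            data["p_peb2"] = self.p_peb2
        return pd.DataFrame(data)


@dataclasses.dataclass
class NoisePanel:
    """Pre-drawn primitive randomness, reusable across parameter values.

    The calibration search evaluates many nearby parameter vectors; holding
    the underlying uniforms/normals fixed (common random numbers) makes the
    measured effect sizes a smooth deterministic function of the parameters.
    """

    u_t: np.ndarray
    u_iv: np.ndarray
    z_u1: np.ndarray
    z_u2: np.ndarray
    u_peb1: np.ndarray
    u_peb2: np.ndarray

    @classmethod
    def draw(cls, n: int, rng: np.random.Generator) -> "NoisePanel":
        return cls(
            u_t=rng.random(n),
            u_iv=rng.random(n),
            z_u1=rng.standard_normal(n),
            z_u2=rng.standard_normal(n),
            u_peb1=rng.random(n),
            u_peb2=rng.random(n),
        )

    @property
    def n(self) -> int:
        return len(self.u_t)


def _sample_from_noise(params: GenerativeParams, noise: NoisePanel) -> SimulatedSample:
    """Deterministic transform of a noise panel under ``params``."""
    n = noise.n
    T = (noise.u_t < 0.5).astype(np.float64)
    IV = (noise.u_iv < 0.5).astype(np.float64)
    U1 = params.phi1 * T + params.sigma_u1 * noise.z_u1

    if params.version is DGPVersion.BINARY:
        p1 = expit(params.attract_peb1 + params.beta_u1 * U1 + params.beta_iv * IV)
        PEB1 = (noise.u_peb1 < p1).astype(np.float64)
        U2 = params.phi21 * U1 + params.phi22 * PEB1 + params.sigma_u2 * noise.z_u2
        p2 = expit(params.attract_peb2 + params.beta_u2 * U2)
        PEB2 = (noise.u_peb2 < p2).astype(np.float64)
        return SimulatedSample(
            n=n, T=T, IV=IV, U1=U1, U2=U2, PEB1=PEB1, PEB2=PEB2,
            version=params.version, p_peb1=p1, p_peb2=p2,
        )

    # continuous version: Gaussian outcomes with the same linear predictors;
    # the uniforms are mapped through the normal quantile function.
    from scipy.special import ndtri

    e1 = ndtri(noise.u_peb1)
    e2 = ndtri(noise.u_peb2)
    PEB1 = (
        params.attract_peb1
        + params.beta_u1 * U1
        + params.beta_iv * IV
        + params.sigma_peb1 * e1
    )
    U2 = params.phi21 * U1 + params.phi22 * PEB1 + params.sigma_u2 * noise.z_u2
    PEB2 = params.attract_peb2 + params.beta_u2 * U2 + params.sigma_peb2 * e2
    return SimulatedSample(
        n=n, T=T, IV=IV, U1=U1, U2=U2, PEB1=PEB1, PEB2=PEB2, version=params.version
    )


def sample_dataset(
    params: GenerativeParams,
    n_total: int,
    seed: int | np.random.Generator,
) -> SimulatedSample:
    """Draw ``n_total`` units from the structural model.

    Parameters
    ----------
    params:
        Structural coefficients; the ``version`` field selects the
        observation model.
    n_total:
        Number of units (>= 2).  Treatment and nudge are Bernoulli(1/2)
        each, crossed independently; arms are not forced to exact balance.
    seed:
        Integer seed or a ``numpy.random.Generator`` (consumed in place).

    Returns
    -------
    SimulatedSample
        Identical inputs (params, n_total, integer seed) give bitwise
        identical samples.
    """
    if n_total < 2:
        raise SampleSizeError(f"n_total must be >= 2, got {n_total}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = NoisePanel.draw(n_total, rng)
    return _sample_from_noise(params, noise)


def closed_form_effects(params: GenerativeParams) -> dict[str, float]:
    """Exact path effects of the linear (continuous) model.

    Returns the partial/total derivatives implied by the chain:

    - ``t_on_peb1``     = beta_u1 * phi1
    - ``peb1_on_peb2``  = beta_u2 * phi22
    - ``direct``        = beta_u2 * phi21 * phi1          (∂T PEB2)
    - ``indirect``      = t_on_peb1 * peb1_on_peb2
    - ``total``         = direct + indirect               (ΔT PEB2)

    These identities are exact only when both behaviors are observed on a
    continuous scale; the binary version has no closed form and must be
    simulated.
    """
    if params.version is not DGPVersion.CONTINUOUS:
        raise UnsupportedVersionError(
            "closed-form path effects exist only for the continuous version"
        )
    t_on_peb1 = params.beta_u1 * params.phi1
    peb1_on_peb2 = params.beta_u2 * params.phi22
    direct = params.beta_u2 * params.phi21 * params.phi1
    indirect = t_on_peb1 * peb1_on_peb2
    return {
        "t_on_peb1": t_on_peb1,
        "peb1_on_peb2": peb1_on_peb2,
        "direct": direct,
        "indirect": indirect,
        "total": direct + indirect,
    }
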