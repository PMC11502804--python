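"""Result containers shared by the estimation layer."""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "CoefficientEstimate",
    "SpilloverDecomposition",
    "ModeratedDecomposition",
    "BootstrapSettings",
]


@dataclasses.dataclass(frozen=True)
class CoefficientEstimate:
    """One regression coefficient with robust inference.

    P-values and the 95% CI use the standard-normal reference; the smallest
    design in scope has several hundred units, where the normal and t
    references agree to the reported precision.
    """

    name: str
    value: float
    robust_se: float
    t_stat: float
    p_two_sided: float
    ci95: tuple[float, float]

    @classmethod
    def from_value_se(cls, name: str, value: float, se: float) -> "CoefficientEstimate":
        value, se = float(value), float(se)
        z = value / se if se > 0 else np.inf * np.sign(value) if value else 0.0
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        half = 1.959963984540054 * se
        return cls(
            name=name,
            value=value,
            robust_se=se,
            t_stat=float(z),
            p_two_sided=p,
            ci95=(value - half, value + half),
        )


@dataclasses.dataclass(frozen=True)
class SpilloverDecomposition:
    """Total / direct / indirect decomposition of a treatment's spillover.

    ``indirect`` is the plug-in ``tau - delta'`` estimate; its interval is a
    studentized bootstrap CI, and the effect is declared significant iff
    that interval excludes zero.
    """

    tau: CoefficientEstimate
    delta_prime: CoefficientEstimate
    beta_prime: CoefficientEstimate
    indirect: float
    indirect_se: float
    indirect_ci95: tuple[float, float]
    first_stage_F: float
    n: int
    n_bootstrap: int

    @property
    def indirect_significant(self) -> bool:
        lo, hi = self.indirect_ci95
        return lo > 0 or hi < 0


@dataclasses.dataclass(frozen=True)
class ModeratedDecomposition:
    """Two-endogenous-regressor (just-identified) moderation system."""

    beta1_prime: CoefficientEstimate
    beta2_prime: CoefficientEstimate
    delta1_prime: CoefficientEstimate
    delta2_prime: Optional[CoefficientEstimate]
    first_stage_Fs: tuple[float, float]
    moderator_name: str
    n: int


@dataclasses.dataclass(frozen=True)
class BootstrapSettings:
    """Settings of the studentized bootstrap for ``tau - delta'``."""

    n_resamples: int = 10_000
    level: float = 0.95
    seed: int | None = None
    inner_se_method: str = "stacked_sandwich"

    def __post_init__(self) -> None:
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be >= 100")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.inner_se_method != "stacked_sandwich":
            raise ValueError("only the stacked_sandwich inner SE is implemented")
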