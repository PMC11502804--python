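"""Cohen's d machinery for calibrating and reporting simulated effects.

All scenario targets are expressed as standardized mean differences
(Cohen's d with the pooled, unbiased-variance SD).  The indirect spillover
has no direct group contrast; its d is *defined* by the subtraction rule

    d_indirect = d_total - d_direct

with the direct d obtained by scaling the 2SLS direct-effect coefficient by
the pooled SD of PEB2 across treatment groups.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "EffectSizeSet",
    "cohens_d_by_group",
    "pooled_sd_by_group",
    "measure_effect_sizes",
    "InsufficientDataError",
    "DegenerateOutcomeError",
]


class InsufficientDataError(ValueError):
    """A group has fewer than two units."""


class DegenerateOutcomeError(ValueError):
    """The pooled variance of the outcome is zero."""


@dataclasses.dataclass(frozen=True)
class EffectSizeSet:
    """The five standardized effects describing one scenario.

    ``d_indirect_peb2`` always equals ``d_total_peb2 - d_direct_peb2``
    exactly; construct instances through :meth:`from_components` to keep the
    identity by construction.
    """

    d_t_peb1: float
    d_iv_peb1: float
    d_total_peb2: float
    d_direct_peb2: float
    d_indirect_peb2: float

    @classmethod
    def from_components(
        cls, d_t_peb1: float, d_iv_peb1: float, d_total_peb2: float, d_direct_peb2: float
    ) -> "EffectSizeSet":
        return cls(
            d_t_peb1=d_t_peb1,
            d_iv_peb1=d_iv_peb1,
            d_total_peb2=d_total_peb2,
            d_direct_peb2=d_direct_peb2,
            d_indirect_peb2=d_total_peb2 - d_direct_peb2,
        )

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def max_abs_gap(self, other: "EffectSizeSet") -> float:
        return max(
            abs(a - b)
            for a, b in zip(self.as_dict().values(), other.as_dict().values())
        )


def pooled_sd_by_group(y, g) -> float:
    """Pooled SD across the two ``g`` groups with unbiased group variances."""
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g)
    y1, y0 = y[g == 1], y[g == 0]
    n1, n0 = len(y1), len(y0)
    if n1 < 2 or n0 < 2:
        raise InsufficientDataError(
            f"both groups need >= 2 units (got {n0} and {n1})"
        )
    s2 = ((n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1)) / (n1 + n0 - 2)
    return float(np.sqrt(s2))


def cohens_d_by_group(y, g) -> float:
    """Classical Cohen's d of ``y`` between the two groups coded in ``g``.

    d = (mean(y | g=1) - mean(y | g=0)) / pooled SD, no small-sample
    (Hedges) correction.
    """
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g)
    sd = pooled_sd_by_group(y, g)
    if sd == 0:
        raise DegenerateOutcomeError("pooled variance of the outcome is zero")
    return float((y[g == 1].mean() - y[g == 0].mean()) / sd)


def measure_effect_sizes(sample, decomposition) -> EffectSizeSet:
    """Standardized effects of a simulated sample.

    Parameters
    ----------
    sample:
        A :class:`~spillpower.dgp.SimulatedSample` (or any object with
        ``T``, ``IV``, ``PEB1``, ``PEB2`` arrays).
    decomposition:
        The fitted spillover decomposition of the same sample; supplies the
        2SLS direct-effect coefficient delta', which is standardized by the
        pooled SD of PEB2 across treatment groups.
    """
    delta = (
        decomposition.delta_prime.value
        if hasattr(decomposition, "delta_prime")
        else float(decomposition)
    )
    return _measure_from_arrays(sample.T, sample.IV, sample.PEB1, sample.PEB2, delta)


def _measure_from_arrays(t, iv, p1, p2, delta_prime: float) -> EffectSizeSet:
    sd2 = pooled_sd_by_group(p2, t)
    if sd2 == 0:
        raise DegenerateOutcomeError("pooled variance of PEB2 is zero")
    return EffectSizeSet.from_components(
        d_t_peb1=cohens_d_by_group(p1, t),
        d_iv_peb1=cohens_d_by_group(p1, iv),
        d_total_peb2=cohens_d_by_group(p2, t),
        d_direct_peb2=float(delta_prime) / sd2,
    )
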