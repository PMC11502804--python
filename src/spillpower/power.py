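"""Simulation-based power analysis over scenarios, sample sizes and estimands.

For each replicate a fresh experiment is simulated and the four registered
decision rules are applied:

- ``t_on_peb1``        : LPM of PEB1 on T, robust p < alpha;
- ``total_spillover``  : OLS of PEB2 on T, robust p < alpha;
- ``direct_spillover`` : 2SLS direct-effect coefficient, robust p < alpha;
- ``indirect_spillover``: studentized bootstrap CI of tau - delta'
  excluding zero.

Power is the fraction of rejecting replicates.  Replicates are seeded from
independent substreams, so cells are order-independent and reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _core
from .calibration import CalibrationSettings, NoisePanel, _measure_on_panel, _root_on
from .dgp import sample_dataset
from .estimators import _studentized_interval
from .params import DGPVersion, GenerativeParams

__all__ = [
    "PowerSettings",
    "PowerCell",
    "ESTIMANDS",
    "run_power_grid",
    "sensitivity_iv_strength",
    "sensitivity_attractiveness",
    "ATTRACTIVENESS_LEVELS",
]

logger = logging.getLogger(__name__)

ESTIMANDS = (
    "t_on_peb1",
    "total_spillover",
    "direct_spillover",
    "indirect_spillover",
)

#: Logit intercepts corresponding approximately to base probabilities
#: 0.01, 0.05, 0.10, 0.20 and 0.40.
ATTRACTIVENESS_LEVELS = (-4.59512, -2.94439, -2.19725, -1.3862, -0.4045651)


@dataclasses.dataclass(frozen=True)
class PowerSettings:
    """Replication settings for the power grid."""

    reps: int = 1000
    alpha: float = 0.05
    n_per_arm_grid: Sequence[int] = (150, 200, 250, 350, 500, 750, 1000, 1250)
    bootstrap_B_inner: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 50:
            raise ValueError("reps must be >= 50")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")


@dataclasses.dataclass(frozen=True)
class PowerCell:
    """Estimated power for one (scenario, n, estimand) combination."""

    scenario: str
    version: str
    n_per_arm: int
    estimand: str
    reps: int
    rejections: int
    power: float
    mc_se: float
    level: float | None = None

    @classmethod
    def from_counts(
        cls, scenario, version, n_per_arm, estimand, reps, rejections, level=None
    ) -> "PowerCell":
        power = rejections / reps
        return cls(
            scenario=scenario,
            version=version,
            n_per_arm=n_per_arm,
            estimand=estimand,
            reps=reps,
            rejections=rejections,
            power=power,
            mc_se=float(np.sqrt(power * (1 - power) / reps)),
            level=level,
        )


def _ols_robust_p(y: np.ndarray, x: np.ndarray) -> float:
    """Two-sided HC1 p-value of the slope in y ~ 1 + x (normal reference)."""
    n = len(y)
    x1, x0 = y[x == 1], y[x == 0]
    n1, n0 = len(x1), len(x0)
    b = x1.mean() - x0.mean()
    # HC1 sandwich of the two-group OLS slope
    v = (x1.var() / n1 + x0.var() / n0) * n / (n - 2)
    if v <= 0:
        return 1.0
    return float(2 * stats.norm.sf(abs(b) / np.sqrt(v)))


def _one_replicate(params, n_total, rng, estimands, alpha, B):
    sample = sample_dataset(params, n_total, rng)
    t, iv, p1, p2 = sample.T, sample.IV, sample.PEB1, sample.PEB2
    out = {}
    need_system = {"total_spillover", "direct_spillover", "indirect_spillover"} & set(
        estimands
    )
    if "t_on_peb1" in estimands:
        out["t_on_peb1"] = _ols_robust_p(p1, t) < alpha
    if need_system:
        point = _core.decompose_point(t, iv, p1, p2)
        if "total_spillover" in estimands:
            z = point["tau"] / point["tau_se"]
            out["total_spillover"] = 2 * stats.norm.sf(abs(z)) < alpha
        if "direct_spillover" in estimands:
            z = point["delta_prime"] / point["delta_se"]
            out["direct_spillover"] = 2 * stats.norm.sf(abs(z)) < alpha
        if "indirect_spillover" in estimands:
            theta_hat = point["tau"] - point["delta_prime"]
            theta_star, se_star = _core.bootstrap_indirect(t, iv, p1, p2, B, rng)
            lo, hi = _studentized_interval(
                theta_hat, point["se_stacked"], theta_star, se_star, 1 - alpha
            )
            out["indirect_spillover"] = lo > 0 or hi < 0
    return out


def run_power_grid(
    params: GenerativeParams,
    settings: PowerSettings | None = None,
    scenario: str = "custom",
    estimands: Iterable[str] = ESTIMANDS,
    level: float | None = None,
) -> list[PowerCell]:
    """Estimate power for every (n_per_arm, estimand) cell.

    Each replicate draws ``2 * n_per_arm`` units (treatment and nudge are
    Bernoulli(1/2), arms not hard-balanced) from its own random substream.
    Replicates where the decomposition is degenerate (constant T, IV or
    PEB1) are dropped from the denominator and counted; more than 5%
    degenerate triggers a log warning.
    """
    settings = settings or PowerSettings()
    estimands = tuple(estimands)
    unknown = set(estimands) - set(ESTIMANDS)
    if unknown:
        raise ValueError(f"unknown estimands: {sorted(unknown)}")
    cells = []
    for n_per_arm in settings.n_per_arm_grid:
        rejections = {e: 0 for e in estimands}
        valid = {e: 0 for e in estimands}
        degenerate = 0
        for rep in range(settings.reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([settings.seed, int(n_per_arm), rep])
            )
            try:
                res = _one_replicate(
                    params,
                    2 * n_per_arm,
                    rng,
                    estimands,
                    settings.alpha,
                    settings.bootstrap_B_inner,
                )
            except (_core.DegenerateSampleError, _core.BootstrapFailureError):
                degenerate += 1
                continue
            for e, rejected in res.items():
                valid[e] += 1
                rejections[e] += bool(rejected)
        if degenerate > 0.05 * settings.reps:
            logger.warning(
                "%d/%d degenerate replicates at n_per_arm=%d",
                degenerate,
                settings.reps,
                n_per_arm,
            )
        for e in estimands:
            cells.append(
                PowerCell.from_counts(
                    scenario,
                    params.version.value,
                    n_per_arm,
                    e,
                    valid[e],
                    rejections[e],
                    level=level,
                )
            )
    return cells


def calibrate_iv_strength(
    base: GenerativeParams,
    iv_d_target: float,
    n_inner: int = 500_000,
    seed: int = 0,
) -> GenerativeParams:
    """Re-tune ``beta_iv`` only so the measured IV->PEB1 d hits a target."""
    panel = NoisePanel.draw(n_inner, np.random.default_rng(seed))
    return _root_on(base, "beta_iv", "d_iv_peb1", iv_d_target, panel)


def sensitivity_iv_strength(
    base: GenerativeParams,
    iv_d_levels: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    settings: PowerSettings | None = None,
    scenario: str = "middle",
) -> list[PowerCell]:
    """Power of the spillover estimands as the instrument strength varies.

    For each level only ``beta_iv`` is recalibrated (the other parameters
    keep their base-scenario values) and the direct/indirect power grid is
    rerun.
    """
    settings = settings or PowerSettings()
    cells = []
    for level in iv_d_levels:
        params = calibrate_iv_strength(base, level, seed=settings.seed)
        cells.extend(
            run_power_grid(
                params,
                settings,
                scenario=scenario,
                estimands=("direct_spillover", "indirect_spillover"),
                level=level,
            )
        )
    return cells


def sensitivity_attractiveness(
    base: GenerativeParams,
    which: str = "peb1",
    levels: Sequence[float] = ATTRACTIVENESS_LEVELS,
    settings: PowerSettings | None = None,
    scenario: str = "middle",
) -> list[PowerCell]:
    """Power of the spillover estimands as a baseline attractiveness varies.

    Binary version only: the levels are logit intercepts (the defaults map
    to base probabilities 0.01, 0.05, 0.10, 0.20, 0.40); all other
    parameters keep their base calibration.
    """
    if base.version is not DGPVersion.BINARY:
        raise ValueError("attractiveness sweep is defined for the binary version")
    if which not in ("peb1", "peb2"):
        raise ValueError("which must be 'peb1' or 'peb2'")
    settings = settings or PowerSettings()
    field = "attract_peb1" if which == "peb1" else "attract_peb2"
    cells = []
    for level in levels:
        params = base.replace(**{field: float(level)})
        cells.extend(
            run_power_grid(
                params,
                settings,
                scenario=scenario,
                estimands=("direct_spillover", "indirect_spillover"),
                level=float(level),
            )
        )
    return cells
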