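import numpy as np
import pytest

import spillpower as sp


@pytest.fixture(scope="session")
def null_binary_params():
    """Binary DGP with every treatment path switched off."""
    return sp.GenerativeParams(
        version="binary",
        phi1=0.0,
        phi21=0.6,
        phi22=0.0,
        beta_u1=1.0,
        beta_u2=1.0,
        beta_iv=1.0,
        attract_peb1=-1.5,
        attract_peb2=-1.5,
    )


@pytest.fixture(scope="session")
def middle_continuous_params():
    """A continuous-version parameterization near the middle scenario."""
    return sp.GenerativeParams(
        version="continuous",
        phi1=1.0,
        phi21=0.7,
        phi22=0.77,
        beta_u1=0.74,
        beta_u2=0.345,
        beta_iv=0.515,
        attract_peb1=0.0,
        attract_peb2=0.0,
    )


@pytest.fixture(scope="session")
def calibrated_binary():
    """Binary-version calibrations of the three registered scenarios.

    Session-scoped: the searches take minutes and are shared by the
    calibration-fidelity and power-threshold acceptance tests.
    """
    cache = {}

    def get(name: str) -> sp.GenerativeParams:
        if name not in cache:
            cache[name] = sp.calibrate_scenario(
                sp.SCENARIOS[name], sp.CalibrationSettings(seed=11), "binary"
            )
        return cache[name]

    return get


def two_sample_power_normal_approx(d: float, n_per_arm: int, alpha: float = 0.05):
    """Closed-form power of the two-sample z-test at effect size d."""
    from scipy.stats import norm

    nc = d * np.sqrt(n_per_arm / 2)
    z = norm.ppf(1 - alpha / 2)
    return norm.cdf(nc - z) + norm.cdf(-nc - z)
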