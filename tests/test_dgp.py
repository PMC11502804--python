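"""The structural simulator: marginals, closed forms, reproducibility."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

import spillpower as sp
from spillpower._quad import logistic_normal_mean
from spillpower.dgp import SampleSizeError, UnsupportedVersionError
from spillpower.params import InvalidParameterError


def make_binary(**kw):
    base = dict(
        version="binary",
        phi1=0.0,
        phi21=0.0,
        phi22=0.0,
        beta_u1=0.0,
        beta_u2=0.0,
        beta_iv=0.0,
        attract_peb1=-1.5,
        attract_peb2=-1.5,
    )
    base.update(kw)
    return sp.GenerativeParams(**base)


class TestParams:
    def test_round_trip_dict(self):
        p = make_binary(phi1=0.3)
        assert sp.GenerativeParams.from_dict(p.to_dict()) == p

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_round_trip_file(self, tmp_path, suffix):
        p = make_binary(phi22=1.25, beta_iv=0.7)
        path = tmp_path / f"params{suffix}"
        p.to_file(path)
        assert sp.GenerativeParams.from_file(path) == p

    def test_unknown_key_rejected(self):
        d = make_binary().to_dict()
        d["phi3"] = 1.0
        with pytest.raises(InvalidParameterError, match="phi3"):
            sp.GenerativeParams.from_dict(d)

    @pytest.mark.parametrize("field", ["sigma_u1", "sigma_u2", "sigma_peb1"])
    def test_nonpositive_sigma_rejected(self, field):
        with pytest.raises(InvalidParameterError, match=field):
            make_binary(**{field: 0.0})

    def test_binary_version_flags_outcome_sigmas_unused(self):
        assert make_binary().unused_fields == ("sigma_peb1", "sigma_peb2")
        cont = make_binary().replace(version="continuous")
        assert cont.unused_fields == ()


class TestSampling:
    def test_baseline_participation_at_minus_1_5(self):
        # intercept -1.5 alone corresponds to a base probability ~18.2%
        s = sp.sample_dataset(make_binary(), 1_000_000, seed=7)
        p = expit(-1.5)
        mc_se = np.sqrt(p * (1 - p) / s.n)
        assert abs(s.PEB1.mean() - 0.182) < 3 * mc_se + 5e-4

    def test_zero_model_is_symmetric(self):
        s = sp.sample_dataset(
            make_binary(attract_peb1=0.0, attract_peb2=0.0), 400_000, seed=3
        )
        se = 3 / (2 * np.sqrt(s.n))
        assert abs(s.PEB1.mean() - 0.5) < se
        assert abs(s.PEB2.mean() - 0.5) < se

    @pytest.mark.parametrize(
        "beta_u1,beta_iv,iv_arm", [(1.0, 0.0, 0), (1.0, 0.8, 1), (0.5, 0.4, 0)]
    )
    def test_marginal_matches_quadrature_oracle(self, beta_u1, beta_iv, iv_arm):
        # P(PEB1=1 | IV=iv) = E[expit(a + bU1*Z + bIV*iv)], Z ~ N(0,1)
        params = make_binary(beta_u1=beta_u1, beta_iv=beta_iv)
        s = sp.sample_dataset(params, 600_000, seed=11)
        mask = s.IV == iv_arm
        expected = logistic_normal_mean(-1.5 + beta_iv * iv_arm, beta_u1)
        mc_se = np.sqrt(expected * (1 - expected) / mask.sum())
        assert abs(s.PEB1[mask].mean() - expected) < 3 * mc_se

    def test_same_seed_bitwise_identical(self):
        p = make_binary(phi1=0.5, beta_u1=1.0, beta_iv=0.5)
        a = sp.sample_dataset(p, 5000, seed=42)
        b = sp.sample_dataset(p, 5000, seed=42)
        for f in ("T", "IV", "U1", "U2", "PEB1", "PEB2", "p_peb1", "p_peb2"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_binary_sample_invariants(self):
        s = sp.sample_dataset(make_binary(beta_u1=1.0, beta_iv=0.6), 10_000, seed=1)
        assert set(np.unique(s.PEB1)) <= {0.0, 1.0}
        assert set(np.unique(s.PEB2)) <= {0.0, 1.0}
        assert np.all((s.p_peb1 > 0) & (s.p_peb1 < 1))
        assert np.all((s.p_peb2 > 0) & (s.p_peb2 < 1))

    def test_too_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            sp.sample_dataset(make_binary(), 1, seed=0)

    def test_irrelevant_instrument_gives_independence(self):
        # beta_iv = 0: the chi-square test of PEB1 x IV rejects at ~ alpha
        params = make_binary(beta_u1=1.0, beta_iv=0.0, phi1=0.5)
        rejections = 0
        n_seeds = 150
        for seed in range(n_seeds):
            s = sp.sample_dataset(params, 2000, seed=seed)
            table = np.array(
                [
                    [np.sum((s.PEB1 == a) & (s.IV == b)) for b in (0, 1)]
                    for a in (0, 1)
                ]
            )
            rejections += chi2_contingency(table).pvalue < 0.05
        rate = rejections / n_seeds
        band = 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert rate < 0.05 + band


class TestClosedFormEffects:
    def test_printed_identity_substitution(self):
        p = sp.GenerativeParams(
            version="continuous",
            phi1=1.0,
            phi21=0.7,
            phi22=0.4,
            beta_u1=0.5,
            beta_u2=1.0,
            beta_iv=1.0,
            attract_peb1=0.0,
            attract_peb2=0.0,
        )
        eff = sp.closed_form_effects(p)
        assert eff["indirect"] == pytest.approx(0.2)
        assert eff["direct"] == pytest.approx(0.7)
        assert eff["total"] == pytest.approx(0.9)

    def test_no_treatment_path_means_no_effects(self):
        p = sp.GenerativeParams(
            version="continuous",
            phi1=0.0,
            phi21=0.7,
            phi22=1.2,
            beta_u1=2.0,
            beta_u2=1.5,
            beta_iv=1.0,
            attract_peb1=0.0,
            attract_peb2=0.0,
        )
        eff = sp.closed_form_effects(p)
        assert eff["t_on_peb1"] == eff["direct"] == eff["indirect"] == eff["total"] == 0

    def test_binary_version_has_no_closed_form(self):
        with pytest.raises(UnsupportedVersionError):
            sp.closed_form_effects(make_binary())

    def test_large_sample_ols_recovers_closed_form(self, middle_continuous_params):
        params = middle_continuous_params
        eff = sp.closed_form_effects(params)
        s = sp.sample_dataset(params, 1_000_000, seed=5)
        for outcome, key in ((s.PEB2, "total"), (s.PEB1, "t_on_peb1")):
            y1, y0 = outcome[s.T == 1], outcome[s.T == 0]
            ate = y1.mean() - y0.mean()
            se = np.sqrt(y1.var() / len(y1) + y0.var() / len(y0))
            assert abs(ate - eff[key]) < 3 * se
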