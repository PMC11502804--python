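"""Analysis-plan estimators: LPM, 2SLS, probit, control function, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import spillpower as sp
from spillpower.estimators import CollinearityError, IdentificationError


def design(n=None, **cols):
    if n is None:
        n = len(next(iter(cols.values())))
    return pd.DataFrame({"const": np.ones(n), **cols})


class TestLinearProbabilityModel:
    def test_perfect_determination(self):
        t = np.array([0.0, 1, 0, 1, 1, 0])
        ests = sp.fit_lpm(t, design(T=t))
        assert ests[1].value == pytest.approx(1.0)
        assert ests[0].value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_group_difference(self):
        y = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        t = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        ests = sp.fit_lpm(y, design(T=t))
        assert ests[1].value == pytest.approx(1 / 3)

    def test_collinearity_names_offender(self):
        y = np.arange(6, dtype=float)
        t = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        with pytest.raises(CollinearityError, match="T_copy"):
            sp.fit_lpm(y, design(T=t, T_copy=t))

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        model = sp.LinearProbabilityModel(fit_intercept=True)
        assert clone(model).get_params() == model.get_params()
        rng = np.random.default_rng(0)
        X = rng.random((50, 2))
        fitted = model.fit(X, rng.random(50))
        assert fitted is model
        assert model.predict(X).shape == (50,)


class TestTwoStageLeastSquares:
    def test_equals_ols_when_instrument_is_regressor(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        y = 1.0 + 2.0 * x + rng.standard_normal(60)
        ests, _ = sp.fit_2sls(y, x, x)
        ols = sp.fit_lpm(y, design(x=x))
        assert ests[-1].value == pytest.approx(ols[1].value, rel=1e-10)

    def test_just_identified_equals_wald_oracle(self):
        # brute-force Wald estimator on a fixed 20-unit table
        rng = np.random.default_rng(7)
        iv = np.repeat([0, 1], 10).astype(float)
        x = (rng.random(20) < 0.3 + 0.4 * iv).astype(float)
        y = 0.2 * x + rng.standard_normal(20)
        wald = (y[iv == 1].mean() - y[iv == 0].mean()) / (
            x[iv == 1].mean() - x[iv == 0].mean()
        )
        ests, fs = sp.fit_2sls(y, x, iv)
        assert ests[-1].value == pytest.approx(wald, rel=1e-12)
        assert fs[0] >= 0

    def test_recovers_structural_paths_at_scale(self, middle_continuous_params):
        params = middle_continuous_params
        eff = sp.closed_form_effects(params)
        s = sp.sample_dataset(params, 1_000_000, seed=13)
        ests, fs = sp.fit_2sls(
            s.PEB2, pd.DataFrame({"PEB1": s.PEB1}), pd.DataFrame({"IV": s.IV}),
            pd.DataFrame({"T": s.T}),
        )
        by_name = {e.name: e for e in ests}
        assert abs(by_name["PEB1"].value - eff["peb1_on_peb2"]) < 3 * by_name["PEB1"].robust_se
        assert abs(by_name["T"].value - eff["direct"]) < 3 * by_name["T"].robust_se
        assert fs[0] > 10

    def test_weak_rank_first_stage_rejected(self):
        y = np.arange(8, dtype=float)
        x = np.ones(8)
        x[0] = 0.0
        with pytest.raises((IdentificationError, CollinearityError)):
            # instrument constant: collinear with the intercept
            sp.fit_2sls(y, x, np.ones(8))


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(sp.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_ties_at_top_rank_unchanged(self):
        np.testing.assert_allclose(sp.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sp.bh_adjust([0.031]), [0.031])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sp.bh_adjust([0.5, 1.2])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_step_up_properties(self, ps):
        adj = sp.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestProbit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(20000) < 0.182).astype(float)
        est = sp.fit_probit(y, design(n=len(y)))
        assert est[0].value == pytest.approx(norm.ppf(y.mean()), abs=1e-6)

    def test_symmetric_outcome_gives_zero_intercept(self):
        y = np.tile([0.0, 1.0], 500)
        est = sp.fit_probit(y, design(n=len(y)))
        assert est[0].value == pytest.approx(0.0, abs=1e-8)

    def test_slope_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100_000)
        y = (rng.standard_normal(100_000) < -0.5 + 1.0 * x).astype(float)
        ests = sp.fit_probit(y, design(x=x))
        assert abs(ests[1].value - 1.0) < 3 * ests[1].robust_se


class TestRiversVuong:
    @staticmethod
    def _endogenous_probit_data(n, rho, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        v = rng.standard_normal(n)
        x = 0.8 * z + v
        e = rng.standard_normal(n)
        y = ((0.5 * x + rho * v + e) > 0).astype(float)
        return z, x, y

    def test_exogenous_regressor_residual_null(self):
        rejections = 0
        for seed in range(120):
            z, x, y = self._endogenous_probit_data(800, rho=0.0, seed=seed)
            ests = sp.rivers_vuong_cf(y, x, z)
            rejections += ests[-1].p_two_sided < 0.05
        rate = rejections / 120
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 120)

    def test_recovers_known_coefficient_under_endogeneity(self):
        z, x, y = self._endogenous_probit_data(100_000, rho=0.6, seed=5)
        ests = sp.rivers_vuong_cf(y, x, z)
        by_name = {e.name: e for e in ests}
        assert abs(by_name["endog"].value - 0.5) < 3 * by_name["endog"].robust_se
        # the residual term picks up the endogeneity
        assert by_name["first_stage_residual"].p_two_sided < 1e-6

    def test_sign_agrees_with_2sls(self):
        z, x, y = self._endogenous_probit_data(50_000, rho=0.6, seed=9)
        cf = sp.rivers_vuong_cf(y, x, z)
        tsls, _ = sp.fit_2sls(y, x, z)
        assert np.sign(cf[-2].value) == np.sign(tsls[-1].value)


class TestModerated2SLS:
    @staticmethod
    def _two_strata(phi22_a, phi22_b, n_each, seed):
        base = sp.GenerativeParams(
            version="continuous",
            phi1=0.8,
            phi21=0.7,
            phi22=phi22_a,
            beta_u1=1.0,
            beta_u2=0.6,
            beta_iv=1.0,
            attract_peb1=0.0,
            attract_peb2=0.0,
        )
        a = sp.sample_dataset(base, n_each, seed=seed).to_frame()
        b = sp.sample_dataset(base.replace(phi22=phi22_b), n_each, seed=seed + 1).to_frame()
        a["mod"], b["mod"] = 0, 1
        return pd.concat([a, b], ignore_index=True), base

    def test_study2_contract_shape(self):
        df, _ = self._two_strata(0.4, 0.4, 2000, seed=1)
        res = sp.fit_moderated_2sls(df, "mod", contract="study2")
        assert res.delta2_prime is None
        assert len(res.first_stage_Fs) == 2
        assert res.moderator_name == "mod"

    def test_no_true_moderation_is_null(self):
        rejections = 0
        for seed in range(100):
            df, _ = self._two_strata(0.4, 0.4, 800, seed=10 * seed)
            res = sp.fit_moderated_2sls(df, "mod", contract="study3")
            rejections += res.beta2_prime.p_two_sided < 0.05
        assert rejections / 100 < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)

    def test_recovers_path_difference(self):
        delta_phi22 = 0.5
        df, base = self._two_strata(0.3, 0.3 + delta_phi22, 500_000, seed=3)
        res = sp.fit_moderated_2sls(df, "mod", contract="study2")
        expected = base.beta_u2 * delta_phi22
        assert abs(res.beta2_prime.value - expected) < 3 * res.beta2_prime.robust_se

    def test_constant_moderator_rejected(self):
        df, _ = self._two_strata(0.4, 0.4, 500, seed=2)
        df["mod"] = 0
        with pytest.raises(ValueError, match="constant"):
            sp.fit_moderated_2sls(df, "mod")
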