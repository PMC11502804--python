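"""The synthetic three-study respondent-table generator."""

import numpy as np
import pandas as pd
import pytest

import spillpower as sp
from spillpower.experiment import (
    ExperimentDesignConfig,
    ProbabilityOverflowError,
    validate_experiment_table,
)


@pytest.fixture(scope="module")
def study1_table():
    cfg = ExperimentDesignConfig(n_study1=10_000, n_study2=0, n_study3=0, seed=4)
    return sp.generate_experiment(cfg)


class TestMarginalAnchors:
    def test_participation_rate_near_70_percent(self, study1_table):
        rate = study1_table.peb1_done.mean()
        assert abs(rate - 0.70) < 3 * np.sqrt(0.7 * 0.3 / len(study1_table))

    def test_overall_signing_rate_near_29_percent(self):
        df = sp.generate_experiment(ExperimentDesignConfig(seed=8))
        assert abs(df.peb2_signed.mean() - 0.29) < 3 * np.sqrt(0.29 * 0.71 / len(df))

    def test_domain_specific_signing_rates(self):
        cfg = ExperimentDesignConfig(n_study1=0, n_study2=0, n_study3=30_000, seed=2)
        df = sp.generate_experiment(cfg)
        env = df[df.petition_health == 0].peb2_signed
        health = df[df.petition_health == 1].peb2_signed
        assert abs(env.mean() - 0.272) < 3 * np.sqrt(0.272 * 0.728 / len(env))
        assert abs(health.mean() - 0.38) < 3 * np.sqrt(0.38 * 0.62 / len(health))

    def test_completion_share_among_participants(self, study1_table):
        done = study1_table[study1_table.peb1_done == 1]
        share = (done.peb1_rounds == 30).mean()
        assert abs(share - 0.85) < 3 * np.sqrt(0.85 * 0.15 / len(done))

    def test_nudge_effect_recovered_by_lpm(self, study1_table):
        design = pd.DataFrame(
            {"const": 1.0, "nudge": study1_table.nudge_easy.to_numpy(float)}
        )
        ests = sp.fit_lpm(study1_table.peb1_done.to_numpy(float), design)
        assert abs(ests[1].value - 0.389) < 3 * ests[1].robust_se


class TestSchemaInvariants:
    def test_all_studies_validate(self):
        df = sp.generate_experiment(
            ExperimentDesignConfig(
                n_study1=2000, n_study2=2000, n_study3=2000, seed=6
            )
        )
        validate_experiment_table(df)
        assert set(df[df.study == 1].arm) == {"placebo", "control", "winwin", "doom"}
        assert set(df[df.study == 2].arm) <= {"control", "doom"}
        assert (df.loc[df.study != 2, "difficulty_easy"] == 0).all()
        assert (df.loc[df.study != 3, "petition_health"] == 0).all()

    def test_validator_names_broken_invariant(self, study1_table):
        bad = study1_table.head(50).copy()
        bad.loc[bad.index[3], "peb1_rounds"] = 5
        bad.loc[bad.index[3], "peb1_done"] = 0
        with pytest.raises(ValueError, match="zero rounds"):
            validate_experiment_table(bad)

    def test_infeasible_probability_config_rejected(self):
        with pytest.raises(ProbabilityOverflowError):
            ExperimentDesignConfig(baseline_uptake=0.8, nudge_effect=0.3)


class TestRandomizationNull:
    def test_null_arm_contrasts_reject_at_alpha(self):
        # no injected arm effects: the winwin-vs-control LPM is a true null
        rejections = 0
        n_seeds = 120
        for seed in range(n_seeds):
            cfg = ExperimentDesignConfig(
                n_study1=700, n_study2=0, n_study3=0, seed=1000 + seed
            )
            df = sp.generate_experiment(cfg)
            sub = df[df.arm.isin(["winwin", "control"])]
            design = pd.DataFrame(
                {"const": 1.0, "T": (sub.arm == "winwin").to_numpy(float)}
            )
            ests = sp.fit_lpm(sub.peb1_done.to_numpy(float), design)
            rejections += ests[1].p_two_sided < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rejections / n_seeds - 0.05) < band

    def test_covariates_balanced_across_nudge(self):
        rejections = 0
        n_seeds = 120
        for seed in range(n_seeds):
            cfg = ExperimentDesignConfig(
                n_study1=500, n_study2=0, n_study3=0, seed=5000 + seed
            )
            df = sp.generate_experiment(cfg)
            design = pd.DataFrame(
                {"const": 1.0, "nudge": df.nudge_easy.to_numpy(float)}
            )
            ests = sp.fit_lpm(df.env_values.to_numpy(float), design)
            rejections += ests[1].p_two_sided < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rejections / n_seeds - 0.05) < band


class TestInjectedEffectRecovery:
    def test_arm_effect_recovered_through_estimation_module(self):
        # a doom-arm shift on the latent activation propagates to uptake
        cfg = ExperimentDesignConfig(
            n_study1=10_000,
            n_study2=0,
            n_study3=0,
            arm_effects={"placebo": 0.0, "control": 0.0, "winwin": 0.0, "doom": 0.5},
            seed=12,
        )
        df = sp.generate_experiment(cfg)
        sub = df[df.arm.isin(["doom", "control"])]
        design = pd.DataFrame({"const": 1.0, "T": (sub.arm == "doom").to_numpy(float)})
        ests = sp.fit_lpm(sub.peb1_done.to_numpy(float), design)
        assert ests[1].value > 3 * ests[1].robust_se  # clearly detected
        # latent shift of 0.5 translates to a few probability points of
        # uptake (attenuated by the logit link near the nudged ceiling)
        assert 0.02 < ests[1].value < 0.20

    def test_behavior_on_behavior_path_recovered(self):
        cfg = ExperimentDesignConfig(
            n_study1=30_000, n_study2=0, n_study3=0, peb1_to_peb2=0.8, seed=21
        )
        df = sp.generate_experiment(cfg)
        sub = df[df.arm.isin(["doom", "control"])].copy()
        sub["T"] = (sub.arm == "doom").astype(float)
        sub["IV"] = sub.nudge_easy.astype(float)
        sub["PEB1"] = sub.peb1_done.astype(float)
        sub["PEB2"] = sub.peb2_signed.astype(float)
        dec = sp.decompose_spillover(
            sub, sp.BootstrapSettings(n_resamples=300, seed=1)
        )
        assert dec.beta_prime.value > 3 * dec.beta_prime.robust_se
        assert dec.first_stage_F > 10


class TestFixtureSuite:
    def test_deterministic_and_complete(self, tmp_path):
        m1 = sp.write_fixture_suite(tmp_path / "a", seed=3)
        m2 = sp.write_fixture_suite(tmp_path / "b", seed=3)
        assert [f["sha256_16"] for f in m1["files"]] == [
            f["sha256_16"] for f in m2["files"]
        ]
        assert len(m1["files"]) == 9  # 3 studies x 3 sizes
        smallest = tmp_path / "a" / "study1_n300.csv"
        validate_experiment_table(pd.read_csv(smallest))
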