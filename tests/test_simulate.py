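"""Generator tests: validation, determinism, sharing structure, and
agreement between simulated data and the analytic implied moments."""

import numpy as np
import pandas as pd
import pytest

from twinwell.params import GenerativeParams, MRDoCTruth, ZYGOSITY_GROUPS
from twinwell.simulate import (
    CORE_VARS,
    implied_moments,
    simulate_families,
    simulate_mrdoc_pairs,
)


def cross_twin_matrix(df, cols, zygosities):
    sub = df[df.zygosity.isin(zygosities) & df.role.isin(["twin1", "twin2"])]
    wide = sub.pivot(index="family_id", columns="role", values=cols).dropna()
    x1 = wide.xs("twin1", axis=1, level=1)[cols].to_numpy()
    x2 = wide.xs("twin2", axis=1, level=1)[cols].to_numpy()
    both = np.hstack([x1, x2])
    return np.cov(both.T), len(wide)


class TestParamsValidation:
    def test_negative_variance_path_rejected(self):
        with pytest.raises(ValueError, match="negative variance path"):
            GenerativeParams(spec_a=-0.1, spec_e=0.5)

    def test_latent_shares_above_one_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            GenerativeParams(a_latent=(0.9, 0.9), d_latent=(0.6, 0.0))

    def test_correlation_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="r_a"):
            GenerativeParams(r_a=1.2)

    def test_post_hoc_mutation_caught_by_validate(self):
        # every admissible configuration yields a PSD covariance by
        # construction (congruence of PSD blocks), so the PSD check is
        # defensive; inadmissible correlations are caught directly
        p = GenerativeParams()
        p.r_a = 1.5
        with pytest.raises(ValueError, match="r_a"):
            p.validate()

    def test_unknown_zygosity_label(self):
        p = GenerativeParams()
        with pytest.raises(ValueError, match="zygosity"):
            implied_moments(p, "XX")


class TestDeterminism:
    def test_same_seed_identical_different_seed_not(self):
        p = GenerativeParams.study_mirror(n_pairs=50)
        a = simulate_families(p, seed=3)
        b = simulate_families(p, seed=3)
        c = simulate_families(p, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not a["wellbeing_t2"].equals(c["wellbeing_t2"])

    def test_mrdoc_same_seed_identical(self):
        t = MRDoCTruth()
        pd.testing.assert_frame_equal(
            simulate_mrdoc_pairs(t, 20, 20, seed=5), simulate_mrdoc_pairs(t, 20, 20, seed=5)
        )


class TestFamilyStructure:
    def test_sex_constraints_hold_everywhere(self, mirror_df):
        twins = mirror_df[mirror_df.role.isin(["twin1", "twin2"])]
        wide = twins.pivot(index="family_id", columns="role", values="sex")
        zyg = mirror_df.groupby("family_id")["zygosity"].first()
        mz = zyg.isin(["MZM", "MZF"])
        dos = zyg == "DOS"
        assert (wide.loc[mz, "twin1"] == wide.loc[mz, "twin2"]).all()
        assert (wide.loc[dos, "twin1"] != wide.loc[dos, "twin2"]).all()

    def test_two_twins_and_at_most_two_siblings(self, mirror_df):
        roles = mirror_df.groupby("family_id")["role"].value_counts().unstack(fill_value=0)
        assert (roles["twin1"] == 1).all()
        assert (roles["twin2"] == 1).all()
        if "sibling" in roles:
            assert (roles["sibling"] <= 2).all()

    def test_life_events_nonnegative_and_capped(self, mirror_df):
        p = GenerativeParams.study_mirror()
        for w, cap in zip(("t1", "t2"), p.le_max):
            le = mirror_df[f"life_events_{w}"].dropna()
            assert (le >= 0).all()
            assert (le <= cap).all()


class TestSharingStructure:
    def test_no_familial_variance_gives_null_twin_correlation(self):
        p = GenerativeParams(
            a_latent=(0.0, 0.0),
            loadings=0.0,
            spec_a=0.0,
            spec_e=1.0,
            r_a=0.0,
            r_e=0.0,
            n_pairs=10000,
            missing_t1=0.0,
            missing_t2=0.0,
            sibling_probs=(1.0, 0.0, 0.0),
        )
        df = simulate_families(p, seed=1, include_truth=True)
        for zygs in (["MZM", "MZF"], ["DZM", "DZF", "DOS"]):
            sub = df[df.zygosity.isin(zygs)]
            wide = sub.pivot(index="family_id", columns="role", values="true_wellbeing_t1").dropna()
            r = np.corrcoef(wide["twin1"], wide["twin2"])[0, 1]
            assert abs(r) < 0.03

    def test_univariate_ae_cross_twin_covariance(self):
        # latent a^2 = 0.6, e^2 = 0.4, loading 1, no specifics:
        # MZ cross-twin covariance 0.6, DZ 0.3
        p = GenerativeParams(
            a_latent=(np.sqrt(0.6), np.sqrt(0.6)),
            r_a=0.0,
            r_e=0.0,
            loadings=1.0,
            spec_a=1e-6,
            spec_e=1e-6,
            n_pairs=100000,
            missing_t1=0.0,
            missing_t2=0.0,
            sibling_probs=(1.0, 0.0, 0.0),
        )
        df = simulate_families(p, seed=2, include_truth=True)
        for zygs, expect in ((["MZM", "MZF"], 0.6), (["DZM", "DZF", "DOS"], 0.3)):
            sub = df[df.zygosity.isin(zygs)]
            wide = sub.pivot(index="family_id", columns="role", values="true_wellbeing_t1").dropna()
            cov = np.cov(wide["twin1"], wide["twin2"])[0, 1]
            se = 1.3 / np.sqrt(len(wide))  # rough MC scale for a covariance of ~unit variates
            assert cov == pytest.approx(expect, abs=4 * se)
        # and the analytic oracle agrees
        _, sig = implied_moments(p, "MZF")
        assert sig[0, 4] == pytest.approx(0.6, abs=1e-8)
        _, sig = implied_moments(p, "DZF")
        assert sig[0, 4] == pytest.approx(0.3, abs=1e-8)

    @pytest.mark.parametrize("zyg", list(ZYGOSITY_GROUPS))
    def test_empirical_covariance_matches_implied_moments(self, zyg):
        """Entrywise agreement with the path-traced moments within 4 MC SEs."""
        p = GenerativeParams.recovery_benchmark(
            n_pairs=120000,
            zygosity_weights={z: (1.0 if z == zyg else 0.0) for z in ZYGOSITY_GROUPS},
        )
        df = simulate_families(p, seed=11, include_truth=True)
        cols = [f"true_{v}" for v in CORE_VARS]
        emp, n = cross_twin_matrix(df, cols, [zyg])
        _, sig = implied_moments(p, zyg)
        scale = np.sqrt(np.outer(np.diag(sig), np.diag(sig)))
        mc_se = scale * np.sqrt((1 + (sig / scale) ** 2)) / np.sqrt(n)
        assert np.all(np.abs(emp - sig) < 4 * mc_se)

    def test_sibling_shares_like_dz(self):
        p = GenerativeParams.recovery_benchmark(n_pairs=40000, sibling_probs=(0.0, 1.0, 0.0))
        df = simulate_families(p, seed=13, include_truth=True)
        mz = df[df.zygosity.isin(["MZM", "MZF"])]
        t1 = mz[mz.role == "twin1"].set_index("family_id")["true_resilience_t1"]
        sib = mz[mz.role == "sibling"].set_index("family_id")["true_resilience_t1"]
        common = t1.index.intersection(sib.index)
        cov = np.cov(t1.loc[common], sib.loc[common])[0, 1]
        _, sig_dz = implied_moments(p, "DZF")
        assert cov == pytest.approx(sig_dz[2, 6], abs=4 * 1.4 / np.sqrt(len(common)))


class TestResilienceGeneration:
    def test_life_event_slope_recovered(self):
        """Regressing standardized anxious-depression on standardized life
        events recovers the generating slope within 3 SE."""
        import statsmodels.api as sm

        p = GenerativeParams.recovery_benchmark(n_pairs=20000)
        df = simulate_families(p, seed=17)
        for w, beta in zip(("t1", "t2"), p.beta_le):
            sub = df[[f"anxdep_{w}", f"life_events_{w}"]].dropna()
            z_ad = (sub[f"anxdep_{w}"] - sub[f"anxdep_{w}"].mean()) / sub[f"anxdep_{w}"].std()
            z_le = (sub[f"life_events_{w}"] - sub[f"life_events_{w}"].mean()) / sub[f"life_events_{w}"].std()
            res = sm.OLS(z_ad, sm.add_constant(z_le)).fit()
            # generated AD has variance beta^2 + Var(core); the standardized
            # slope is beta / sqrt(beta^2 + var_core)
            var_core = 0.8**2 + 0.18 + 0.18
            expect = beta / np.sqrt(beta**2 + var_core)
            assert res.params.iloc[1] == pytest.approx(expect, abs=3 * res.bse.iloc[1])


class TestMRDoCPairs:
    def test_no_path_from_instrument_to_outcome(self):
        t = MRDoCTruth(g1=0.0, b2=0.0, b1=0.4)
        df = simulate_mrdoc_pairs(t, 50000, 50000, seed=3)
        s1 = df[df.role == "twin1"]
        cov = np.cov(s1.pgs, s1.outcome)[0, 1]
        assert abs(cov) < 4 / np.sqrt(len(s1))

    def test_instrument_outcome_covariance_path_tracing(self):
        # Cov(S, Y) = b1*g1 + b2 = 0.25
        t = MRDoCTruth(b1=0.3, g1=0.5, b2=0.1, sigma_s2=1.0)
        df = simulate_mrdoc_pairs(t, 100000, 0, seed=4)
        s1 = df[df.role == "twin1"]
        cov = np.cov(s1.pgs, s1.outcome)[0, 1]
        assert cov == pytest.approx(0.25, abs=0.02)

    def test_instrument_sharing_by_zygosity(self):
        t = MRDoCTruth()
        df = simulate_mrdoc_pairs(t, 30000, 30000, seed=5)
        for zyg, expect in (("MZ", 1.0), ("DZ", 0.5)):
            sub = df[df.zygosity == zyg]
            wide = sub.pivot(index="family_id", columns="role", values="pgs")
            cov = np.cov(wide["twin1"], wide["twin2"])[0, 1]
            assert cov == pytest.approx(expect * t.sigma_s2, abs=0.03)

    def test_pair_count_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_mrdoc_pairs(MRDoCTruth(), -1, 10, seed=0)


class TestImpliedMomentsExamples:
    def test_pure_noise_gives_identity(self):
        p = GenerativeParams(
            a_latent=(0.0, 0.0), loadings=0.0, spec_a=1e-12, spec_e=1.0, r_a=0.0, r_e=0.0
        )
        _, sig = implied_moments(p, "MZF")
        assert np.allclose(sig, np.eye(8), atol=1e-12)

    def test_causal_path_enters_cross_trait_covariance(self):
        base = dict(
            a_latent=(np.sqrt(0.5), np.sqrt(0.5)),
            loadings=1.0,
            spec_a=1e-6,
            spec_e=1e-6,
            r_a=0.0,
            r_e=0.0,
        )
        p = GenerativeParams(g_wb_to_res=0.4, **base)
        _, sig = implied_moments(p, "MZF")
        # resilience_t1 = core + 0.4 * wellbeing_t1 => Cov(wb1, res1) = 0.4 * Var(wb1)
        assert sig[0, 2] == pytest.approx(0.4 * sig[0, 0], rel=1e-9)
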