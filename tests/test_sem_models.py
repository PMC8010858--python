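"""Model-zoo tests: the common-pathway ladder, latent decomposition,
longitudinal bivariate models, LRT calibration, and twin correlations."""

import numpy as np
import pandas as pd
import pytest

from twinwell.params import GenerativeParams
from twinwell.sem import (
    FamilyData,
    choose_model_family,
    common_pathway_ladder,
    common_pathway_spec,
    correlation_spec,
    covariance_shares,
    decompose_latent,
    fit,
    longitudinal_bivariate_spec,
    lrt,
    solve_rg_from_share,
    twin_group_correlations,
)
from twinwell.simulate import CORE_VARS, simulate_families

from conftest import ae_pair_frame


def core_frame(df):
    out = df[["family_id", "zygosity", "role", "sex"]].copy()
    for v in CORE_VARS:
        out[v] = df[f"true_{v}"]
    return out


class TestDecomposition:
    def test_final_model_values_give_reported_shares(self):
        gen, env = covariance_shares((0.548, 0.609), (0.452, 0.391), 0.71, 0.93)
        assert gen == pytest.approx(51.2, abs=0.05)
        assert env == pytest.approx(48.8, abs=0.05)

    def test_zero_environmental_correlation_is_all_genetic(self):
        gen, env = covariance_shares((0.5, 0.5), (0.5, 0.5), 0.6, 0.0)
        assert gen == 100.0
        assert env == 0.0

    def test_inverse_solve_for_rg(self):
        rg = solve_rg_from_share(51.2, (0.548, 0.609), (0.452, 0.391), 0.93)
        assert round(rg, 2) == 0.71

    def test_matches_brute_force_latent_matrix(self):
        """Shares agree with direct standardization of the implied 2x2
        latent covariance assembled from random paths."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.uniform(0.3, 0.9, 2)
            e = np.sqrt(1 - a**2)
            rg, re = rng.uniform(-0.9, 0.9, 2)
            cov_a = np.array([[a[0] ** 2, rg * a[0] * a[1]], [rg * a[0] * a[1], a[1] ** 2]])
            cov_e = np.array([[e[0] ** 2, re * e[0] * e[1]], [re * e[0] * e[1], e[1] ** 2]])
            total_cov = (cov_a + cov_e)[0, 1]
            if abs(total_cov) < 1e-3:
                continue
            gen, env = covariance_shares(tuple(a**2), tuple(e**2), rg, re)
            assert gen == pytest.approx(100 * cov_a[0, 1] / total_cov, rel=1e-9)
            assert gen + env == pytest.approx(100.0, abs=1e-9)

    def test_degenerate_zero_covariance_reported(self):
        with pytest.raises(ZeroDivisionError):
            covariance_shares((0.5, 0.5), (0.5, 0.5), 0.0, 0.0)


class TestLadderStructure:
    def test_free_parameter_counts_are_monotone(self):
        ladder = common_pathway_ladder()
        n = {k: s.n_free for k, s in ladder.items()}
        assert n["I"] > n["III"] > n["IV"]
        assert n["I"] > n["II"]
        # dropping D removes: 2 latent d paths + r_d + 8 sex-specific
        # wave-specific d paths = 11, matching the published delta-df
        assert n["III"] - n["IV"] == 11

    def test_model_iv_has_no_d_parameters(self):
        spec = common_pathway_ladder()["IV"]
        assert not any(l.startswith(("d_lat", "ds_", "r_d")) for l in spec.free_labels)

    def test_contradictory_request_rejected(self):
        # D cannot be dropped per-sex only: the flag set has no such state;
        # the builder rejects an unknown configuration via Param duplication
        spec = common_pathway_spec(include_d=False)
        with pytest.raises(KeyError):
            spec.fix(d_lat_wellbeing=0.0)


@pytest.fixture(scope="module")
def fitted():
    params = GenerativeParams.recovery_benchmark(n_pairs=4000)
    df = simulate_families(params, seed=21, include_truth=True)
    frame = core_frame(df)
    spec = common_pathway_spec(
        include_d=False, sex_specific_latent=False, sex_specific_specific=False, sex_specific_means=False
    )
    res = fit(spec, FamilyData.from_frame(frame, CORE_VARS), n_starts=2, seed=0)
    return params, res


class TestCommonPathwayRecovery:
    def test_latent_heritabilities_recovered(self, fitted):
        params, res = fitted
        assert res.converged
        dec = decompose_latent(res)
        assert dec.h2[0] == pytest.approx(0.548, abs=0.04)
        assert dec.h2[1] == pytest.approx(0.609, abs=0.04)
        assert dec.r_g == pytest.approx(0.71, abs=0.05)
        assert dec.r_e == pytest.approx(0.93, abs=0.04)

    def test_shares_sum_to_one_and_hundred(self, fitted):
        _, res = fitted
        dec = decompose_latent(res)
        for t in range(2):
            assert dec.h2[t] + dec.d2[t] + dec.e2[t] == pytest.approx(1.0, abs=1e-6)
        assert dec.genetic_covariance_pct + dec.environmental_covariance_pct == pytest.approx(100.0)

    def test_ace_with_true_c_zero_equals_ae(self, fitted):
        """Fitting with a redundant boundary component reproduces the AE
        -2LL: here ADE with true D = 0 against plain AE."""
        params, res_ae = fitted
        df = simulate_families(params, seed=21, include_truth=True)
        frame = core_frame(df)
        spec_ade = common_pathway_spec(
            include_d=True, sex_specific_latent=False, sex_specific_specific=False, sex_specific_means=False
        )
        res_ade = fit(spec_ade, FamilyData.from_frame(frame, CORE_VARS), n_starts=2, seed=0, compute_se=False)
        assert res_ade.m2ll <= res_ae.m2ll + 1e-3
        d, ddf, p = lrt(res_ade, res_ae, force=True)
        assert p > 0.001  # D never needed when truth is AE


class TestSexEqualityMachinery:
    def test_equating_sexes_when_truth_equal_costs_little(self):
        """No sex differences in truth: the sex-specific model beats the
        equal model by no more than chi-square expectation allows."""
        params = GenerativeParams.recovery_benchmark(n_pairs=3000)
        df = simulate_families(params, seed=23, include_truth=True)
        frame = core_frame(df)
        data = FamilyData.from_frame(frame, CORE_VARS)
        spec_sex = common_pathway_spec(
            include_d=False, sex_specific_latent=False, sex_specific_specific=True, sex_specific_means=True
        )
        spec_eq = common_pathway_spec(
            include_d=False, sex_specific_latent=False, sex_specific_specific=False, sex_specific_means=False
        )
        spec_eq.parent = spec_sex.name
        res_sex = fit(spec_sex, data, n_starts=1, seed=0, compute_se=False)
        res_eq = fit(spec_eq, data, n_starts=1, seed=0, compute_se=False)
        d, ddf, p = lrt(res_sex, res_eq)
        assert p > 0.001


class TestLongitudinal:
    def test_cross_trait_correlation_recovery(self):
        frame = ae_pair_frame(2000, 2000, 0.7, 0.65, 0.71, 0.76, 0.62, 0.19, seed=30, var_names=("res_t1", "wb_t2"))
        spec = longitudinal_bivariate_spec("res_t1", "wb_t2")
        res = fit(spec, FamilyData.from_frame(frame, ["res_t1", "wb_t2"]), n_starts=2, seed=0)
        assert abs(res.estimates["r_a"] - 0.62) < 3 * res.se["r_a"]
        assert abs(res.estimates["r_e"] - 0.19) < 3 * res.se["r_e"]

    def test_power_to_reject_zero_genetic_correlation(self):
        """True rA = 0.6 at 5,000 pairs: dropping rA is rejected at
        p < .001 in every replicate."""
        spec = longitudinal_bivariate_spec("v1", "v2")
        rejections = 0
        for rep in range(6):
            frame = ae_pair_frame(2500, 2500, 0.7, 0.7, 0.71, 0.71, 0.6, 0.2, seed=40 + rep)
            data = FamilyData.from_frame(frame, ["v1", "v2"])
            full = fit(spec, data, n_starts=1, seed=0, compute_se=False)
            null = fit(spec.fix(r_a=0.0), data, n_starts=1, seed=0, compute_se=False)
            rejections += lrt(full, null)[2] < 0.001
        assert rejections == 6

    def test_interior_null_lrt_calibration(self):
        """True rA = rE = 0 (interior null): dropping both gives a
        chi-square(2) statistic -- mean ~ 2 within 15% and roughly uniform
        p-values."""
        spec = longitudinal_bivariate_spec("v1", "v2")
        both = spec.fix(r_a=0.0, r_e=0.0)
        deltas, pvals = [], []
        for rep in range(120):
            frame = ae_pair_frame(150, 150, 0.7, 0.7, 0.71, 0.71, 0.0, 0.0, seed=500 + rep)
            data = FamilyData.from_frame(frame, ["v1", "v2"])
            full = fit(spec, data, n_starts=1, seed=0, compute_se=False)
            null = fit(both, data, n_starts=1, seed=0, compute_se=False)
            d, ddf, p = lrt(full, null)
            deltas.append(d)
            pvals.append(p)
        assert ddf == 2
        assert np.mean(deltas) == pytest.approx(2.0, rel=0.15)
        # uniformity: quartile occupancy within binomial slack
        counts, _ = np.histogram(pvals, bins=4, range=(0, 1))
        assert np.all(counts > 120 / 4 - 3 * np.sqrt(120 * 0.25 * 0.75))

    def test_boundary_null_is_conservative(self):
        """Dropping D when truth has no D: the boundary makes the naive
        chi-square statistic conservative (mean below delta-df)."""
        spec_ade = longitudinal_bivariate_spec("v1", "v2", include_d=True, name="ADE")
        spec_ae = longitudinal_bivariate_spec("v1", "v2", include_d=False, name="AE", parent="ADE")
        deltas = []
        for rep in range(30):
            frame = ae_pair_frame(400, 400, 0.7, 0.7, 0.71, 0.71, 0.5, 0.2, seed=700 + rep)
            data = FamilyData.from_frame(frame, ["v1", "v2"])
            full = fit(spec_ade, data, n_starts=1, seed=0, compute_se=False)
            null = fit(spec_ae, data, n_starts=1, seed=0, compute_se=False)
            deltas.append(max(null.m2ll - full.m2ll, 0.0))
        ddf = spec_ade.n_free - spec_ae.n_free
        assert ddf == 3
        assert np.mean(deltas) <= ddf


class TestTwinCorrelations:
    def test_known_cross_twin_correlation_recovered(self):
        frame = ae_pair_frame(2500, 0, np.sqrt(0.45), np.sqrt(0.45), np.sqrt(0.55), np.sqrt(0.55), 0.0, 0.0, seed=50)
        # univariate view: use v1 only
        tg = twin_group_correlations(frame, ["v1"], groups=("MZF",))
        info = tg.groups["MZF"]
        assert info["available"]
        r = info["cross_twin"].loc["v1", "v1"]
        assert r == pytest.approx(0.45, abs=3 * 1 / np.sqrt(2500))
        lo, hi = info["ci"][("v1", "v1")]
        assert lo < 0.45 < hi

    def test_duplicated_twin_gives_unit_correlation(self):
        rng = np.random.default_rng(51)
        vals = rng.standard_normal(300)
        frame = pd.DataFrame(
            {
                "family_id": np.repeat(np.arange(300), 2),
                "zygosity": "MZF",
                "role": ["twin1", "twin2"] * 300,
                "sex": "F",
                "v1": np.repeat(vals, 2) + rng.standard_normal(600) * 1e-4,
            }
        )
        tg = twin_group_correlations(frame, ["v1"], groups=("MZF",))
        assert tg.groups["MZF"]["cross_twin"].loc["v1", "v1"] > 0.999

    def test_absent_group_marked_unavailable(self):
        frame = ae_pair_frame(50, 0, 0.7, 0.7, 0.7, 0.7, 0.3, 0.1, seed=52)
        tg = twin_group_correlations(frame, ["v1"], groups=("MZF", "DZM"))
        assert not tg.groups["DZM"]["available"]

    def test_equating_dz_and_sibling_correlations_when_truth_equal(self):
        """The no-special-twin-environment constraint: merging the DZ and
        sibling relationship classes does not deteriorate the fit when
        both truly share 0.5 of the A variance."""
        p = GenerativeParams.recovery_benchmark(n_pairs=1500, sibling_probs=(0.0, 1.0, 0.0))
        df = simulate_families(p, seed=53, include_truth=True)
        frame = core_frame(df)
        frame["v1"] = frame["resilience_t1"]
        dzsib = frame[frame.zygosity.isin(["DZM", "DZF"])]
        full_spec = correlation_spec(["v1"], classes=("dz", "sib"), name="sep")
        merged_spec = correlation_spec(["v1"], merge_dz_sib=True, classes=("dz", "sib"), name="merged", parent="sep")
        data = FamilyData.from_frame(dzsib, ["v1"])
        full = fit(full_spec, data, n_starts=1, seed=0, compute_se=False)
        merged = fit(merged_spec, data, n_starts=1, seed=0, compute_se=False)
        d, ddf, pval = lrt(full, merged)
        assert ddf == 1
        assert pval > 0.001


class TestModelFamilyChoice:
    @pytest.mark.parametrize(
        "r_mz, r_dz, expect",
        [(0.48, 0.17, "ADE"), (0.4, 0.2, "ACE"), (0.3, 0.05, "ADE")],
    )
    def test_decision_rule(self, r_mz, r_dz, expect):
        out = choose_model_family(r_mz, r_dz)
        assert out["family"] == expect

    def test_margin_reported(self):
        out = choose_model_family([0.5, 0.4], [0.1, 0.1])
        assert out["margin"] == pytest.approx(0.45 - 0.2)
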