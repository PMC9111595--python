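import numpy as np
import pytest
from scipy.stats import multivariate_normal

from qolped.pedigree import relatedness_matrices
from qolped.simulate import SimConfig, simulate, table3_ace_truth
from qolped.varcomp import (
    ComponentMatrix,
    ModelSpec,
    VarCompError,
    compare,
    family_covariance,
    fit,
    loglik,
    residualize,
    residualize_pedigree,
    summarize,
    summarize_components,
)


class TestResidualize:
    def test_exact_linear_age_effect_removed(self):
        age = np.linspace(20, 60, 100)
        sex = ["M", "F"] * 50
        y = 0.1 * age
        res = residualize(y, age, sex)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_mean_zero_and_missing_preserved(self):
        rng = np.random.default_rng(2)
        y = rng.normal(7, 1, 200)
        y[::7] = np.nan
        res = residualize(y, rng.uniform(20, 70, 200), rng.choice(["M", "F"], 200))
        assert np.isnan(res[::7]).all()
        assert np.nanmean(res) == pytest.approx(0.0, abs=1e-10)

    def test_independent_covariates_keep_variance(self):
        rng = np.random.default_rng(3)
        n = 5000
        y = rng.normal(0, 1, n)
        res = residualize(y, rng.uniform(20, 70, n), rng.choice(["M", "F"], n))
        assert np.var(res) == pytest.approx(np.var(y), rel=0.02)

    def test_constant_sex_warns_but_fits(self):
        with pytest.warns(UserWarning, match="sex is constant"):
            res = residualize([1.0, 2.0, 3.0, 4.0], [20, 30, 40, 50], ["F"] * 4)
        assert np.isfinite(res).all()


class TestFamilyCovariance:
    ACE = {
        "A": ComponentMatrix("A", 0.4, 0.3, 0.2),
        "C": ComponentMatrix("C", 0.5, 0.45, 0.19),
        "E": ComponentMatrix("E", 0.3, 1.1, 0.03),
    }

    def test_single_individual_both_occasions(self, dz_family):
        rel = relatedness_matrices(dz_family, "f1")
        mask = np.zeros((4, 2), dtype=bool)
        mask[2] = True  # one twin, both occasions
        sigma = family_covariance(rel, self.ACE, mask)
        expected = sum(cm.matrix for cm in self.ACE.values())
        assert np.allclose(sigma, expected)

    def test_twin_pair_one_occasion(self, dz_family, mz_family):
        ae = {"A": self.ACE["A"], "E": self.ACE["E"]}
        for ped, factor in ((mz_family, 1.0), (dz_family, 0.5)):
            rel = relatedness_matrices(ped, "f1")
            mask = np.zeros((len(rel.member_order), 2), dtype=bool)
            t = [rel.member_order.index(p) for p in ("t1", "t2")]
            mask[t, 0] = True
            sigma = family_covariance(rel, ae, mask)
            assert sigma[0, 1] == pytest.approx(factor * 0.4)

    def test_spouse_pair_household_only(self, dz_family):
        rel = relatedness_matrices(dz_family, "f1")
        mask = np.zeros((4, 2), dtype=bool)
        sp = [rel.member_order.index(p) for p in ("fa", "mo")]
        mask[sp, 0] = True
        sigma = family_covariance(rel, self.ACE, mask)
        assert sigma[0, 1] == pytest.approx(0.5)  # v_pre(C) alone


class TestLikelihood:
    def test_matches_dense_mvn_oracle(self, three_gen_family):
        """Family-block log-likelihood equals an independently assembled
        dense MVN log-density."""
        est = self.dense_truth = {
            "A": ComponentMatrix("A", 0.35, 0.28, 0.18),
            "C": ComponentMatrix("C", 0.48, 0.47, 0.19),
            "E": ComponentMatrix("E", 0.30, 1.08, 0.03),
        }
        ped = three_gen_family
        means = (7.5, 7.0)
        ll = loglik(ped, est, means)

        # independent dense assembly with explicit loops
        grp = ped.df
        rel = relatedness_matrices(ped, "g1")
        order = rel.member_order
        n = len(order)
        big = np.zeros((2 * n, 2 * n))
        comp_R = {"A": rel.additive, "C": rel.household, "E": np.eye(n)}
        for a in range(n):
            for b in range(n):
                for o1 in range(2):
                    for o2 in range(2):
                        v = 0.0
                        for c, cm in est.items():
                            v += comp_R[c][a, b] * cm.matrix[o1, o2]
                        big[2 * a + o1, 2 * b + o2] = v
        y = grp.set_index("person_id").loc[order, ["qol_pre", "qol_pan"]].to_numpy().ravel()
        mu = np.tile(means, n)
        expected = multivariate_normal(mean=mu, cov=big).logpdf(y)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_missing_cells_are_dropped_not_families(self, dz_family):
        df = dz_family.df.copy()
        df.loc[df["person_id"] == "t1", "qol_pan"] = np.nan
        from qolped.pedigree import Pedigree

        ped = Pedigree(df)
        est = TestFamilyCovariance.ACE
        ll = loglik(ped, est, (7.0, 6.5))
        # oracle: dense density on the 7 observed cells
        rel = relatedness_matrices(ped, "f1")
        mask = ~ped.df[["qol_pre", "qol_pan"]].isna().to_numpy()
        sigma = family_covariance(rel, est, mask)
        y = ped.df[["qol_pre", "qol_pan"]].to_numpy().ravel()
        y = y[~np.isnan(y)]
        mu = np.tile([7.0, 6.5], 4)[mask.ravel()]
        expected = multivariate_normal(mean=mu, cov=sigma).logpdf(y)
        assert ll == pytest.approx(expected, abs=1e-8)


@pytest.fixture(scope="module")
def twin_only_ae_data():
    cfg = SimConfig(
        n_families=5000, seed=17, missing_pre=0, missing_pan=0,
        truth={
            "A": ComponentMatrix("A", 0.5, 0.5, 0.35),
            "E": ComponentMatrix("E", 0.5, 0.5, 0.1),
        },
        p_mother_phenotyped=0.0, p_father_phenotyped=0.0,
        p_sibling=0.0, p_twin_spouse=0.0,
    )
    return simulate(cfg)


class TestFit:
    def test_ae_truth_recovery_on_twin_pairs(self, twin_only_ae_data):
        """AE fit on 5000 MZ+DZ twin pairs recovers the additive variance
        within 10%, and matches the closed-form twin expectations
        r_MZ ~ h2, r_DZ ~ h2/2."""
        res = fit(
            residualize_pedigree(twin_only_ae_data), "AE",
            seed=4, standard_errors=False, n_restarts=0,
        )
        assert res.converged
        assert res.estimates["A"].v_pre == pytest.approx(0.5, rel=0.10)
        assert res.estimates["A"].v_pan == pytest.approx(0.5, rel=0.10)
        h2 = res.standardized["A"]["pre"]
        from qolped.pedigree import classify_pairs
        from qolped.kincor import kinship_correlation_table

        tab = kinship_correlation_table(twin_only_ae_data)
        r_mz = tab[(tab["relationship_type"].isin(["MZF", "MZM"]))
                   & (tab["occasion_pair"] == "pre-pre")]["r"].mean()
        r_dz = tab[(tab["relationship_type"].isin(["DZF", "DZM", "DOS"]))
                   & (tab["occasion_pair"] == "pre-pre")]["r"].mean()
        assert h2 == pytest.approx(r_mz, abs=0.06)
        assert h2 / 2 == pytest.approx(r_dz, abs=0.06)

    def test_zero_variance_errors(self, dz_family):
        df = dz_family.df.copy()
        df["qol_pre"] = 5.0
        df["qol_pan"] = 5.0
        from qolped.pedigree import Pedigree

        with pytest.raises(VarCompError):
            fit(Pedigree(df), "AE", standard_errors=False)

    def test_loglik_monotone_in_nesting(self, twin_only_ae_data):
        ped = residualize_pedigree(twin_only_ae_data)
        ae = fit(ped, "AE", seed=4, standard_errors=False, n_restarts=0)
        ade = fit(ped, "ADE", seed=4, standard_errors=False, n_restarts=0)
        assert ade.loglik >= ae.loglik - 1e-6
        chi2, df, p = compare(ade, ae)
        assert df == 3
        assert chi2 >= 0 and 0 <= p <= 1

    def test_standard_errors_attached(self, twin_only_ae_data):
        small = simulate(SimConfig(
            n_families=400, seed=5, missing_pre=0, missing_pan=0,
        ))
        res = fit(residualize_pedigree(small), "ACE", seed=2, n_restarts=0)
        for cm in res.estimates.values():
            assert cm.se_v_pre is None or cm.se_v_pre > 0


class TestCompare:
    def test_identical_models_chi2_zero(self, twin_only_ae_data):
        ped = residualize_pedigree(twin_only_ae_data)
        ae = fit(ped, "AE", seed=4, standard_errors=False, n_restarts=0)
        chi2, df, p = compare(ae, ae)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_non_nested_raises(self, twin_only_ae_data):
        ped = residualize_pedigree(twin_only_ae_data)
        ace = fit(ped, "ACE", seed=4, standard_errors=False, n_restarts=0)
        ade = fit(ped, "ADE", seed=4, standard_errors=False, n_restarts=0)
        with pytest.raises(VarCompError):
            compare(ace, ade)


class TestSummarize:
    def test_published_component_correlations(self):
        res = summarize_components(table3_ace_truth())
        assert round(res.component_corr["A"], 2) == 0.58
        assert round(res.component_corr["C"], 2) == 0.40
        assert round(res.component_corr["E"], 2) == 0.05

    def test_shares_sum_to_one(self):
        res = summarize_components(table3_ace_truth())
        for occ in ("pre", "pan"):
            assert sum(v[occ] for v in res.standardized.values()) == pytest.approx(1.0, abs=1e-8)
        assert sum(res.covariance_shares.values()) == pytest.approx(1.0, abs=1e-8)

    def test_zero_cov_gives_zero_correlation(self):
        cm = ComponentMatrix("A", 0.5, 0.5, 0.0)
        assert cm.cross_correlation() == 0.0

    def test_zero_variance_gives_nan_not_zero(self):
        cm = ComponentMatrix("A", 0.0, 0.5, 0.0)
        assert np.isnan(cm.cross_correlation())
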