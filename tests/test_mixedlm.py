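import warnings

import numpy as np
import pandas as pd
import pytest

import shuttlegp as sg
from conftest import balanced_single_site
from oracles import direct_reml_loglik, engine_loglik_grid
from shuttlegp.mixedlm import GenomicMixedModel

warnings.filterwarnings("ignore", message=".*does not divide.*")


def _random_tiny_instance(seed):
    """<= 12 records: 2 sites x 3 genotypes x 2 reps, 2 blocks."""
    rng = np.random.default_rng(seed)
    rows = []
    for site in ("A", "B"):
        for rep in (1, 2):
            for gi in range(3):
                rows.append(
                    {
                        "genotype": f"g{gi}",
                        "site": site,
                        "year": 1,
                        "rep": rep,
                        "block": 1 + gi % 2,
                        "y": 5.0
                        + (1.0 if site == "B" else 0.0)
                        + rng.normal(0.0, 1.0) * (1 + gi * 0.3),
                    }
                )
    return pd.DataFrame(rows)


class TestREMLEngineOracle:
    def test_tiny_instances_beat_grid_search(self):
        """On 20 random tiny instances the converged logREML is at least
        the best value found by a direct grid search over the variance
        components (evaluated through the n x n marginal covariance — an
        independent likelihood formula)."""
        for seed in range(20):
            df = _random_tiny_instance(seed)
            model = GenomicMixedModel(df, "y", design="single",
                                      site="A", kernel=None)
            res = model.fit()
            eng = model._engine
            vary = float(np.var(eng.y))
            grid = np.geomspace(0.05 * vary, 3.0 * vary, 20)
            grids = [grid] * (eng.k + eng.n_groups)
            best = engine_loglik_grid(eng, grids)
            assert res.llf >= best - 1e-6

    def test_model2_tiny_matches_direct_optimum(self):
        """Two-site fit agrees with a derivative-free optimiser on the
        direct V-matrix restricted likelihood."""
        from scipy import optimize

        df = _random_tiny_instance(3)
        model = GenomicMixedModel(df, "y", design="two_site", kernel=None)
        res = model.fit()
        eng = model._engine
        z_list = [t.z for t in eng.terms]
        k_list = [None] * len(z_list)

        def neg(log_theta):
            return -direct_reml_loglik(
                eng.y, eng.x, z_list, k_list, eng.resid_group,
                np.exp(log_theta),
            )

        x0 = np.log(np.maximum(res.varcomp.to_numpy(), 1e-4))
        opt = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert res.llf == pytest.approx(-opt.fun, abs=1e-5)

    def test_balanced_identity_matches_anova_estimators(self):
        """Balanced complete one-site data, identity kernel: REML equals
        the classical expected-mean-square estimators."""
        n_geno, n_rep = 10, 4
        df = balanced_single_site(n_geno, n_rep, s2g=3.0, s2e=1.5, seed=5)
        res = sg.fit_model1(df, "y", site="S")
        wide = df.pivot_table(index="genotype", columns="rep", values="y")
        y = wide.to_numpy()
        grand = y.mean()
        ms_g = n_rep * np.sum((y.mean(axis=1) - grand) ** 2) / (n_geno - 1)
        ms_r = n_geno * np.sum((y.mean(axis=0) - grand) ** 2) / (n_rep - 1)
        ms_e = (
            np.sum((y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + grand) ** 2)
            / ((n_geno - 1) * (n_rep - 1))
        )
        assert res.varcomp["residual"] == pytest.approx(ms_e, abs=1e-6)
        assert res.varcomp["genotype"] == pytest.approx(
            (ms_g - ms_e) / n_rep, abs=1e-6
        )

    def test_blup_closed_form_shrinkage(self):
        """Identity kernel, balanced 6 genotypes x 2 reps with variances
        held fixed: the genotype BLUP equals the closed-form shrinkage
        (s2g / (s2g + s2e/2)) * (genotype mean - grand mean)."""
        df = balanced_single_site(6, 2, s2g=2.0, s2e=1.0, seed=6)
        model = GenomicMixedModel(df, "y", design="single", site="S")
        s2g, s2e = 2.0, 1.0
        res = model.fit(fixed_varcomp={"genotype": s2g, "residual": s2e})
        gm = df.groupby("genotype")["y"].mean()
        w = s2g / (s2g + s2e / 2)
        expected = w * (gm - gm.mean())
        got = res.blups["genotype"].reindex(gm.index)
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_record_order_permutation_invariance(self, tiny_phenotypes):
        res1 = sg.fit_model2(tiny_phenotypes, "y")
        shuffled = tiny_phenotypes.sample(frac=1.0, random_state=9)
        res2 = sg.fit_model2(shuffled, "y")
        np.testing.assert_allclose(res1.varcomp, res2.varcomp, atol=1e-10)
        np.testing.assert_allclose(res1.fe_params, res2.fe_params, atol=1e-10)
        assert res1.llf == pytest.approx(res2.llf, abs=1e-10)

    def test_fit_is_deterministic(self, tiny_phenotypes):
        a = sg.fit_model2(tiny_phenotypes, "y")
        b = sg.fit_model2(tiny_phenotypes, "y")
        assert a.llf == b.llf
        assert (a.varcomp == b.varcomp).all()

    def test_null_genetic_variance_collapses_to_boundary(self):
        """Data with no genotype effect: the REML estimate of s2_g follows
        the boundary mixture — a large point mass exactly at the floor and
        a positive part of order s2_e * sqrt(2/(n r)), so essentially all
        estimates are statistically indistinguishable from zero."""
        n_rep = 30
        n_geno, n_r = 100, 3
        at_floor, near_zero = 0, 0
        for seed in range(n_rep):
            df = balanced_single_site(n_geno, n_r, s2g=0.0, s2e=2.0,
                                      seed=100 + seed)
            res = sg.fit_model1(df, "y", site="S")
            ratio = res.varcomp["genotype"] / res.varcomp["residual"]
            if ratio < 1e-6:
                at_floor += 1
            if ratio < 0.15:  # ~3 sd of the half-normal positive part
                near_zero += 1
        assert near_zero >= 0.9 * n_rep
        assert at_floor >= n_rep / 3  # chi-bar-square point mass at zero


class TestModel2:
    def test_interaction_variance_at_floor_when_absent(self, small_config):
        """Simulations with r_g = 1 (no interaction at equal site
        variances) push both gs components to ~0."""
        import dataclasses

        cfg = dataclasses.replace(small_config, genetic_correlation=1.0,
                                  seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mk, truth, ph = sg.simulate_dataset(cfg)
        K = sg.linear_kernel(mk)
        res = sg.fit_model2(ph, "trait", kernel=K)
        assert truth.variance_components_truth["gs_PAL"] == 0.0
        assert res.varcomp["gs_PAL"] < 0.05 * res.varcomp["genotype"]
        assert res.varcomp["gs_SRO"] < 0.05 * res.varcomp["genotype"]

    def test_requires_two_sites(self, tiny_phenotypes):
        single = tiny_phenotypes[tiny_phenotypes["site"] == "A"]
        with pytest.raises(ValueError, match="two site"):
            GenomicMixedModel(single, "y", design="two_site")

    def test_genotype_in_data_but_not_kernel_is_error(self, tiny_phenotypes):
        kernel = sg.GenomicKernel.identity(["g1", "g2", "g3"])  # g4 missing
        with pytest.raises(ValueError, match="absent from the"):
            GenomicMixedModel(tiny_phenotypes, "y", design="two_site",
                              kernel=kernel)


class TestGEBV:
    def test_unphenotyped_genotype_identity_kernel(self, tiny_phenotypes):
        """With an identity kernel an unphenotyped genotype has g_hat = 0,
        so its GEBV is mu (+ site effect)."""
        ids = ["g1", "g2", "g3", "g4", "g9"]
        kernel = sg.GenomicKernel.identity(ids)
        res = sg.fit_model2(tiny_phenotypes, "y", kernel=kernel)
        tab = res.predict_gebv(["g9"], target_site="B",
                               include_interaction=True)
        assert tab.loc["g9", "g"] == pytest.approx(0.0, abs=1e-10)
        expected = res.mu + res.site_effect("B")
        assert tab.loc["g9", "gebv"] == pytest.approx(expected, abs=1e-10)

    def test_translation_equivariance(self, tiny_phenotypes):
        res1 = sg.fit_model2(tiny_phenotypes, "y")
        shifted = tiny_phenotypes.assign(y=tiny_phenotypes["y"] + 11.0)
        res2 = sg.fit_model2(shifted, "y")
        g1 = res1.predict_gebv(target_site="B")["gebv"]
        g2 = res2.predict_gebv(target_site="B")["gebv"]
        np.testing.assert_allclose(g2 - g1, 11.0, atol=1e-6)
        assert (g1.rank() == g2.rank()).all()

    def test_interaction_flag_changes_components(self, tiny_phenotypes):
        res = sg.fit_model2(tiny_phenotypes, "y")
        with_gs = res.predict_gebv(target_site="B", include_interaction=True)
        without = res.predict_gebv(target_site="B", include_interaction=False)
        assert "gs" in with_gs.columns and "gs" not in without.columns
        np.testing.assert_allclose(
            with_gs["gebv"] - with_gs["gs"], without["gebv"], atol=1e-12
        )

    def test_unknown_genotype_rejected(self, tiny_phenotypes):
        res = sg.fit_model2(tiny_phenotypes, "y")
        with pytest.raises(KeyError):
            res.predict_gebv(["nope"], target_site="B")


class TestAdjustedMeans:
    def test_noise_free_limit_equals_plot_means(self):
        """Zero residual and block variance: adjusted means reproduce the
        per-genotype plot means exactly (no shrinkage needed)."""
        df = balanced_single_site(8, 3, s2g=4.0, s2e=1e-12, seed=8)
        adj = sg.blup_adjusted_means(df, "y", site="S")
        gm = df.groupby("genotype")["y"].mean()
        np.testing.assert_allclose(adj.reindex(gm.index), gm, atol=1e-4)

    def test_ranking_preserved_in_balanced_design(self):
        df = balanced_single_site(12, 3, s2g=2.0, s2e=3.0, seed=9)
        adj = sg.blup_adjusted_means(df, "y", site="S")
        gm = df.groupby("genotype")["y"].mean()
        assert (adj.reindex(gm.index).rank() == gm.rank()).all()

    def test_one_value_per_phenotyped_genotype(self, small_dataset):
        _, _, ph = small_dataset
        adj = sg.blup_adjusted_means(ph, "trait", site="SRO")
        assert len(adj) == ph[ph.site == "SRO"]["genotype"].nunique()


class TestSiteCorrelation:
    def test_identical_sites_give_r_one(self):
        df_a = balanced_single_site(10, 2, s2g=3.0, s2e=1.0, seed=10, site="A")
        df_b = df_a.copy()
        df_b["site"] = "B"
        df = pd.concat([df_a, df_b], ignore_index=True)
        r, p = sg.site_correlation(df, "y")
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_independent_sites_give_near_zero(self):
        """r_g = 0: |r| < 0.15 in most replicates at n = 334."""
        ok = 0
        n_rep = 10
        for seed in range(n_rep):
            df_a = balanced_single_site(334, 3, s2g=3.0, s2e=1.0,
                                        seed=300 + seed, site="A")
            df_b = balanced_single_site(334, 3, s2g=3.0, s2e=1.0,
                                        seed=600 + seed, site="B")
            df = pd.concat([df_a, df_b], ignore_index=True)
            r, _ = sg.site_correlation(df, "y")
            if abs(r) < 0.15:
                ok += 1
        assert ok >= n_rep - 1


class TestDescriptiveStats:
    def test_hand_computed(self):
        df = pd.DataFrame(
            {
                "genotype": ["a", "b", "c"],
                "site": "S",
                "year": 1,
                "rep": [1, 1, 1],
                "block": [1, 2, 3],
                "y": [1.0, 2.0, 3.0],
            }
        )
        out = sg.descriptive_stats(df, "y")
        assert out["mean"] == 2.0
        assert out["min"] == 1.0 and out["max"] == 3.0
        assert out["c_var"] == pytest.approx(50.0)

    def test_constant_values(self):
        df = pd.DataFrame(
            {
                "genotype": list("abc"),
                "site": "S",
                "year": 1,
                "rep": 1,
                "block": [1, 2, 3],
                "y": 7.0,
            }
        )
        out = sg.descriptive_stats(df, "y")
        assert out["se"] == 0.0
        assert out["c_var"] == 0.0

    def test_simulated_yield_like_cv(self):
        """A yield-like site (mean 400, large variances) hits its implied
        coefficient of variation at ~1e3 plots."""
        cfg = sg.SimulationConfig(
            n_genotypes=334, n_markers=150, n_chromosomes=4,
            sites=[
                sg.SiteConfig("PAL", 400.0, sigma2_block=900.0,
                              sigma2_residual=7000.0, target_h2_trial=0.55),
                sg.SiteConfig("SRO", 400.0, sigma2_block=900.0,
                              sigma2_residual=7000.0, target_h2_trial=0.55),
            ],
            genetic_correlation=0.6, sigma2_rep=1.0, seed=55,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, _, ph = sg.simulate_dataset(cfg)
        out = sg.descriptive_stats(ph, "trait", site="SRO")
        assert out["n"] >= 1000
        # implied CV: sqrt(2852 + 900 + 7000) / 400 = 26%
        assert 24.0 <= out["c_var"] <= 30.0

    def test_zero_mean_flagged(self):
        df = pd.DataFrame(
            {
                "genotype": list("ab"),
                "site": "S",
                "year": 1,
                "rep": 1,
                "block": [1, 2],
                "y": [-1.0, 1.0],
            }
        )
        with pytest.warns(UserWarning, match="zero mean"):
            out = sg.descriptive_stats(df, "y")
        assert np.isnan(out["c_var"])


class TestSummary:
    def test_summary_contains_key_quantities(self, tiny_phenotypes):
        res = sg.fit_model2(tiny_phenotypes, "y")
        text = res.summary()
        assert "logREML" in text
        assert "Variance components" in text
        assert "gs_B" in text
        assert "H2" in text
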