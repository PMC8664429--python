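import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shuttlegp as sg
from shuttlegp.simulate import SimulationConfig, SiteConfig


def _quiet_dataset(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return sg.simulate_dataset(cfg)


def _two_equal_sites(s2e=5.0, h2=0.8, s2b=0.9):
    return [
        SiteConfig("PAL", 88.2, sigma2_block=s2b, sigma2_residual=s2e,
                   target_h2_trial=h2),
        SiteConfig("SRO", 82.2, sigma2_block=s2b, sigma2_residual=s2e,
                   target_h2_trial=h2),
    ]


class TestGenotypes:
    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SimulationConfig(n_genotypes=40, n_markers=80, seed=5)
        a = sg.simulate_genotypes(cfg)
        b = sg.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.marker_ids == b.marker_ids

    def test_zero_heterozygosity_means_no_zero_codes(self):
        cfg = SimulationConfig(n_genotypes=50, n_markers=120,
                               residual_heterozygosity=0.0, seed=2)
        mm = sg.simulate_genotypes(cfg)
        assert not np.any(mm.values == 0.0)
        assert set(np.unique(mm.values)) <= {-1.0, 1.0}

    def test_heterozygosity_rate_matches_config(self):
        cfg = SimulationConfig(n_genotypes=300, n_markers=400,
                               residual_heterozygosity=0.25, seed=3)
        mm = sg.simulate_genotypes(cfg)
        het = float(np.mean(mm.values == 0.0))
        assert het == pytest.approx(0.25, abs=0.01)

    def test_codes_are_valid(self):
        cfg = SimulationConfig(n_genotypes=30, n_markers=50, seed=4)
        mm = sg.simulate_genotypes(cfg)
        assert set(np.unique(mm.values)) <= {-1.0, 0.0, 1.0}

    def test_allele_frequencies_follow_beta_distribution(self):
        """Realised allele frequencies at large n pass a KS test against
        the configured Beta(1, 3) at alpha = 0.01."""
        cfg = SimulationConfig(n_genotypes=4000, n_markers=10_000,
                               n_chromosomes=12, maf_beta=(1.0, 3.0),
                               ld_rho=0.0, seed=6)
        mm = sg.simulate_genotypes(cfg)
        p_hat = mm.allele_freq()
        stat, pval = stats.kstest(p_hat, stats.beta(1.0, 3.0).cdf)
        assert pval > 0.01

    def test_adjacent_marker_ld(self):
        """First-order dependence: adjacent same-chromosome markers carry
        positive allele correlation near ld_rho."""
        cfg = SimulationConfig(n_genotypes=2000, n_markers=200,
                               n_chromosomes=1, ld_rho=0.6,
                               residual_heterozygosity=0.0,
                               maf_beta=(2.0, 2.0), seed=7)
        mm = sg.simulate_genotypes(cfg)
        cors = []
        x = mm.values
        for j in range(0, 150):
            if np.std(x[:, j]) > 0 and np.std(x[:, j + 1]) > 0:
                cors.append(np.corrcoef(x[:, j], x[:, j + 1])[0, 1])
        assert np.mean(cors) == pytest.approx(0.6, abs=0.08)

    def test_monomorphic_markers_flagged(self):
        cfg = SimulationConfig(n_genotypes=10, n_markers=60,
                               maf_beta=(0.2, 5.0), seed=8)
        with pytest.warns(UserWarning, match="monomorphic"):
            mm = sg.simulate_genotypes(cfg)
        assert mm.monomorphic().any()


class TestTrueValues:
    def test_rg_one_gives_identical_site_effects(self):
        cfg = SimulationConfig(n_genotypes=80, n_markers=100,
                               sites=_two_equal_sites(), genetic_correlation=1.0,
                               seed=9)
        mm = sg.simulate_genotypes(cfg)
        truth = sg.simulate_true_values(mm, cfg)
        u = truth.true_site_effects
        np.testing.assert_allclose(u["PAL"], u["SRO"], atol=1e-10)

    def test_rg_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            SimulationConfig(genetic_correlation=1.5)

    def test_empirical_correlation_tracks_rg(self):
        """r_g = 0.6 at n = 334: the realised correlation of site effects
        stays in [0.5, 0.7] across 50 seeds."""
        ok = 0
        for seed in range(50):
            cfg = SimulationConfig(n_genotypes=334, n_markers=300,
                                   sites=_two_equal_sites(),
                                   genetic_correlation=0.6, seed=900 + seed)
            mm = sg.simulate_genotypes(cfg)
            truth = sg.simulate_true_values(mm, cfg)
            u = truth.true_site_effects
            r = np.corrcoef(u["PAL"], u["SRO"])[0, 1]
            if 0.5 <= r <= 0.7:
                ok += 1
        assert ok >= 45

    def test_null_genetics_warns(self):
        """All-monomorphic markers leave zero effects and warn that the
        heritability target is unreachable."""
        cfg = SimulationConfig(n_genotypes=20, n_markers=10, seed=11)
        mm = sg.simulate_genotypes(cfg)
        mm.values[:] = 1.0  # force monomorphic
        with pytest.warns(UserWarning):
            truth = sg.simulate_true_values(mm, cfg)
        assert truth.variance_components_truth["genotype"] == 0.0
        assert float(truth.true_site_effects.to_numpy().std()) == 0.0

    def test_truth_components_match_targets(self):
        cfg = SimulationConfig(n_genotypes=100, n_markers=200,
                               sites=_two_equal_sites(s2e=6.0, h2=0.75),
                               genetic_correlation=0.5, seed=12)
        mm = sg.simulate_genotypes(cfg)
        truth = sg.simulate_true_values(mm, cfg)
        vc = truth.variance_components_truth
        # V_site (kernel scale) = H2/(1-H2) * s2e/n_rep / mean_diag
        mean_diag = sg.simulate.realised_gblup_scale(mm)
        v_site = 0.75 / 0.25 * 6.0 / 3 / mean_diag
        assert vc["genotype"] == pytest.approx(0.5 * v_site, rel=1e-9)
        assert vc["gs_PAL"] == pytest.approx(0.5 * v_site, rel=1e-9)
        assert vc["residual_SRO"] == 6.0


class TestTrial:
    def test_noise_free_limit(self):
        """With zero block and residual variance every plot value equals
        site mean + replicate shift + true site effect."""
        cfg = SimulationConfig(
            n_genotypes=32, n_markers=60, n_blocks=4,
            sites=_two_equal_sites(s2e=0.0, h2=0.9, s2b=0.0),
            genetic_correlation=0.6, seed=13,
        )
        mm, truth, ph = _quiet_dataset(cfg)
        means = {s.name: s.trait_mean for s in cfg.sites}
        u = truth.true_site_effects
        resid = ph.apply(
            lambda r: r["trait"] - means[r["site"]] - u.loc[r["genotype"], r["site"]],
            axis=1,
        )
        # what is left is the per-replicate shift: constant within site x rep
        groups = ph.assign(resid=resid).groupby(["site", "rep"])["resid"]
        assert float(groups.std().max()) < 1e-10

    def test_one_record_per_genotype_rep_site_year(self, small_config,
                                                   small_dataset):
        _, _, ph = small_dataset
        counts = ph.groupby(["genotype", "site", "year"]).size()
        assert (counts == small_config.n_replicates).all()
        expected = (small_config.n_genotypes * 2 * small_config.n_replicates
                    * len(small_config.years))
        assert len(ph) == expected

    def test_lattice_block_layout(self, small_config, small_dataset):
        _, _, ph = small_dataset
        for _, grp in ph.groupby(["site", "year", "rep"]):
            sizes = grp.groupby("block").size()
            assert len(sizes) == small_config.n_blocks
            assert sizes.max() - sizes.min() <= 1

    def test_residual_variance_within_ten_percent(self):
        """Empirical residual variance per site matches sigma2_residual
        within 10% once there are >= 1e4 plots."""
        cfg = SimulationConfig(
            n_genotypes=1700, n_markers=100, n_blocks=16,
            sites=_two_equal_sites(s2e=4.0, h2=0.5, s2b=0.0),
            genetic_correlation=0.5, sigma2_rep=0.0, seed=14,
        )
        mm, truth, ph = _quiet_dataset(cfg)
        u = truth.true_site_effects
        means = {s.name: s.trait_mean for s in cfg.sites}
        for site in ("PAL", "SRO"):
            sub = ph[ph["site"] == site]
            resid = (
                sub["trait"].to_numpy()
                - means[site]
                - u.loc[sub["genotype"], site].to_numpy()
            )
            assert len(resid) >= 5000
            assert np.var(resid) == pytest.approx(4.0, rel=0.10)

    def test_second_year_shares_genetics_but_not_noise(self):
        cfg = SimulationConfig(
            n_genotypes=48, n_markers=60, n_blocks=4,
            sites=_two_equal_sites(), genetic_correlation=0.6,
            years=[2017, 2018],
            year_effects={"PAL": [0.0, -2.5], "SRO": [0.0, 8.4]},
            seed=15,
        )
        mm, truth, ph = _quiet_dataset(cfg)
        y17 = ph[ph["year"] == 2017]
        y18 = ph[ph["year"] == 2018]
        assert len(y17) == len(y18)
        # year shift moves the site mean, genetics unchanged
        d_sro = y18[y18.site == "SRO"]["trait"].mean() - y17[y17.site == "SRO"]["trait"].mean()
        assert d_sro == pytest.approx(8.4, abs=1.5)
        # residual draws differ between years
        assert not np.allclose(y17["trait"].to_numpy(), y18["trait"].to_numpy())

    def test_phenotype_roundtrip_through_io(self, small_dataset, tmp_path):
        _, _, ph = small_dataset
        from shuttlegp import io

        path = tmp_path / "pheno.csv"
        io.write_phenotypes(ph, path)
        back = io.read_phenotypes(path)
        assert len(back) == len(ph)
        np.testing.assert_allclose(back["trait"].to_numpy(),
                                   ph["trait"].to_numpy())
        assert (back["genotype"].to_numpy() == ph["genotype"].astype(str).to_numpy()).all()


class TestRecovery:
    def test_trial_h2_recovered_by_single_site_fit(self):
        """Target H2 = 0.8 with 3 replicates: the single-site fit's
        repeatability lands in [0.7, 0.9] across seeds."""
        ok = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = SimulationConfig(
                n_genotypes=150, n_markers=200,
                sites=_two_equal_sites(s2e=5.0, h2=0.8),
                genetic_correlation=0.6, seed=500 + seed,
            )
            mm, truth, ph = _quiet_dataset(cfg)
            res = sg.fit_model1(ph, "trait", site="SRO")
            if 0.7 <= res.h2() <= 0.9:
                ok += 1
        assert ok >= n_rep - 1

    def test_site_correlation_pipeline(self):
        """r_g = 0.6 at full scale gives between-site BLUP correlations
        averaging in [0.45, 0.70] (BLUP noise attenuates the correlation
        below r_g by roughly the trial repeatability)."""
        rs = []
        for seed in (16, 17, 18, 19, 20):
            cfg = SimulationConfig(
                n_genotypes=334, n_markers=300,
                sites=_two_equal_sites(), genetic_correlation=0.6, seed=seed,
            )
            mm, truth, ph = _quiet_dataset(cfg)
            r, p = sg.site_correlation(ph, "trait")
            assert p < 0.001
            rs.append(r)
        assert 0.45 <= float(np.mean(rs)) <= 0.70
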