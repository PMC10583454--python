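import numpy as np
import pytest

from sldp_gp.bayesr import (
    BayesRConfig, bayesr_fit, bayesr_predict, summarize_mixture,
)
from sldp_gp.bayesr import BayesRPosterior
from sldp_gp.simulate import GenoSimConfig, simulate_genotypes, simulate_trait

from conftest import make_gm, make_pheno

FAST = dict(iterations=1200, burnin=400, thinning=4)


@pytest.fixture(scope="module")
def fitted(small_panel, small_trait):
    pheno, truth = small_trait
    post = bayesr_fit(small_panel, pheno, BayesRConfig(seed=101, **FAST))
    return post, truth


class TestBayesRFit:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="ascending"):
            BayesRConfig(seed=1, multipliers=(1e-4, 0.0, 1e-3, 1e-2))
        with pytest.raises(ValueError, match="burnin"):
            BayesRConfig(seed=1, iterations=100, burnin=100)

    def test_mixture_proportions_sum_to_one_every_draw(self, fitted):
        post, _ = fitted
        np.testing.assert_allclose(post.pi_draws.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(post.occupancy.sum(axis=1), 1.0, atol=1e-12)
        # per-draw variance shares are a simplex (or all-zero when no
        # SNP is in a non-null component)
        row = post.pvar_draws.sum(axis=1)
        assert np.all((np.abs(row - 1.0) < 1e-9) | (row == 0.0))

    def test_fixed_seed_is_bit_reproducible(self, small_panel, small_trait):
        pheno, _ = small_trait
        cfg = BayesRConfig(seed=202, iterations=300, burnin=100, thinning=2)
        a = bayesr_fit(small_panel, pheno, cfg)
        b = bayesr_fit(small_panel, pheno, cfg)
        np.testing.assert_array_equal(a.effect_mean, b.effect_mean)
        np.testing.assert_array_equal(a.sigma2_g_draws, b.sigma2_g_draws)
        np.testing.assert_array_equal(a.pi_draws, b.pi_draws)

    def test_pure_noise_mass_sits_in_effectively_null_components(self):
        """With no genetic signal the sampler parks SNPs in the zero and
        near-zero variance components and depletes the large-effect one.

        At this marker density the 1e-4 sigma2_g component is statistically
        indistinguishable from the point-mass null, so the two are pooled.
        """
        gm = simulate_genotypes(GenoSimConfig(n_individuals=500, n_snps=1000,
                                              seed=3, chromosomes=2,
                                              ld_decay=0.5))
        rng = np.random.default_rng(9)
        pheno = make_pheno(gm, rng.standard_normal(500))
        post = bayesr_fit(gm, pheno, BayesRConfig(seed=11, iterations=10_000,
                                                  burnin=2_500, thinning=10))
        p_num = summarize_mixture(post).p_num
        assert p_num[0] + p_num[1] > 0.6
        assert p_num[3] < 0.15

    def test_signal_recovery_effects_correlate_with_truth(self, fitted):
        post, truth = fitted
        r = np.corrcoef(post.effect_mean[truth.qtn_indices],
                        truth.qtn_effects)[0, 1]
        assert r > 0.3

    def test_variance_draws_cover_phenotypic_variance(self, fitted, small_trait):
        pheno, _ = small_trait
        post, _ = fitted
        tot = post.genetic_var_draws.mean() + post.sigma2_e_draws.mean()
        assert abs(tot - np.var(pheno.y)) / np.var(pheno.y) < 0.25

    def test_misaligned_samples_rejected(self, small_panel):
        from sldp_gp.genotype import PhenotypeTable
        ph = PhenotypeTable([f"q{i}" for i in range(small_panel.n_samples)],
                            np.zeros(small_panel.n_samples))
        with pytest.raises(ValueError, match="misaligned"):
            bayesr_fit(small_panel, ph, BayesRConfig(seed=1, **FAST))


class TestBayesRPredict:
    def test_zero_effects_give_zero_gebv(self, fitted, small_panel):
        post, _ = fitted
        zeroed = BayesRPosterior(
            effect_mean=np.zeros_like(post.effect_mean),
            occupancy=post.occupancy, sigma2_g_draws=post.sigma2_g_draws,
            sigma2_e_draws=post.sigma2_e_draws,
            genetic_var_draws=post.genetic_var_draws, pi_draws=post.pi_draws,
            pvar_draws=post.pvar_draws, var_weights=post.var_weights,
            train_means=post.train_means, vids=post.vids, config=post.config)
        pred = bayesr_predict(zeroed, small_panel)
        assert (pred.gebv == 0).all()

    def test_single_snp_product(self):
        gm = make_gm(np.array([[0.0], [1.0], [2.0]]))
        pheno = make_pheno(gm, [0.0, 1.0, 2.0])
        post = bayesr_fit(gm, pheno, BayesRConfig(seed=5, iterations=200,
                                                  burnin=50, thinning=1))
        manual = BayesRPosterior(
            effect_mean=np.array([1.0]), occupancy=post.occupancy,
            sigma2_g_draws=post.sigma2_g_draws,
            sigma2_e_draws=post.sigma2_e_draws,
            genetic_var_draws=post.genetic_var_draws, pi_draws=post.pi_draws,
            pvar_draws=post.pvar_draws, var_weights=post.var_weights,
            train_means=np.array([1.0]), vids=post.vids, config=post.config)
        pred = bayesr_predict(manual, gm)
        np.testing.assert_allclose(pred.gebv, [-1.0, 0.0, 1.0])

    def test_matches_dot_product_oracle(self, fitted, small_panel):
        post, _ = fitted
        pred = bayesr_predict(post, small_panel)
        z = small_panel.dosage - post.train_means
        oracle = np.array([z[i] @ post.effect_mean
                           for i in range(small_panel.n_samples)])
        np.testing.assert_allclose(pred.gebv, oracle, atol=1e-10)

    def test_snp_mismatch_is_alignment_error(self, fitted, small_panel):
        post, _ = fitted
        with pytest.raises(ValueError, match="misaligned"):
            bayesr_predict(post, small_panel.subset(snps=range(10)))


class TestSummarizeMixture:
    def test_p_num_sums_to_one(self, fitted):
        post, _ = fitted
        ms = summarize_mixture(post)
        assert ms.p_num.sum() == pytest.approx(1.0)
        assert ms.p_var[0] == 0.0  # null component never explains variance

    def test_degenerate_all_null_chain(self, fitted):
        post, _ = fitted
        forced = BayesRPosterior(
            effect_mean=np.zeros_like(post.effect_mean),
            occupancy=np.column_stack([np.ones(len(post.vids)),
                                       np.zeros((len(post.vids), 3))]),
            sigma2_g_draws=post.sigma2_g_draws,
            sigma2_e_draws=post.sigma2_e_draws,
            genetic_var_draws=post.genetic_var_draws,
            pi_draws=post.pi_draws,
            pvar_draws=np.zeros_like(post.pvar_draws),
            var_weights=post.var_weights, train_means=post.train_means,
            vids=post.vids, config=post.config)
        ms = summarize_mixture(forced)
        np.testing.assert_allclose(ms.p_num, [1, 0, 0, 0])
        assert ms.p_var[0] == 0.0

    def test_variance_share_matches_hand_oracle(self):
        """Two-SNP toy: P_var from frozen assignments equals the
        closed-form share w_j beta_j^2 / sum."""
        w = np.array([0.5, 0.32])
        beta = np.array([2.0, -1.0])
        contrib = w * beta ** 2                      # (2.0, 0.32)
        shares = contrib / contrib.sum()
        pvar = np.zeros((1, 4))
        pvar[0, 2] = shares[0]                       # SNP0 in component 3
        pvar[0, 3] = shares[1]                       # SNP1 in component 4
        post = BayesRPosterior(
            effect_mean=beta,
            occupancy=np.array([[0, 0, 1, 0], [0, 0, 0, 1.0]]),
            sigma2_g_draws=np.array([1.0]), sigma2_e_draws=np.array([1.0]),
            genetic_var_draws=np.array([1.0]),
            pi_draws=np.array([[0.25, 0.25, 0.25, 0.25]]),
            pvar_draws=pvar, var_weights=w, train_means=np.zeros(2),
            vids=["a", "b"], config=BayesRConfig(seed=1))
        ms = summarize_mixture(post)
        np.testing.assert_allclose(ms.p_var,
                                   [0.0, 0.0, 2.0 / 2.32, 0.32 / 2.32])
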