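"""Predict breeding values with GBLUP and BayesR and score them.

GBLUP: u ~ N(0, G sigma2_g) with REML variance components, GEBV from
the mixed-model equations.  BayesR: SNP effects follow a four-component
normal mixture (one point mass at zero), sampled by Gibbs; GEBV are
centered dosages times posterior-mean effects.  Accuracy is the
correlation between GEBV and true breeding values; bias is the slope of
TBV on GEBV (1 = correctly dispersed).
"""

import numpy as np

from sldp_gp import (
    BayesRConfig, GenoSimConfig, accuracy, bayesr_fit, bayesr_predict, bias,
    build_grm, gblup_predict, reml_fit, simulate_genotypes, simulate_trait,
    summarize_mixture,
)

gm = simulate_genotypes(GenoSimConfig(n_individuals=800, n_snps=2000,
                                      chromosomes=4, ld_decay=0.9, seed=4))
pheno, truth = simulate_trait(gm, n_qtn=100, h2=0.5, seed=5)

train = list(range(600))
val = list(range(600, 800))
train_ids = [gm.samples[i] for i in train]
val_ids = [gm.samples[i] for i in val]
ph_train = pheno.reindex(train_ids)
tbv_val = truth.tbv[val]

grm = build_grm(gm)
est = reml_fit(ph_train, grm.submatrix(np.array(train)))
print(f"REML: sigma2_g {est.sigma2_g:.2f} (SE {est.se_sigma2_g:.2f}), "
      f"sigma2_e {est.sigma2_e:.2f}, h2 {est.h2:.3f} (SE {est.se_h2:.3f})")

pred_g = gblup_predict(ph_train, grm, val_ids, variance=est)
print(f"GBLUP : accuracy {accuracy(pred_g.gebv, tbv_val):.3f}, "
      f"bias {bias(pred_g.gebv, tbv_val):.3f}")

post = bayesr_fit(gm.subset(samples=train), ph_train,
                  BayesRConfig(seed=6, iterations=3000, burnin=1000,
                               thinning=5))
pred_b = bayesr_predict(post, gm.subset(samples=val))
print(f"BayesR: accuracy {accuracy(pred_b.gebv, tbv_val):.3f}, "
      f"bias {bias(pred_b.gebv, tbv_val):.3f}")

ms = summarize_mixture(post)
print("\nBayesR mixture (components 0, 1e-4, 1e-3, 1e-2 x sigma2_g):")
print("  P_num (% of SNPs):     ", np.round(100 * ms.p_num, 2))
print("  P_var (% of gen. var): ", np.round(100 * ms.p_var, 2))
print("a sparse trait parks most SNPs in the null component and most "
      "variance in the largest one")
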