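# Methods

This note documents the models implemented in `sldp_gp`, the synthetic
data the package validates them on, the numerical choices that matter,
and the limits of what the desk-scale experiments show.

## Marker selection

### Pairwise LD

r² between two markers is the squared Pearson correlation of their
dosage vectors after per-SNP mean imputation of missing calls
(composite LD — no phase information is used). A constant (monomorphic)
vector has undefined LD; callers receive 0 so such markers never trigger
a removal. The removal comparison carries an absolute slack of 1e-9 so
that r² = 1 computed in floating point (a duplicated column evaluates to
1 − O(1e-15)) is still removed at threshold 1; at every other threshold
the slack is far below the resolution of the grid.

### Sliding-window pruning (LDP) and the selective variant (SLDP)

Pruning runs per chromosome over a window of `window_snps` markers
(default 500) advancing by `step_snps` (default 200) across the list of
markers still alive. Within a window, pairs are scanned by increasing
index; when a pair reaches the r² threshold, the member with the lower
MAF is removed (ties remove the higher index). Removals are immediate:
a removed marker is skipped in all later pairs and windows. This single
forward pass mirrors the behaviour of the standard pruning tools; it
guarantees that no *evaluated* window retains a violating pair at the
moment of evaluation, not that the final set is globally pair-free — an
intentional property of windowed pruning.

SLDP adds a retention rule with three cases: important/important pairs
remove neither member; important/ordinary pairs remove the ordinary one;
ordinary/ordinary pairs follow the MAF rule. With an empty important set
SLDP is exactly LDP. The important set is
`{P < p_threshold} ∪ {r² > 0.90 with any member of that set}`; the
partner search is limited to a 1-Mb window around each hit (the rule
itself does not bound the search; the bound keeps the scan linear in
practice and is configurable via `link_window_bp`).

Single-window instances are verified against a brute-force oracle that
scans all pairs with an independently computed correlation matrix.

## Mixed-model GWAS

Each SNP is tested in `y = Xβ + αb + g + e` with `g ~ N(0, G σ²g)`.
Variance components are estimated once under the SNP-free null model and
reused for every SNP (P3D); with them fixed, each SNP test reduces to
generalized least squares on the eigenbasis of G, vectorized over SNPs,
with a two-sided 1-df Wald χ² P-value. Exact per-SNP REML and
leave-one-chromosome-out GRMs are deliberately not the default: the
whole-genome GRM enters the model as written, and the calibration
experiment (below) shows the P3D scan holds its nominal size at the
sample sizes used here. Monomorphic SNPs are reported untested with
missing statistics. Categorical covariates (e.g. year, season) expand to
intercept + full-rank indicator contrasts; simulated traits fit an
intercept only.

Derived summaries: the nine-threshold significance gradient (10⁻⁴ …
10⁻²) with strict `P < t` selection; QTL-covered regions as half-open
[pos − 50 kb, pos + 50 kb) intervals clipped at zero and merged when they
touch; the simulated-trait false-positive rate (detections that are
neither QTN nor in r² ≥ 0.50 with one, over all detections); and
top/bottom fractions of the P-ranking (untested SNPs rank last).

## GRM, REML, GBLUP

The GRM uses per-SNP standardization (`z = (x − 2p)/√(2p(1−p))`,
`G = ZZ'/m`), matching the convention of the GWAS tooling this package
mirrors; monomorphic SNPs are skipped and the SNP count reported. A
VanRaden-weighted variant was considered and omitted — it changes G by a
scalar-like reweighting that REML absorbs.

REML for `y = Xβ + u + e` with a single genetic variance is solved by
profiling: on the eigenbasis of G the restricted likelihood is a smooth
one-dimensional function of δ = σ²e/σ²g, maximized by a 41-point coarse
grid on log δ ∈ [−14, 14] followed by bounded Brent refinement
(xatol 1e-10). This finds the same optimum an average-information
iteration would, cannot diverge, and reuses one eigendecomposition for
REML, the association scan, and prediction. Estimates within half a log
unit of the bounds are flagged as boundary fits (h² ≈ 0 or 1). Standard
errors come from inverting the 2×2 Fisher information of (σ²g, σ²e)
computed with the REML projection matrix; the h² standard error is
delta-method, and is labelled as such.

GEBV for any set of individuals (phenotyped or not) are
`û = σ²g G[pred, train] V⁻¹ (y − Xβ̂)` with `V = σ²g G_tt + σ²e I`. On
every fixture this agrees with ridge SNP-BLUP (λ = m σ²e/σ²g) to 1e-6,
which is the implementation's main correctness oracle.

## BayesR

Single-site Gibbs over component indicators, effects, mixture weights
(Dirichlet(1,1,1,1)), σ²g, and σ²e. Component variances are multiples
(0, 10⁻⁴, 10⁻³, 10⁻²) of the *current* σ²g draw; σ²g and σ²e carry
scaled inverse-χ² priors with 4 df and scale set so each prior mean is
half the phenotypic variance. Genotypes are centered (not scaled) in the
sampler; fixed effects are pre-absorbed by projecting y and the genotype
design onto the covariate-orthogonal space. The sweep is numba-compiled
with a residual-update scheme (two dot products per SNP per iteration)
and is bit-reproducible for a fixed seed. Defaults are desk-scale:
10,000 iterations, 2,500 burn-in, thinning 10; chains used in tests are
shorter and stated there.

Two identifiability caveats, both consequences of desk-scale marker
counts rather than implementation choices:

* σ²g is a *scale* parameter (the mixture variances are multiples of
  it), identified only through which components markers occupy. When a
  trait's per-QTN variance share exceeds the largest multiplier (fewer
  than ~100 effective QTN), σ²g systematically overshoots the realized
  genetic variance. The posterior therefore also records per-draw
  realized genetic variance Var(g) (g = y − e inside the chain), whose
  sum with σ²e tracks the phenotypic variance; the variance-envelope
  test uses that identified decomposition.
* At a few thousand markers the 10⁻⁴σ²g component is statistically
  indistinguishable from the point-mass null (its per-SNP Bayes factor
  differs from 1 by O((τ z'z/σ²e)²)), so under a pure-noise phenotype
  the chain wanders between the two effectively-null components rather
  than concentrating on the point mass alone. The noise test asserts
  the identified property: the combined mass of the two smallest
  components dominates and the large-effect component is depleted. The
  near-total null occupancy reported for sequence-scale panels emerges
  only in the m ≫ n regime, where the collective absorption of tiny
  effects is constrained by the data.

P_num is the posterior-mean fraction of SNPs per component; P_var is the
posterior-mean per-draw share of Σ 2p(1−p)ε² per component, with the
null component contributing zero.

## Synthetic data

The genotype generator draws two haplotypes per individual from a
first-order Markov chain: at each locus the allele is copied from the
previous locus with probability `ld_decay` (default 0.9), else drawn at
the locus frequency; the chain restarts at chromosome boundaries. Target
allele frequencies are uniform with MAF in [0.05, 0.5] and random
orientation. This reproduces the one property marker selection depends
on — block-wise LD decaying geometrically with distance — and exposes it
as a single parameter. It does **not** reproduce coalescent allele
frequency spectra, variable recombination, population structure, or
relatedness gradients; the copying chain also compresses realized
frequencies toward intermediate values. Passing tests therefore
demonstrate the machinery's correctness and the direction of the
selection effects, not performance on any real population.

Traits are strictly additive: QTN drawn uniformly without replacement
from markers with MAF ≥ 0.05, effects from N(0, 1), TBV = dosage ×
effects, and residual variance Var(TBV)(1 − h²)/h² so the realized
heritability matches the target in expectation. The truth object stores
QTN, effects, TBV, and realized h².

## Benchmark experiment conditions

Chosen once as desk-scale mirrors of the study design; the sizes keep
each experiment in minutes on one CPU.

* **Heritability recovery** — 20 replicates of 1,000 individuals × 5,000
  SNPs, 100 QTN, at h² 0.15 and 0.30; mean REML ĥ² within ±0.05.
* **Scan calibration** — one 300 × 200 low-LD panel scanned against 500
  permutations of a noise phenotype; the pooled rejection rate at
  α = 0.05 is compared with the 95% binomial interval at N = 500 (a
  conservative interval given the larger pooled count), and the pooled
  P-values with uniformity (Kolmogorov distance < 0.05).
* **SLDP by architecture** — 800 individuals (600 train / 200
  validation) × 2,500 SNPs, h² 0.30. The important set is the
  truth-based one (QTN plus r² > 0.90 partners); the pruning r² is
  chosen per replicate by five-fold CV in training over {0.10, 0.50,
  0.90}, mirroring the parameter-optimization protocol. With 100 QTN the
  SLDP panel beats the unpruned panel in essentially every replicate
  (double-digit percentage gains); with 1,250 of 2,500 loci causal the
  gain loses statistical sign (small residual positive gains remain —
  at this scale a truth-informed panel still concentrates the GRM
  slightly, consistent with the near-zero gains of the infinitesimal
  setting).
* **BayesR vs GBLUP** — 10 replicates of 800 × 2,000, 100 QTN, h² 0.50;
  mean BayesR validation accuracy is at least GBLUP's.

## Degenerate inputs and tie-breaks

QC removes individuals first, then recomputes SNP statistics; emptying
either axis is an error. Panel extraction resolves equidistant
candidates toward the lower position and uses each source SNP once.
Grid-search ties break by higher accuracy, then smaller panel, then
larger P threshold; cells with empty panels are recorded as failed and
excluded from the argmax. Cross-validation folds are simple random
partitions differing in size by at most one; folds too small for a
within-fold correlation (leave-one-out) fall back to the pooled
correlation over held-out predictions. The pipeline writes its manifest
with sorted keys, fixed float rounding, and no timestamps, so a fixed
configuration yields byte-identical manifests.

## Known limitations

Real-data formats are supported (VCF, PLINK text, dosage tables) but the
validation is entirely simulation-based. The GWAS scan has no LOCO
option wired in, BayesR has no scaled-genotype default, and neither
dominance nor epistasis is modelled anywhere. Desk-scale chain lengths
are adequate for the tested contrasts but short of publication-grade
posterior summaries.
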