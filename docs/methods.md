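# Methods

This note documents the statistical models implemented in `polygxe`, the
conventions adopted where the methods leave details open, what the synthetic
data generator does and does not emulate, and the study conditions used by
the packaged experiments.

## The testing problem

Given n subjects with a trait Y (continuous or binary), a single exposure E,
covariates X, and L biallelic SNP dosages G (counting minor alleles, 0/1/2),
the null hypothesis is that no SNP interacts with E:
H₀: β_GE,1 = … = β_GE,L = 0 in the per-SNP generalized linear model

    g[E(Y)] = β₀ + β_G·G_l + β_E·E + β_GE,l·G_l·E + β_X′X ,

with identity link for gaussian traits and logit link for binary traits.
Single-marker scans test each β_GE,l separately and pay an L-fold
multiplicity price; the polygenic tests below aggregate all L signals into
one statistic.

## ADABF

**Pruning and screening.** SNPs in high LD are first pruned with a windowed
variance-inflation-factor rule (window 50 SNPs, step 5, VIF = 1/(1−R²) ≤ 2;
R² from regressing each SNP on the others in the window, recomputed after
every single removal, never across a chromosome boundary). Remaining SNPs
are screened on marginal association (trait ~ SNP + covariates) at P < 0.05.
Screening on the *marginal* statistic does not bias the subsequent
interaction test under the null, so the whole sample is reused.

**Scale conventions.** A continuous exposure is rescaled to [0, 1]
(min → 0, max → 1, computed on the analysis sample after listwise deletion),
so the interaction regressor G·E lives on the same 0–2 scale as a dosage.
On the ADABF path a continuous trait is standardized to mean 0, SD 1
(sample SD, n−1), which puts the default prior below on the right scale.
The GRS and single-marker paths keep the raw trait so coefficients stay in
trait units.

**Bayes factors.** Each screened SNP's interaction MLE β̂ with estimated
variance V̂ gives the Wakefield approximate Bayes factor under a N(0, W)
effect prior:

    log BF = ½·log( V̂/(V̂+W) ) + β̂²·W / ( 2V̂(V̂+W) ) ,

computed in log space (finite up to |β̂|/√V̂ ≈ 40 and beyond). The default
W = 0.2² = 0.04 says 95% of standardized interaction effects (or log odds
ratios) lie in ±0.4. Because the test compares observed BFs with resampled
BFs under the *same* prior, conclusions are insensitive to W — the test
suite verifies rank correlation > 0.9 of overall P-values across
W ∈ {0.01, 0.04, 0.09}.

**Adaptive combination and resampling null.** The log-BFs are sorted in
decreasing order (ties broken by original SNP index, making the selected set
a well-defined prefix) and accumulated into S_k = Σ_{l≤k} log BF_(l). The
null ensemble draws B coefficient vectors from N(0, V) with
V_ij = R_ij·√(V̂_i·V̂_j), where R is the Pearson correlation of the screened
dosages over pairwise-complete samples (the correlation of interaction Wald
statistics is well approximated by the genotype correlation). V is repaired
to positive semidefiniteness by clipping eigenvalues at 1e-8 and rescaling
to the original diagonal; a matrix with an eigenvalue below −1e-6 (relative)
is rejected as invalid. Each draw is converted entry-wise to log-BFs and its
own score profile.

Per-k P-values are p_k = (1/B)·#{b : S_k^(b) ≥ S_k}; each resample's own
profile is ranked against the other B−1 (computed by one sort per k, exactly
equivalent to the double sum). The overall P-value is the fraction of
resamples whose min-over-k P is at most the observed min-P. One consequence
of the leave-one-out convention is a resolution floor: the resample that is
the maximum of some score column has min-P exactly 0, so the overall P can
never drop below (#distinct column argmaxes)/B — irrelevant at the 0.05 and
0.01 decision levels used here, and the conventional "< 1/B" display is kept
for the boundary case. B = 1000 suffices for simulation decisions at 0.05;
real analyses use B = 10⁵.

**Pinpointing SNPs.** From the same resamples,
FP_(k) = (1/B)·Σ_b Σ_l I(BF_l^(b) ≥ BF_(k)) estimates the expected count of
null BFs at least as large as the k-th observed one, FDR_(k) = FP_(k)/k, and
the selection is the largest k with FDR_(k) < 5%.

## GRS-M and GRS-I

Both scores are pre-scaled sums Σ w_l·G_il·I(select-P_l < P_t) over ten
thresholds P_t ∈ {10⁻⁴, 2.5·10⁻⁴, 5·10⁻⁴, 10⁻³, 2.5·10⁻³, 5·10⁻³, 0.01,
0.025, 0.05, 0.1}, rescaled by (number of available SNPs)/(Σ|w_l| of
available SNPs) so the score reads as a calibrated allele count.
"Available" is evaluated **per subject** (selected and non-missing); a
subject with no available SNP scores 0. The rescaled score is invariant to
multiplying all weights by a positive constant.

GRS-M takes w_l = β̂_G,l and select-P from the marginal scan on the full
sample — marginal selection is independent of the interaction statistic
under H₀, so no splitting is required. GRS-I takes w_l = β̂_GE,l and
select-P from an interaction scan on a random half (odd n puts the extra
subject in training) and builds/tests the score on the held-out half; the
splitting preserves its type I error at the cost of power, which is why it
is consistently the weakest of the three polygenic tests.

At each threshold the score enters `Y ~ GRS + E + GRS·E + X`; the combined
statistics M* and I* are min(1, 10·min_t P_t). Thresholds that select no
SNP are skipped but still count in the multiplier (conservative), and
per-threshold type I error summaries use only replicates where the
threshold was evaluated.

## GLM engine

Gaussian scans are exact ordinary least squares, computed for all SNPs at
once by residualizing the SNP-specific columns on the shared block
(Frisch–Waugh); P-values use the t reference with residual degrees of
freedom (indistinguishable from the normal at GWAS sample sizes). Binomial
scans use a batched IRLS Newton solver (tolerance 1e-8 on the step, max 50
iterations, linear predictor clipped at ±30); P-values use the normal Wald
reference. Degenerate designs (monomorphic SNP, constant interaction
column, condition number > 1e10) and separated or non-converged logistic
fits (|log-odds| > 30) are flagged and excluded downstream, never imputed.
Missing dosages are handled complete-case per SNP.

## Synthetic data generator

The generator emulates the study conditions of a biobank-scale G×E scan:

- **Genotypes**: MAF ~ U(0.05, 0.5) per SNP, dosages Binomial(2, MAF)
  (Hardy–Weinberg). Optional LD: each of two latent AR(1) Gaussian
  haplotypes (parameter `ld_rho`) is thresholded at the MAF quantile, which
  preserves single-SNP HWE while correlating neighbours. Default ld_rho = 0.
- **Exposure**: independent Bernoulli(0.248) — the smoking prevalence of the
  cohort the method was developed on.
- **Traits**: binary from a logit model with intercept log(0.05/0.95)
  (5% prevalence; prints as −2.94) plus Σ_d β_GE,d·G_d·E; continuous as the
  same linear predictor plus standard normal noise. D interacting SNPs are
  redrawn each replicate; |β_GE| is uniform on a configurable interval with
  exactly ⌈D/2⌉ positive signs. With main effects present, 1.5·D causal SNPs
  are placed: the first D/2 main-only, the middle D/2 both, the last D
  interaction-only; β_G signs are half positive, and among "both" SNPs the
  sign concordance β_G·β_GE > 0 holds for exactly half.

**What it does not emulate**: real LD block structure, allele-frequency
spectra with rare variants, population stratification, covariate
confounding, exposure–genotype correlation, or case–control ascertainment.
Passing tests therefore demonstrate the statistical properties of the tests
under clean polygenic architectures, not robustness to those complications.

## Desk-scale study conditions

The packaged experiments shrink the full-scale design (n = 16555, L ≈ 7650
screened SNPs, 10000 replicates, B = 1000) to desk scale: n = 2000, L = 300,
1000 replicates with B = 500 for type I error, 500 replicates for power.
Type I error is scale-free, so the null studies use the reference effect
setup unchanged (D = 0).

For power studies the per-SNP interaction z-score scales as |β|·√n, so
keeping the reference effect intervals ([0.05, 0.07] for a standardized
continuous trait) at n = 2000 would leave every method at the null and the
comparison uninformative. The `*_scaled` effect presets therefore multiply
the interval bounds by √(16555/2000) ≈ 2.88, preserving each causal SNP's
non-centrality (interaction z ≈ 2.4, marginal screening z ≈ 1.2 for the
smaller gaussian preset) at the full-scale operating point. One distortion
remains and cannot be removed at L = 300: the screened panel holds ~15 null
SNPs instead of ~380, so the causal fraction among screened SNPs is far
higher than at full scale. This inflates the *adaptive* test's power
relative to the GRS tests — ADABF hunts its signal among far fewer noise
BFs — and the full-scale ranking "GRS-M above ADABF when main effects are
present" is not expected to survive desk scaling, while the no-main-effect
ranking (ADABF above GRS-M above GRS-I) does.

## Numerical conventions and edge cases

- Minor-allele orientation is decided per SNP from the loaded sample; ties
  at frequency exactly 0.5 keep the file's A1 allele.
- QC defaults: call rate ≥ 0.95, Hardy–Weinberg 1-df chi-square P ≥ 5.7e-7,
  MAF ≥ 0.01; a monomorphic SNP has HWE P = 1 by convention.
- VIF pruning removes the highest-VIF SNP first; ties break by lower MAF,
  then higher index. Windows with more SNPs than samples use
  ridge-stabilized least squares (λ = 1e-8).
- An empty screened set yields an overall P of 1 and an empty selection; a
  constant exposure or constant score aborts the affected test with an
  explicit signal rather than a spurious number.
- All resampling is driven by a single user seed through
  `numpy.random.default_rng`; identical seeds give bit-identical results.
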