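# Methods

`ctenopop` re-implements, at desk scale, the population-genomic analysis
chain used to study native and introduced grass carp (*Ctenopharyngodon
idella*): SNP quality filtering, diversity and differentiation statistics,
isolation-by-distance, maximum-likelihood admixture, approximate Bayesian
computation (ABC) for tracing introduction origins, three selection scans,
and sliding-window genomic-island detection.  Every stage runs on data from
the package's own synthetic-cohort generator, so the full pipeline is
testable without any sequencing archive.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## The synthetic cohort

The generator (`ctenopop.synthetic`) emulates the sampled design of the
study system: 197 diploid individuals from nine locations —

* six native locations in three river systems: Nenjiang (Heilongjiang),
  Hanjiang / Jiujiang / Shishou (Yangtze), Zhaoqing / Vietnam (Pearl);
* Nenjiang is individual-heterogeneous: half its sample is purely native
  Heilongjiang, the other half carries almost entirely Yangtze/Pearl
  ancestry, so the location mean lands near 49/44/8 percent
  Heilongjiang/Yangtze/Pearl and exactly ten individuals exceed the 50%
  foreign-ancestry removal threshold;
* three introduced locations (Malaysia, India, Nepal) founded from an
  admixture of the Yangtze and Pearl clusters through a founder bottleneck.

Allele frequencies drift along a population graph under the
Balding–Nichols construction: a child frequency is Beta-distributed with
mean equal to the parent frequency and variance `c·p·(1−p)`.  The branch
parameter `c` equals the expected F_ST across the branch, which supplies
free analytic oracles (a two-population design with `c = 0.05` must
measure Weir–Cockerham θ ≈ 0.05).  A founder bottleneck of size `Nm`
lasting `db` generations adds the Wright–Fisher drift increment
`c_f = 1 − (1 − 1/(2·Nm))^db`; the default introduced-population
bottleneck (`Nm = 100`, `db = 50`, `c_f ≈ 0.22`) places native–introduced
θ in the 0.11–0.25 band and native–native θ in the 0.002–0.05 band, the
ranges characteristic of the system.  Annual mean temperature is an affine
function of latitude plus N(0, 0.3 °C) noise, reproducing the near-perfect
temperature–latitude collinearity of the sampling sites (R² > 0.99).

Selected loci are planted on the neutral background with persisted truth
labels: *clinal* loci shift each population's logit frequency by
`slope × standardized latitude` (default slope 2 over the ~46° latitude
span); *divergent* loci re-run the drift graph with branch variance
inflated (default ×5); *balanced* loci draw every population's frequency
from Beta(80, 80) around 0.5.  Loci are grouped onto RAD tags (truncated
Poisson SNPs-per-tag, mean 0.61, within-tag span < 100 bp) and placed on a
24-scaffold panel spanning 9.6–19.1 Mb, so window scans and tag-level
filters operate on realistic coordinates.

What the generator does **not** emulate: sequencing depth and genotyping
error, linkage disequilibrium beyond co-location on a tag (loci are
exchangeable draws), non-equilibrium migration, and selection acting on
haplotypes rather than single sites.  Passing tests therefore demonstrate
statistical correctness of the estimators and calibration of the decision
rules under the stated frequency models — not robustness to artifacts of
real RAD data.

## Filtering cascade

Stages in study order, each a pure projection of the genotype matrix:
per-location call rate strictly > 0.7; removal of whole RAD tags carrying
any SNP with more than two alleles **or** observed heterozygosity > 0.5
(the OR combination is deliberate: a multi-allelic SNP cannot be a valid
biallelic dosage column and is an independent paralogy signal; the literal
AND is available by flag); retention of the lowest-coordinate SNP per tag;
and a per-location Hardy–Weinberg exact test at α = 0.01, removing loci
deviating in at least one location (the inclusive reading matches the
purpose of purging null-allele tags; an `exactly_one` rule is provided).
The HWE test is the conditional enumeration (Levene/Haldane) test — no
chi-square approximation, since location samples are ~20 individuals —
with the two-sided p-value summing all heterozygote counts whose
conditional probability does not exceed the observed one.

The demographic-inference subset adds pooled MAF strictly > 0.05, overall
missingness ≤ 0.05, and greedy genome-order LD pruning that drops a
candidate when its genotype R² with any recently kept locus reaches 0.05.
The pruning direction is "remove high-R² loci": retaining a low-LD marker
panel is the stated goal of that step, although the source text's wording
inverts the inequality.

## Diversity, differentiation, distance

All differentiation uses the Weir–Cockerham variance-components estimator
θ, with multi-locus values as the ratio of summed components; a single
implementation serves the diversity tables, the pairwise matrix, the ABC
summary statistics, and the window scans, keeping every stage coherent.
Pairwise significance is a permutation test (individuals permuted between
the pair, p = (1 + #{θ* ≥ θ}) / (n_perm + 1)) with Bonferroni correction
across pairs.  H_E uses the unbiased `2p̂(1−p̂)·2n/(2n−1)`; per-site
nucleotide diversity for a biallelic site equals that quantity.  Gene flow
is read from F_ST ≈ 1/(4Nm + 1).  Isolation-by-distance correlates
linearized F_ST/(1−F_ST) with great-circle distance (planar available by
flag) through a Mantel test with simultaneous row/column permutation,
reporting R² = r².  Trees are neighbor-joining on Nei's standard distance
(gene-identity terms averaged over loci) with bootstrap-over-loci
bipartition supports; PCA uses the classic `√(p̂(1−p̂))` column scaling
with mean imputation of missing entries.

## Admixture

The ancestry model is the standard binomial mixture: dosage `g_il` has
log-likelihood `Σ g·ln(Σ_k q_ik f_kl) + (2−g)·ln(Σ_k q_ik (1−f_kl))` over
row-stochastic Q and cluster frequencies F.  Fitting is EM with restarts
(default 5; the likelihood trace is monotone by construction and asserted
in tests).  Model order is chosen by masked-entry cross-validation:
a random fraction of non-missing entries is hidden, the model refit, and
the hidden dosages scored by squared deviation from `2·Σ_k q_ik f_kl`.
Cluster-to-river-system labels come from a majority vote of the sampling
groups of the individuals hard-assigned (argmax) to each cluster; ties are
a hard error.  The migrant-removal rule flags individuals whose summed
non-native ancestry strictly exceeds 0.5.

Finite-sample behavior worth knowing: with three clusters at F_ST 0.05,
2,000 loci and 20 individuals per population, per-entry Q error at the
joint maximum-likelihood optimum is ≈ 0.07–0.08, even though with known
cluster frequencies the per-individual error would be ≈ 0.03.  Estimating
F together with Q is what sets the noise floor; population-mean ancestry
(composition) averages most of it away and is recovered within a few
points.  The acceptance suite states the stricter per-entry target and
documents the measured gap rather than quietly relaxing it.

## ABC origin inference

Three competing demographic scenarios for each introduced population I
sampled with a Yangtze-cluster population A and a Pearl-cluster population
B (times in generations, backwards): (1) I founded at t1 as an admixture
of A (rate r) and B; (2) I from A alone; (3) I from B alone — each with a
founder bottleneck (size N_m from the founding until t1 − db) and the deep
A/B split at t3.  Priors are uniform with the ordering constraints
t3 > t2 > t1 > db and N > N_m (applied to every population size), sizes
and t3 on [10, 10000], t1/t2/db on [1, 150], all interpreted as
generations.  The per-locus simulator is a structured coalescent
(exponential waiting times at rate k(k−1)/2/(2N), lineage movement at
events, one segregating site placed on a branch chosen proportional to
length), numba-compiled and cross-checked against msprime on split models
within Monte-Carlo error.

Summary statistics (21 for three populations): per-population genic
diversity mean and variance over loci, pairwise multi-locus θ, pairwise
Nei D, and pooled MAF deciles — the quoted statistic families, with the
panel size configurable rather than pinned to any particular count.
Model choice retains the closest 1–2% of simulations by Euclidean distance
on standardized statistics and fits a multinomial logistic regression of
scenario identity on statistic differences, read out at difference zero;
the regression design is projected onto leading (uncentered) singular axes
so it stays full-rank at small retained counts, and the CI comes from the
delta method on the intercepts.  Quasi-separation falls back to a
penalized regression with a degenerate-CI flag.  Parameter posteriors use
the local-linear regression adjustment on the same reduced design (logit
scale for rates, log scale for sizes and times), truncated to the prior
support; the adjustment dimension is kept small (≤ 4 axes) because
aggressive local regression demonstrably under-covers.  Type I/II errors
come from classifying prior-drawn pseudo-observed datasets.

Reference-table sizes are desk-scale by default (3 × 10³ simulations of a
few hundred loci in the acceptance runs, against 10⁶ × ~3,000 in a
full-scale run); both are configuration, not code.

## Selection scans

**Environmental association.**  Population allele frequencies are
standardized by the pooled frequency, `x = (p̂ − ε̂)/√(ε̂(1−ε̂))`, and the
genome-wide covariance Ω of these vectors is estimated by a Gibbs sampler
(latent Gaussian vectors conjugate given Ω; Ω inverse-Wishart given the
vectors; sampling noise 1/(2n_j) folded into the observation model), with
the posterior mean over retained iterations reported and thinned draws
kept.  The per-locus Bayes factor compares a linear covariate effect
(effect size integrated over a uniform grid on [−1, 1]) against the
Ω-null; whitening by the Cholesky factor of Ω + sampling noise reduces the
likelihood ratio to a closed form, so the integration is exact quadrature
rather than MCMC.  A locus is significant when BF > 3 in every one of
five runs under independent Ω draws.  Under this full-prior integration a
signal-free locus earns an Occam penalty (null BFs concentrate near 0.15,
not 1), which makes the BF > 3 rule conservative: the neutral
false-positive rate measures well under 1%.

**Hierarchical-island outliers.**  The null is a two-level Balding–Nichols
hierarchy — groups drift from the total with `c_CT`, demes within groups
with `c_SC` — which is the equilibrium allele-frequency law of a
hierarchical island model and vectorizes to 5 × 10⁴ simulated loci in
seconds.  The two drift levels are calibrated so the simulated F_ST and
F_CT match the observed values, with three safeguards: the observed
targets use tail-trimmed per-locus θ (candidate outliers must not inflate
the neutral target), the simulated quantities are trimmed identically
(otherwise the calibration is biased low), and the fixed-point updates are
bias-corrected through the analytic relations F_CT = c_CT and
F_ST = c_CT + (1 − c_CT)·c_SC.  Each observed locus is placed at its
conditional θ quantile within its heterozygosity bin, with neighboring
bins pooled so the p-value floor stays well below the FDR threshold.
Flags require quantile > 0.995 and Benjamini–Hochberg FDR ≤ 0.01; the low
tail symmetrically flags balancing candidates.  On data generated by the
calibrated null itself the pre-FDR high-tail rate is ≈ 0.5% and post-FDR
flags vanish; on structured data with admixture and bottlenecks the island
null is mis-specified and the realized false-discovery proportion exceeds
the nominal level — the known weakness of this method class, and one
reason the study interpreted only balancing selection from the
all-locations run.

**F-model.**  logit(F_ij) = α_i + β_j with a beta-binomial likelihood for
allele counts given ancestral frequencies; reversible-jump MCMC toggles
each locus effect α_i with prior inclusion odds 1:10 against, using the
α prior N(0, 2) as the birth proposal so the acceptance ratio reduces to a
likelihood ratio times the prior odds.  β starts at the logit of the
observed global θ.  The q-value of a locus is the running mean of the
posterior error (1 − inclusion probability) in ranked order; outliers at
q ≤ 0.05 are classed positive (α > 0) or balancing (α < 0).  Balancing
power at desk scale is very low — planted balanced loci show clearly
negative posterior α (the rank-sum test is decisive) but rarely cross the
q threshold, consistent with the well-documented behavior of F-model
scans; interpreting balancing candidates therefore leans on the
all-locations design, where the bottlenecked introduced populations raise
the genome-wide background and low-θ loci stand out.

**Combination and stability.**  Outlier sets combine by exact set algebra
over persisted locus ids; the leave-one-out protocol reruns a given test
dropping one location at a time and reports common-locus proportions
against the full-data run.

## Genomic islands

Windows tile each scaffold (tumbling by default, step = size; arbitrary
step supported) in half-open base-pair coordinates, converted once from
the 1-based inclusive convention of the on-disk formats.  Window score is
the mean per-locus θ between the pooled Yangtze and Pearl groups, defined
only when the window holds ≥ 3 SNPs.  A window is elevated when its mean
exceeds the background mean + 3 SD (background: all defined windows); an
island is a maximal run of adjacent elevated windows containing at least
one outlier SNP, and a single background window breaks a run.  SNP-density
independence is checked by Spearman correlation with a permutation p.

## Problem sizes

Defaults and test sizes are chosen for a single-CPU desk run: cohorts of
1,500–6,000 loci; 999–10,000 permutations; ABC reference tables of
3,000 simulations × 400 loci with 20 diploids per population; covariance
chains of 500–800 Gibbs iterations; F-model chains of 1,200–2,500
iterations; 5 × 10⁴ island-null loci.  All are function parameters, and
the full-scale settings of the study design (10⁶ ABC simulations, 10⁵
covariance iterations, 10⁴ permutations) remain available by
configuration.

## Known limitations

* The coalescent simulator is single-site per locus (no intra-locus
  recombination or multi-site haplotypes) and approximates discrete
  generations by exponential waiting times; both are standard at these
  time scales but matter for very recent, very strong bottlenecks.
* The ABC confidence intervals are regression-based; bootstrap CIs are
  not implemented.
* The environmental-association model integrates latent frequencies
  analytically under a Gaussian approximation rather than by importance
  sampling; for very rare alleles (ε̂ < 0.05) the approximation is crude,
  which is one reason scans run on the MAF-filtered subset.
* The F-model chain length needed for well-mixed β (effective sample size
  > 50) is larger than the desk-scale default; results carry an explicit
  non-mixing flag when the threshold is not met.
* Window detection assumes dense enough SNP coverage that a 400 kb signal
  spans several defined windows; sparse scaffolds yield undefined windows
  rather than false islands.
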