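# Methods

`ithshift` reimplements, as a tested pipeline, a multiregion whole-exome
analysis of intratumor heterogeneity (ITH) that contrasts precancerous
colorectal lesions (PCRC: adenoma and carcinoma in situ, sampled as
laterally spreading tumors) with advanced colorectal cancers (ACRC). The
patient-level data behind such studies are controlled-access, so the package
pairs every analysis stage with a synthetic-cohort generator that emits the
same file formats plus ground truth, and the test suite exercises the whole
pipeline on data where the expected answers are known by construction.

## Mutation profiles

Per case, a variant enters the multiregion profile when the upstream somatic
caller flagged it in at least one region and every region covers the site
with strictly more than ten reads. In regions the caller left negative,
presence is rescued when all three hold: tumor VAF >= 0.05, matched-normal
VAF <= 0.01, and Fisher's exact test on the tumor-vs-normal read-count table
has p <= 0.05. The test is one-sided (enrichment of variant reads in the
tumor) by default: the criterion screens for tumor-specific signal and the
upstream caller's analogous filter is one-sided; the convention is
switchable (`RescueThresholds.fisher_alternative`). At a normal depth of
zero the normal-VAF criterion is treated as passed (no evidence of germline
signal); the tumor-VAF criterion already requires tumor coverage.

Variants present in all regions are *ubiquitous*; in several but not all,
*shared*; in exactly one, *private*. Where an evolutionary-tree annotation
is absent, trunk / internal-branch / external-branch labels fall back on the
correspondence ubiquitous -> trunk, shared -> internal branch, private ->
external branch.

Display order for heatmaps: ubiquitous variants by genomic position; shared
variants by average-linkage hierarchical clustering (Euclidean distance on
presence rows — the clustering flavor is our choice, as only "a hierarchical
clustering" is prescribed by the procedure this follows); private variants
by owning region, then VAF descending. Region label colors come from the
first three principal components of the VAF profile, min–max rescaled per
component to [0, 1] and used as RGB; degenerate components sit at 0.5 so
identical profiles share one color.

Tumor content (cellularity) per region is estimated as twice the median
ubiquitous VAF, capped at 1.0 (the uncapped estimator can exceed 1 by
sampling noise; the cap is our choice). A metadata override is available
— in the original analysis the tumor content fed to the VAF model came from
a tree-building tool's estimate, which we do not reimplement.

## Downsampling-corrected alteration counts

Cases contribute 4–21 regions; raw ubiquitous/heterogeneous counts are not
comparable across cases. The correction enumerates every subset of k = 4
regions (the smallest case size): within a subset, the ubiquitous count is
the number of alterations present in all four regions (recomputed from
scratch — an alteration heterogeneous in the full case may be ubiquitous in
a subset), and the heterogeneous count is the median over the four regions
of per-region counts of alterations present there but not in all. The
corrected values are medians over all C(J, 4) subsets; medians use the
midpoint convention at both levels. Enumeration is exhaustive (at most
C(21, 4) = 5985 subsets), with no sampling approximation.

## Arm-level and focal CNAs

Inputs are segment-level log2 tumor/normal depth ratios (log2R) from an
upstream segmentation tool. A segment is arm-level when its overlap with a
chromosome arm strictly exceeds 50% of the arm's length. For every arm
carrying an arm-level segment in at least one region of a case, each region
is re-examined: the arm's length-weighted mean log2R is computed with
uncovered bases contributing zero (coverage handling is our choice; the rule
as published averages "along the arm" without specifying it), and a CNA is
present when |mean| strictly exceeds 0.15. The mean is rounded to 12
decimals before the comparison so inputs constructed to sit exactly at the
threshold compare exactly rather than by floating-point accident. Gains and
losses follow the sign; an arm present with one sign in every region is
ubiquitous, otherwise heterogeneous (discordant signs across regions are
heterogeneous and flagged — sign conflicts are not addressed by the
published rule). Focal candidate loci (configuration) are examined only
when they overlap a focally classified segment somewhere in the case, with
the same |mean log2R| > 0.15 rule over the locus. Arm definitions ship as an
hg19 cytoband-derived table (p arm = start of chromosome to centromere gap,
q arm = gap end to chromosome end).

## Hierarchical Bayesian models

Three models share one architecture. Group means sit in a Cauchy hierarchy:
beta_t ~ Cauchy(beta, tau), beta ~ Cauchy(beta0 = 0, tau0 = 1),
tau ~ Half-Cauchy(lambda0 = 1). Residuals are nested by case and sample
(and mutation, for the binomial models): r_i ~ Cauchy(r0, t),
r_ij ~ Cauchy(r_i, t_i), r_ijk ~ Cauchy(r_ij, t_ij), with
Half-Cauchy(1) hyper-priors on every scale (l0, l1, l2). All constants are
explicit in `Hyperparameters` and overridable.

* **Counts** (`AlterationCountModel`): per-region alteration counts
  n_ij ~ Poisson(exp(beta_t(ij) + r_ij)), t indexing tumor stage
  (adenoma, carcinoma, ACRC).
* **VAFs** (`VafCategoryModel`): per-mutation variant reads
  b_ijk ~ Binomial(d_ijk, logistic(beta_t(ijk) + r_ijk) * TC_ij) —
  the logistic term is the tumor-content-free mean VAF of the mutation's
  category (cohort x trunk/internal/external branch, or cohort x
  ubiquitous/shared/private).
* **CCFs** (`CcfCategoryModel`): the logistic term is the cancer cell
  fraction C and the success probability is
  TC*C / ((1-TC)*2 + TC*CN) with CN the local absolute copy number
  (mutant-allele multiplicity fixed at 1, as the formula implies).
  Sex-chromosome mutations are excluded before fitting. Where CN is not
  supplied it is discretized from the overlapping segment's log2R as
  CN = round(2*(2^log2R - (1-TC))/TC), floored at 1 — the discretization
  rule is our choice.

### Sampling

The posterior is explored by slice-within-Gibbs MCMC implemented in
`ithshift.mcmc`: each parameter block (group means; residual vectors;
log-transformed scales) has conditionally independent elements and is
updated by a univariate slice sampler (stepping-out plus shrinkage),
vectorized across the block. Slice sampling needs no step-size tuning and
handles the heavy Cauchy tails that defeat naive random-walk proposals; it
is the same family of univariate conditional samplers that Gibbs-based
engines apply to this model class. Chains are independent, seeded from a
`SeedSequence` spawn of the run seed, and draws are bit-reproducible for a
fixed seed. Convergence is monitored with the split Gelman–Rubin potential
scale reduction factor, reported per monitored parameter in `rhat_`.

Published chain settings are preserved as named configs (20 chains;
burn-in/total of 100k/200k for mutation counts, 50k/100k for CNA counts,
50k/50k for VAFs, 200k/200k for CCFs; thinning 5). Those totals are
internally inconsistent about whether they include burn-in (100k/200k
suggests yes; 50k/50k would then retain nothing), so `McmcConfig` stores
both numbers and retains `n_total - n_burnin` iterations when positive,
else `n_total`. The default config used by tests and quick runs is scaled
down to 4 chains, 2000 burn-in, 2000 retained, thin 1; problem sizes in the
test suite (60 samples per stage; 500 mutations per category; mini-cohorts
of 3 cases per arm with per-sample mutation counts of 40–120) are the
package's own scaled-down choices that keep the contrasts detectable.

### Identifiability and reported quantities

The likelihood constrains only the sum beta_t + residual, so the split
between group means and the residual hierarchy is resolved by the priors
alone. This matters because the residual anchor is r0 = 1 as printed in the
constants above — an anchor at 1 shifts the residual center away from zero
and biases raw beta_t downward by a compensating amount. We implement r0 = 1
as the default, exactly as printed, and expose three reporting modes:

* `raw` — beta_t as monitored (the published quantity);
* `adjusted` — beta_t plus the mean fitted residual of the group's
  observations: the likelihood-identified combination, immune to the
  prior-driven split; used for group comparisons and ordering
  probabilities;
* `predictive` — beta_t plus a residual drawn for a new observation
  through the fitted hierarchy (a new region of a randomly chosen observed
  case, or a new mutation of a randomly chosen region), whose interval
  adds between-observation variability to posterior uncertainty; this is
  the interval used when asking whether a true simulated group mean is
  recovered, since the identified interval tracks the realized sample mean
  (which differs from the population mean by sampling noise).

Recovery tests and the acceptance script fit with r0 = 0 (and, for the
binomial models, residual-scale hyper-priors tightened to 0.05) so that
logistic(beta_t) itself is interpretable as the group mean on data simulated
without residual structure; the printed default remains r0 = 1 everywhere
else. Between-group orderings are insensitive to this choice because the
residual hierarchy is shared across groups.

### Numerical notes

Log-densities carry all normalization constants, so the joint density can
be pinned against independently coded sums (tested to 1e-8). Scale
parameters are sampled on the log scale with the Jacobian included.
Binomial terms use `xlogy` so zero-probability/zero-count corners are exact;
Poisson means may overflow to infinity during stepping-out, which the slice
sampler treats as zero density. Chains are initialized at data-driven
points (log group means; logit of pooled frequencies, divided by the mean
success-probability scaling) with small jitter per chain.

## Frequentist comparisons

Fisher's exact test is two-sided under the sum-of-small-p convention (sum
over tables with the observed margins whose point probability does not
exceed the observed one). Rank tests use the Wilcoxon rank-sum
(Mann–Whitney) and signed-rank tests, exact when sample sizes are small and
tie-free, otherwise normal approximation with continuity correction; the
exact flavor the original analysis used is unstated, so this convention is
fixed and documented here. Driver mutations are counted per mutation, not
per gene. Mutation spectra collapse substitutions to the six
pyrimidine-context classes (G>T counted as C>A and so on) plus an indel
fraction, without trinucleotide context.

## Synthetic cohorts

`SimConfig` defaults mirror the study design: 10 PCRC cases of 4–7 regions
and 8 ACRC cases (region range capped at 4–12 as a size choice), ~150
mutations per region, mean depth 132x with negative-binomial over-dispersion
(dispersion 8 — only the coverage median is known, the dispersion is our
choice), tumor content U(0.4, 0.9), matched-normal error rate 0.002 (below
the 0.01 rescue ceiling), and a caller false-negative rate of 0.05 so the
rescue step has work to do. Each case is a star-or-bifurcating clone tree:
a trunk clone (CCF 1 everywhere), subclones spanning contiguous region
blocks, and per-region private mutations. Variant reads are
Binomial(depth, expected VAF + error) with the expected VAF given by the
CCF formula above; segments carry log2R = log2(((1-TC)*2 + TC*CN)/2) plus
Gaussian noise (sd 0.03). Copy states are clonal within the regions that
carry them, so per-region CN stays integral.

Two regimes encode the evolutionary contrast the pipeline is meant to
detect. *Darwinian* (default for the PCRC cohort): 2–3 subclones at CCF
0.60–0.95, half of driver mutations subclonal, private fraction 0.15.
*Neutral* (default for ACRC): 1–2 shared clones at CCF 0.15–0.40, 10% of
drivers subclonal, private fraction 0.30. Mutation budgets are split so the
expected per-region count equals the stage mean regardless of regime.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline's statistics recover contrasts that are true by
construction under its own measurement model (binomial reads, clonal copy
states, known purity behavior). They do not validate behavior under
alignment artifacts, mutational-signature structure, subclonal CNAs,
spatial sampling geometry, or purity estimation bias — none of which the
generator emulates.

## Known limitations

* The models treat tumor content as known and fixed; uncertainty in the
  2x-median estimator is not propagated.
* CCF is bounded below 1 by the logistic link; mutant multiplicity above 1
  (amplified mutant alleles) is not modeled.
* The slice-within-Gibbs sampler mixes slowly along the beta/residual ridge
  when residual scales are free; the identified (`adjusted`) quantities mix
  well and are the ones used for inference.
* Tree-based trunk/branch labels are accepted as annotations, not
  inferred; without them the category correspondence is used.
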