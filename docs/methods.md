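# Methods

This note documents the statistical models, estimators and numerical
choices implemented in `radpop`, the design decisions taken where several
constructions were defensible, and what the simulation-based tests do and
do not demonstrate about real data.

## Data model

Genotypes are diploid, biallelic, coded as alternate-allele dosage
g ∈ {0, 1, 2} with −1 for a missing call. The minor allele is determined
per computation scope (overall or per population), never fixed globally.
Every analysis takes a `GenotypePanel`: dosage matrix + population labels +
locus metadata (ddRAD tag id, SNP id `<tag>_<offset>`, chrom, pos).

## SNP filtering

Rules are applied in a fixed order — (1) one SNP per ddRAD tag, (2)
per-population call rate, (3) MAF — because the per-rule removal counts
depend on the order; the counts reported in `FilterReport` are sequential
and always satisfy `n_input = removed₁ + removed₂ + removed₃ + retained`.

* One-per-tag keeps the SNP with the highest overall MAF (most informative
  downstream), ties broken by smallest position. Restricting to one SNP
  per tag removes intra-read LD and haplotype-calling artifacts.
* Call rate: a SNP is kept iff genotyped in ≥ `call_rate_min` (default
  0.75, inclusive) of the samples of *every* population.
* MAF: default scope is the pooled sample (MAF ≥ 0.05 across all
  individuals). A per-population mode keeps a SNP reaching the threshold
  in at least one population — the only per-population reading that does
  not discard every private allele. Both modes exist because genotyping
  pipelines differ on this point; the choice is visible in the API and
  the pipeline config.

## Diversity

Per locus within a population: Ho = heterozygotes / called genotypes;
He = 2p̂(1−p̂) with p̂ from called allele copies (optionally the unbiased
2n/(2n−1) correction — off by default since the upstream tools this
mirrors do not document using it). Population summaries average over loci
polymorphic in the full panel; monomorphic-in-panel loci are excluded so
the statistics describe variant sites only, and all-missing loci are
excluded per population. Fis defaults to the ratio-of-means estimator
1 − H̄o/H̄e, which is robust to near-zero-He loci; a per-locus-averaged
mode is provided for comparison. A population with H̄e = 0 has undefined
(NaN) Fis. Populations with fewer than two samples trigger a
low-confidence warning rather than an error.

## Weir–Cockerham F<sub>ST</sub>

For a pair of populations, each locus contributes the method-of-moments
variance components (r = 2): with per-population called sample sizes n_i,
alt frequencies p_i and het proportions h_i,

    n̄ = (n₁+n₂)/2,  n_c = 2n̄ − (n₁²+n₂²)/(2n̄),
    p̄ = Σnᵢpᵢ/(2n̄),  s² = Σnᵢ(pᵢ−p̄)²/n̄,  h̄ = Σnᵢhᵢ/(2n̄)
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
    c = h̄/2

and θ̂ = Σa / Σ(a+b+c) over loci segregating in the pair (monomorphic and
singly-typed loci excluded; loci with n̄ ≤ 1 skipped with a log entry).
The test suite checks this implementation against a literal, loop-based
transcription of the general-r published formulas to 1 × 10⁻¹⁰ on random
panels; the same check is recomputed by the reproduction script. Note the
estimator's known small negative bias for identical populations
(≈ −1/(2(n−1))), visible in the "identical tables" test.

Inference bootstraps loci (the standard genome-wide choice): resampled
(a, b, c) sums give percentile CIs, and the p-value is the bootstrap mass
at θ* ≤ 0, i.e. a one-sided test of deviation from zero. A mass of
exactly zero is reported as `< 1/n_boot` in tables.

## AMOVA

Individual pairwise squared Euclidean distances on dosage, pairwise
deletion over shared loci and rescaled by L/(shared loci) so all pairs are
on a common denominator (a no-rescaling mode exists). One-way variance
decomposition: SSD_total = Σd²/N partitioned into within (per-population
Σd²/n_p) and among; σ²_w = MS_within, σ²_a = (MS_among − MS_within)/n₀
with n₀ = (N − Σn_p²/N)/(P−1); Φ_ST = σ²_a/(σ²_a+σ²_w). Negative σ²_a is
retained raw but truncated to zero for percentage reporting. Significance
permutes individual labels; p = (1 + #{Φ* ≥ Φ})/(1 + n_perm) (never
exactly zero). All-identical genotypes yield a flagged, NaN Φ.

## Admixture model

The generative model is STRUCTURE's admixture model: individual i has
ancestry q_i on the K-simplex; each allele copy at locus l picks cluster k
with probability q_ik and is the alternate allele with probability p_kl.
The Gibbs sweep samples (1) the cluster of origin of every called allele
copy, (2) p_kl ~ Beta(λ + alt-count, λ + ref-count), (3) q_i ~ Dirichlet
(α + per-cluster copy counts). Missing genotypes contribute nothing.

Choices: uncorrelated-frequencies prior with λ = 1; α fixed at 1 rather
than sampled (the Metropolis update of α adds cost and rarely changes
point assignments at these panel sizes; α is configurable). lnL is
recorded every `thin` sweeps post-burn-in; L(K) = mean(lnL) − var(lnL)/2
is the standard harmonic-style evidence surrogate and is documented as an
approximation, not a marginal likelihood. Defaults are desk-scale
(4,000 sweeps, 2,000 burn-in, thin 10) — production-scale chains
(200,000/100,000) are a parameter change, not a code change.

Evanno ΔK: with replicate runs per K, L″(K) is the second difference of
each replicate's L(K); ΔK = mean|L″(K)| / sd(L(K)), defined for interior
K with positive sd, and the selected K maximizes ΔK (ties broken by the
higher mean L(K)). At least two replicates are required, enforced.
Replicate label alignment (greedy column matching by correlation, with a
−MSE fallback for constant columns) is used only for averaged-Q display,
never for L(K) or ΔK.

## DAPC

PCA: per-locus mean centering with missing dosages imputed by the locus
mean (standard for modest missingness; imputation values are stored and
reused for prediction), components by SVD. `find_clusters` runs k-means
(Lloyd, best of `n_starts` restarts, via scikit-learn) on retained PC
scores and scores each K with BIC(K) = n·ln(WSS/n) + K·ln(n); the
selected K is the first whose single-step BIC decrease falls below 5% of
the largest single-step decrease (the elbow), with the full curve
returned for manual choice.

Discriminant axes solve B v = λ W v in retained-PC space with the pooled
within-group scatter ridge-stabilized by 10⁻⁸·tr(W)/d. The retained-PC
default min(⌊N/3⌋, N−K−1) guards against the overfitting that
discriminant analysis on p ≫ n genotype data invites. Membership
posteriors use equal priors and an isotropic Gaussian on discriminant
coordinates: P(g|x) ∝ exp(−d_g²/2) to the group centroid — a deliberately
simple density whose exact form matters little once groups separate.
Per-SNP contributions are squared (rotation × discriminant-coefficient)
loadings summed over axes and normalized to 1.

## Cross-validated assignment

"Four-fold" is implemented as independently redrawn stratified 25%
holdouts (⌈0.25·n_p⌉ per population) repeated `repeats` = 10 times — the
repetition is explicitly for averaging over random holdout allocations, so
independent redraws are the natural reading; a rotating-disjoint-folds
mode is provided for comparison. n_pca is fixed across repeats so repeats
are comparable. Per-repeat RNGs derive from the master seed by fixed
increments, making the confusion matrix reproducible bit for bit. With
7 populations × 5 held out × 10 repeats the matrix always pools 350
assignments.

## Synthetic data

Two-level Balding–Nichols hierarchy: ancestral frequency π_l from a
truncated spectrum (inverse-CDF sampling); cluster frequency
c_kl ~ Beta(π(1−F_k)/F_k, (1−π)(1−F_k)/F_k); population frequency from
c_kl with f_pop. F = 0 copies exactly (no degenerate Beta); loci already
fixed stay fixed. Pure individuals draw both copies from their population
frequency; admixed individuals have q_i ~ Dirichlet(concentration) and
draw each copy at the cluster level — exactly the admixture model the
Gibbs sampler assumes, so that module is estimated under its own truth.
Inbreeding is realized as copy duplication: the second allele copy
duplicates the first (cluster and allelic state) with probability Fis,
reproducing P(het) = 2p(1−p)(1−Fis) with p the individual's marginal
alt-probability while staying within the copy-level generative model.
Missingness is MCAR (no mechanism is documented for the motivating data;
the default 10% rate is a placeholder in that sense). Everything is
deterministic given the scenario seed.

The default `study_scenario` encodes the study design: 7 populations
× 20 fish, ~2,500 candidate loci, ancestral spectrum Beta(0.6, 7)
truncated at 0.02 (mass just above the 5% MAF threshold), four ancestry
components — a lake cluster (F = 0.6) carrying three nearly panmictic
populations (f_pop 0.035–0.045, pairwise F_ST ≈ 0.03–0.045), a moderately
drifted isolate (F = 0.2, realized F_ST ≈ 0.4–0.45 against the cluster),
and two farm components from which Kunduchi, Karanga and Ruhila are
admixed with elevated Fis (0.26–0.5). Known limitation: with a single
genome-wide drift coefficient per group, strong between-group divergence
necessarily produces a heavier pooled-MAF tail than real ddRAD panels
show — about 55–60% of retained SNPs have MAF < 0.2 here, versus > 80% in
typical low-diversity panels whose differentiation is concentrated in a
minority of loci. A per-locus drift distribution would fix this but is
out of scope (loci are exchangeable and unlinked; no LD, no coalescent).

## What the tests show — and don't

Parameter-recovery tests (F_ST bias and CI coverage at F = 0.2, Fis at
0/0.25/0.5, Q-matrix RMSE at F = 0.3, Evanno K selection on three
clusters) demonstrate estimator correctness *under the generating model*:
unlinked loci, Balding–Nichols drift, MCAR missingness, honest labels.
Real ddRAD data add LD between nearby SNPs, allele-dropout at restriction
sites (missingness correlated with genotype), genotyping error, and
mislabelled or hybrid individuals — none of which the generator emulates,
so passing tests bound implementation error, not field performance.
Problem sizes in the acceptance battery (e.g. Evanno: 3 × 20 individuals,
300 loci, 1,500-sweep chains, 10 experiment seeds) are chosen so the
battery completes in minutes on one CPU while each check retains clear
statistical power.

## Numerical details

* Cluster-frequency draws are clipped to [10⁻¹², 1−10⁻¹²] inside the
  sampler; lnL uses a 10⁻³⁰⁰ floor before log.
* Dirichlet sampling uses normalized Gamma draws (vectorized across
  individuals).
* All RNG flows through `numpy.random.Generator`; nested experiments
  derive child seeds via `SeedSequence.spawn`, kept below 2³¹.
* Posterior ties in hard assignment break by group order with a logged
  warning; k-means restarts that produce empty clusters are handled by
  scikit-learn's reinitialization.
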