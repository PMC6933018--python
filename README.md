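# radpop

Population structure and genetic diversity analysis for reduced-representation
(RAD-seq / ddRAD-seq) SNP panels.

`radpop` covers the downstream half of a population-genomics study on diploid
biallelic SNP genotypes — the kind of analysis run on farmed and wild fish
strains (the motivating system is Nile tilapia, *Oreochromis niloticus*,
cultured in Tanzania) to decide which populations are distinct, which are
admixed, and whether a SNP panel can trace a fish back to its population of
origin. It is a library first (importable API plus `examples/`), with a thin
`radpop` command-line wrapper for end-to-end pipeline runs.

## What it computes

* **SNP filtering** — one SNP per ddRAD locus (highest MAF, ties by
  position), a per-population call-rate rule (≥ 75% genotyped in *every*
  population), and a minor-allele-frequency rule (overall MAF ≥ 0.05 by
  default; per-population mode available). The `FilterReport` obeys a
  conservation invariant: removals always sum back to the input count.
* **Diversity** — per population: expected heterozygosity
  He = mean over loci of 2p̂(1−p̂), observed heterozygosity Ho, inbreeding
  coefficient F<sub>IS</sub> = 1 − H̄o/H̄e, and mean MAF.
* **Differentiation** — pairwise Weir & Cockerham θ̂ from per-locus variance
  components (a, b, c), θ̂ = Σa / Σ(a+b+c), with locus-bootstrap percentile
  CIs and a one-sided bootstrap test of θ = 0; two-level AMOVA
  (σ²<sub>among</sub>, σ²<sub>within</sub>, Φ<sub>ST</sub>) on squared
  dosage distances with a label-permutation test.
* **Admixture** — a Gibbs sampler for the STRUCTURE admixture model
  (ancestry proportions Q, cluster allele frequencies P, uncorrelated-
  frequency Beta(λ, λ) prior, symmetric Dirichlet(α) prior on Q), replicate
  runs over a K range, the model score L(K) = mean(lnL) − var(lnL)/2, and
  the Evanno ΔK criterion for choosing K.
* **DAPC** — PCA (mean-imputed dosages, SVD), k-means + BIC cluster
  discovery with an elbow rule, discriminant axes from the generalized
  eigenproblem B v = λ W v, Gaussian membership posteriors, and per-SNP
  discriminatory contributions.
* **Assignment** — repeated stratified 25% holdout: fit DAPC on the
  training split, assign the held-out fish, pool a confusion matrix and
  overall assignment rate.
* **Simulation** — a two-level Balding–Nichols generator (ancestral
  spectrum → cluster drift F<sub>k</sub> → population drift f<sub>pop</sub>,
  copy-level admixture, within-population inbreeding, MCAR missingness)
  whose default scenario reproduces the study design: 7 populations × 20
  fish, a nearly panmictic lake cluster, one strong isolate, and admixed
  farm populations with elevated F<sub>IS</sub>.

## Worked example

```python
import radpop as rp

panel, truth = rp.simulate_panel(rp.study_scenario())
filtered, report = rp.filter_panel(panel)
print(report.log_lines())
# ['2500 SNPs in', '0 removed by one-SNP-per-locus rule',
#  '180 removed by per-population call-rate rule',
#  '1295 removed by MAF rule', '1025 SNPs retained']

rp.amova(filtered, n_perm=100, seed=1).phi_st     # 0.407: strong structure
rep = rp.crossval_assignment(filtered, seed=1)
print(f"{100 * rep.overall_rate:.1f}%")           # 90.0% correct assignment
```

The filter log shows the bookkeeping (removals + retained = input). The
AMOVA Φ_ST of 0.41 says ~41% of molecular variance lies among populations.
The 90% cross-validated assignment rate means 315 of the 350 held-out fish
were traced to their true population; the misassignments fall almost
entirely inside the nearly panmictic lake cluster, whose members are barely
differentiated (pairwise F_ST ≈ 0.03–0.06). Run the scripts in `examples/`
for one narrative walkthrough per capability.

The same pipeline runs from the shell:

```bash
radpop simulate --out sim/
radpop pipeline --genotypes sim/simulated.vcf --popmap sim/simulated.popmap.tsv \
    --out run/ --seed 1
```

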