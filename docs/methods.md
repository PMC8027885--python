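# Methods

`sebpop` studies how fine-scale population structure in admixed Southern
African Bantu-speaker cohorts distorts downstream analyses — most
importantly case-control GWAS — using synthetic genotype data whose ground
truth is known. This note documents the generative model, the statistics,
the numerical choices, and what the synthetic data do and do not emulate.

## The cohort generator

### Allele frequencies: two-layer Balding–Nichols

Each locus draws a base frequency `p ~ Uniform(lo, hi)` (default
`(0.05, 0.95)`). Ancestral population `k` draws

```
f_k ~ Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k),   E[f_k] = p,  Var[f_k] = F_k p(1-p)
```

with per-ancestry differentiation `F_anc = (0.02, 0.08, 0.13)` for the
Bantu-related (BS), Khoe-San-related (KS) and Eurasian-related (EUR)
components. These defaults put the expected ancestral pairwise F_ST near
0.10 (BS–KS) and 0.15 (BS–EUR), the magnitudes typical of African
hunter-gatherer vs. farmer and African vs. European comparisons. Each
*group* then adds its own drift `F_g` as a second Balding–Nichols layer
around the ancestry frequencies, so between-group F_ST is controllable
independently of admixture differences. All frequencies are clipped to
`[0.001, 0.999]`; fixed loci would break the downstream estimators.

### Local ancestry and genotypes

A haplotype's ancestry along a chromosome is a Poisson switch process of
rate `g` (generations since admixture) per Morgan; at each switch (and the
chromosome start) the ancestry is an i.i.d. draw from the haplotype's
proportions `q`. Same-ancestry "silent" switches are allowed, which keeps
the process stationary; the observed switch rate is `g (1 - Σ q_k²)` per
Morgan and the maximal run of ancestry `k` is exponential with mean
`1/(g (1-q_k))` Morgans. Alleles are Bernoulli draws from the group- and
ancestry-specific frequency at each locus; diploid dosages are the sum of
two haplotypes. Genetic maps default to 1 cM/Mb; coordinates are 1-based
inclusive bp.

Group defaults follow the published cohort: eight groups whose K=3 ancestry
proportions match the reported unsupervised-clustering means (Khoe-San
ancestry from 1.5% in Tsonga to 20% in Tswana), admixture ages inside the
reported 24–45 generation range (Tsonga and Venda oldest), relative sample
sizes proportional to the ethno-linguistically concordant counts, and three
sampling sites with mixed group composition (Tsonga concentrated at
Agincourt, Pedi at Dikgale, the rest mostly at the urban site). The exact
per-site fractions are qualitative: the published per-site table is only
partially recoverable, so the fractions reproduce its pattern, not its
digits.

### The X chromosome and sex bias

Each group carries female/male per-ancestry contribution fractions
`s_f, s_m` with `(s_f + s_m)/2 = q`. X haplotypes draw their ancestry from
the single-pulse equilibrium expectation `H_X = (2 s_f + s_m)/3` (the X
spends two thirds of its history in females); autosomes use
`H_A = (s_f + s_m)/2`. Males carry one X haplotype; hemizygous dosages are
in {0, 1}. The single-pulse equilibrium is our modelling choice — the
relation between contribution fractions and X/autosome ancestry under
ongoing admixture is more complex, and the inversion
`s_f = 3H_X - 2H_A, s_m = 4H_A - 3H_X` is exact only under this model.
Default sex bias: KS female-biased (`s_f,KS = 1.4 q_KS`), EUR male-biased
(`s_f,EUR = 0.6 q_EUR`), BS absorbing the remainder.

### Metadata

Each sample reports its own ethnicity plus six parent/grandparent
ethnicities; each of the six independently matches the sample's group with
probability `1 - mismatch_rate` (default 0.2). A sample is
*ethno-linguistically concordant* (EC) when at least 5 of 6 labels match.
The default rate implies an EC fraction of `0.8^6 + 6·0.2·0.8^5 ≈ 0.655`,
close to the 63% observed in the real cohort.

### What the generator does not emulate

No background LD beyond ancestry tracts (LD pruning therefore removes
almost nothing from simulated panels), no genotyping error model, no
relatedness or pedigree structure, no coalescent variance in ancestral
frequencies, and local-ancestry "posteriors" are truth values (1.0) unless
explicitly degraded. Tests passing on these data show that the estimators
recover planted parameters under the assumed model — not that the model
captures every feature of array data.

## Statistics

* **Weir–Cockerham F_ST** — the 1984 variance components `a, b, c` per
  locus (two populations, missing genotypes excluded per locus), combined
  as the ratio of averages `θ = Σa / Σ(a+b+c)`. Ratio-of-averages is the
  estimator's standard multi-locus usage; average-of-ratios is biased.
  Negative `θ` is reported raw and floored at 0 only when used as a
  distance.
* **PCA** — per-variant mean imputation, centering by `2p̂`, scaling by
  `sqrt(2p̂(1-p̂))`, eigendecomposition of the sample covariance via the
  n×n Gram matrix. Deterministic up to column sign.
* **LD pruning** — greedy windowed scan (r² > 0.5, window 50 SNPs, step
  5), dropping the later variant of an offending pair; implemented with a
  banded correlation so the common no-LD case costs one pass.
* **UPGMA** — average-linkage agglomeration; merge height d/2, ties broken
  by the lexicographically smallest label pair; output is ultrametric and
  serialized as newick.
* **Geography** — Weiszfeld iteration for weighted geometric medians on a
  local equirectangular plane about the weighted centroid (tol 1e-9
  degrees; the coincident-point case uses the standard optimality test);
  great-circle distances by haversine with R = 6371.0 km.
* **Mantel / Procrustes** — one-sided permutation tests with add-one
  p-values, 9999 permutations by default; Mantel also supports exhaustive
  enumeration for small label sets. Procrustes centers and unit-scales
  both configurations, allows reflection, and reports `m²`, `r = √(1-m²)`
  and `r²` so either convention of "Procrustes correlation" can be read
  off.
* **Supervised ancestry (EM)** — per-individual maximum likelihood under
  the binomial admixture model `g_ℓ ~ Bin(ploidy, q·f_ℓ)` with known
  ancestral frequencies. The EM update multiplies `q_k` by its average
  posterior responsibility; convergence when the EM-step change falls
  below 1e-6 (max 500 steps). Because the ancestries are weakly
  differentiated, plain EM converges slowly; the implementation wraps the
  same update in SQUAREM extrapolation with a log-likelihood guard that
  falls back to the plain EM iterate whenever extrapolation would decrease
  the likelihood — the fixed point, the monotonicity property and the
  convergence criterion are unchanged, only the iteration count drops by
  an order of magnitude. Supervision (truth frequencies exist in
  simulation) replaces unsupervised clustering so that parameter recovery
  is testable.
* **ΔAdmix** — per-ancestry `(Q̄_X - Q̄_A)/Q̄_A` over group means; positive
  means female-biased. The relative-difference normalization is our
  choice (the source delegates the formula to a reference that does not
  print it); it is dimensionless and preserves the published sign
  semantics. SEs come from 50 without-replacement bootstrap subsamples of
  20. For low-admixture groups the ratio denominator is small and the
  bootstrap SE can explode — that instability is real and reported, not
  suppressed.
* **PBS** — `T = -log(1 - max(F_ST, 0))` and `PBS_A = (T_AB + T_AC -
  T_BC)/2`; F_ST = 1 gives an infinite branch and flags the variant
  invalid. Negative F_ST estimates are floored before the log.
* **Enrichment scan** — drop calls with posterior ≤ 0.8 and variants
  within 2 Mb of chromosome ends or the centromere; flag variants whose
  ancestry dosage exceeds the genome-wide mean by 3 SD (high tail by
  default; `tail="both"` available); merge consecutive flagged variants;
  keep runs of ≥ 3 SNPs.
* **Allele-frequency scan** — fold `= max(f_i/f_j, f_j/f_i)` per group
  pair, ranked at fold ≥ 3; zero-frequency variants are unbounded and
  reported separately rather than ranked (a 0.03 vs 0.18 pair is a
  six-fold difference here — the literal ratio is used). Frequency SEs:
  50 bootstrap subsamples of 30.

## The simulated-trait GWAS framework

Four binary-trait assignment schemes use site and group labels as trait
proxies: (1) cases from one site, controls from another; (2) cases a
stated mixture of two sites (e.g. 37.5/62.5), controls from one site; (3)
cases and controls from one site with one group absent among cases; (4)
random labels within a site — the null design. The raw test is the allelic
2×2 chi-square on common variants (MAF > 0.05); λ is the median 1-df
chi-square over its null median `χ²₁,0.5 ≈ 0.4549` (computed from p-values,
so it applies to any 1-df test). Genomic control divides chi-squares by λ
when λ > 1 — after which recomputing λ gives exactly 1. PC correction
recomputes PCs per iteration on the LD-pruned analysis samples and adds
the first 3 PCs as logistic covariates.

The logistic solver is a variant-batched IRLS Newton fit with a Wald test
on the genotype term. When covariates separate cases from controls
completely the ML estimates do not exist; such variants fall back to Firth
bias-reduced logistic regression (penalized score with leverage
adjustment), as modern GWAS tools do. Note the limiting case: if a PC
*perfectly* classifies case status, conditioning on it removes all
residual contrast and no test of the genotype term is informative — the
framework therefore exercises the realistic regime in which sites are
ethno-linguistically mixed, so PCs track ancestry rather than the
case-control split itself. The significance thresholds are 5e-8
(genome-wide) and 1e-5 (suggestive; 5e-5 is available as the alternative
convention).

## Problem sizes

Unit tests run at desk scale (hundreds of samples, 10²–10³ variants). The
acceptance checks use: null calibration 800 samples × 20,000 variants × 20
label draws; structured inflation 1,760 samples × 20,000 variants × 10
replicates; F_ST recovery 200 × 5,000 × 20; topology recovery 150 × 1,200
× 100; sex-bias recovery 200 × 20,000 × 50 seeds; enrichment 200
haplotypes × 4,000 variants × 20 seeds. `scripts/acceptance.py` recomputes
the same quantities at moderately reduced replicate counts (printed in its
JSON output as `n`) so a full reproduction runs in minutes on one core.

## Known limitations

* The X/autosome sex-bias inversion assumes a single admixture pulse.
* Simulated sites are exchangeable apart from group composition; there is
  no within-group geographic substructure, so Mantel correlations on the
  default cohort preset are weak by construction (the geography-linked
  properties use the explicit cline generator).
* The allelic chi-square assumes Hardy–Weinberg within the pooled sample;
  its tail calibration at extreme thresholds relies on large counts
  (guaranteed here by the MAF > 0.05 restriction).
* EC filtering at small simulated cohort scales can leave too few samples
  per group for pairwise F_ST; the analysis drivers restrict to groups
  with enough retained samples.
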