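# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of the `lupings` toolkit.

## Genomic prediction

The prediction model is the standard single-trait homoscedastic-marker
mixed model `y = 1μ + Wu + e` with `u ~ N(0, σu²I)`, `e ~ N(0, σe²I)`, and
`W` the dosage matrix centered at twice the training allele frequencies.
The variance ratio `λ = σe²/σu²` is estimated by REML in the contrast space
orthogonal to the intercept: with `M = Qᵀ(WWᵀ)Q = VΘVᵀ` and `η = VᵀQᵀy`,
the restricted profile deviance `(n−1)·log Σ ηᵢ²/(θᵢ+λ) + Σ log(θᵢ+λ)` is
minimized over `log₁₀λ ∈ [−8, 8]` (bounded scalar search). Marker effects
follow as `û = Wᵀ(WWᵀ+λI)⁻¹(y−μ̂)` with the GLS intercept `μ̂`; by the
push-through identity this equals the ridge solution
`(WᵀW+λI)⁻¹Wᵀ(y−μ̂)`, which is the oracle the tests check against.
A constant phenotype short-circuits to zero effects and an infinite λ.

WGBLUP replaces `WWᵀ` with `WDWᵀ`, `D = diag(dₖ)`,
`dₖ = ûₖ²/mean(û²)` from an initial rrBLUP fit (mean weight 1; the weight
formula is a convention, configurable via the `weights` argument). Effects
are reported as `D Wᵀ α` so that prediction remains `intercept + W_new·û`.
With unit weights the fitted breeding values coincide with rrBLUP to
numerical tolerance — an invariant the acceptance suite enforces at 10⁻⁶
relative.

Predictions for new genotypes always center with the *training* allele
frequencies, so a genotype sitting exactly at those frequencies predicts to
the intercept, and markers absent from the new panel are a hard error.

Cross-validated predictive ability uses seeded k-fold partitions, refits
the model per fold, and computes one Pearson r per repeat on the pooled
held-out predictions (pooling is more stable than per-fold averaging at the
training sizes used here, ~80–150 genotypes). Note that under a true null
the pooled r is slightly negative, not zero: held-out predictions shrink
toward the training-fold mean, which anticorrelates with the held-out
observations. The test suite therefore checks the null one-sidedly (no
spurious *positive* ability).

The phenology-adjusted yield statistic is the residual of an ordinary
least-squares regression of genotype yields on onset of flowering —
removing the drought-escape component of yield; residuals sum to zero and
are orthogonal to the flowering vector.

## Quality control

Marker statistics are computed from non-missing calls: missing rate,
heterozygosity (fraction of calls equal to 1; defined as 0 for a marker
with no calls), minor-allele frequency, and a monomorphic flag (MAF = 0).
Filters use strict thresholds — a marker is kept iff missing rate < 0.3 AND
heterozygosity < 0.3 and it is polymorphic; genotypes are kept iff missing
rate < 0.5. Marker filters run first and genotype missing rates are then
recomputed on the retained panel; this order is a fixed convention (it
changes only borderline genotypes) and makes filtering idempotent. Each
removed item carries one reason, assigned in the priority order
monomorphic → missing rate → heterozygosity.

Imputation is a deterministic k-nearest-genotype mode imputer (default
k = 10): similarity is the fraction of identical calls over shared
non-missing markers; neighbour order is similarity-descending with input
order as the tie-break, and mode ties resolve to the lowest dosage. A
random-forest imputer is the field's common alternative, but it is not
bit-reproducible across stacks; downstream predictions depend only weakly
on the imputer, and determinism is required for testing. Observed calls are
never altered; a marker with no observed calls is a named error.

## Synthetic populations and trials

The generator exists to give every downstream stage inputs with the right
*statistical structure*; its defaults describe the study conditions the
package is built around, not estimates of any real germplasm.

* **Factorial-cross lines** — 4 × 4 parents, 45 lines per cross (720
  lines), F1 advanced five selfing generations by single-seed descent.
  Founders are fully homozygous with per-locus allele frequencies
  Uniform(0.1, 0.9); loci segregate independently (no linkage map — linkage
  is irrelevant to the statistics validated here). Residual heterozygosity
  at loci segregating within a cross is (1/2)⁵ ≈ 3.1% in expectation.
* **Landrace collection** — 113 accessions × 4 fully homozygous genotypes
  (452). Accession allele frequencies drift from a common base under a
  Balding–Nichols Beta model with Fst = 0.30. The value is deliberately
  high for a neutral-drift model: with unlinked loci the accession
  structure is the *only* relatedness a GS model can exploit, and at lower
  Fst an 81-genotype training set predicts the collection essentially at
  random, which would make the landrace track uninformative rather than
  "modestly successful" as a landrace programme with real linkage
  disequilibrium is.
* **Trait architectures** — sparse additive effects at 10–60 QTL per trait
  (Normal(0,1)); flowering time gets 2 major genes inflated to carry the
  dominant share (≥ 50%) of genetic variance, reflecting the major-gene
  control of flowering in this crop. Genetic values are rescaled to
  calibrated trait scales (grain yield mean 3.53 t/ha, genetic SD
  0.45 t/ha; flowering 15.95 ± 1.5 d; etc.) so synthetic outputs are
  directly comparable with the published validation-trial tables.
* **Trials** — plot values decompose as genotype + water + soil +
  water × soil + genotype-specific sensitivities (GEI) + block(environment)
  + plot error, over 2 × 2 environments × 4 blocks. Environment effects are
  calibrated to the published environment means (e.g. drought −0.375,
  sandy-loam +0.465 t/ha for yield). Noise SDs are expressed in units of
  each trait's genetic SD; the plot error defaults to the value that makes
  genotype means over r blocks realize the target heritability
  (`σp = σg √(r(1−h²)/h²)`), and can be overridden (0 gives the exact
  noise-free limit in which genotype means equal genetic values).
  Crossover GEI is implanted explicitly: designated genotype pairs get
  equalized genetic values and sign-flipped water sensitivities sized
  ~2.5× the expected LSD, guaranteeing the phenomenon is detectable.
* **GBS noise** — per-marker and per-genotype missing rates drawn from
  configurable ranges, combined per cell as independent dropout, plus
  heterozygous miscalls of homozygous calls at 3%. Designated bad
  markers/genotypes receive rates above the QC thresholds so the filters
  are exercised with known ground truth.

All randomness derives from one integer seed through named CRC-keyed
sub-streams (`stream(seed, label)`), so every operation is reproducible
independently of call order.

What the generator does **not** emulate: linkage disequilibrium and genetic
maps, dominance and epistasis, selection history, spatial field trend, and
genotype-specific missingness patterns of real GBS libraries. Passing tests
therefore demonstrate the *statistical machinery* is correct and calibrated
— not that real populations will show the same predictive abilities.

## Trial analysis

The partitioned ANOVA assumes a complete balanced g × 2 × 2 × r layout and
computes sums of squares from the closed-form balanced decomposition
(exact, oracle-testable; no general REML). The environment term and its
genotype interaction are split into water amount, soil type and
water × soil. Error terms follow the split-plot-like structure of managed
environments: water, soil and water × soil are tested against
block-within-environment (df = 4(r−1)); genotype and all
genotype-involving interactions against the residual (df = 4(g−1)(r−1)).
Unbalanced data are a hard error (out of scope by design).

LSD at level α is `t(1−α/2, df_err)·√(2·MS_err/n)`, with n the number of
plots per compared mean — r·2 = 8 for genotype means across two soil types,
g·r for environment means. Letter groupings use a descending-mean sweep
over maximal homogeneous runs; a difference of exactly the LSD is
significant (strict `<` for homogeneity), with the convention that exactly
equal means always share a letter (relevant only in the degenerate LSD = 0
case). Crossover detection reports a genotype pair iff their mean
difference reverses sign across the two conditions and reaches the LSD in
both.

Reduction percentages (water budgets, stress-induced trait reductions) are
rounded to the nearest integer, the precision at which such values are
reported. One published water-budget row prints 64% where its own printed
inputs give 64.52% → 65; the package reports the exact computation.

## The pipeline

`run_pipeline` executes three tracks from one seeded configuration:
breeding lines for drought (rrBLUP + WGBLUP averaged, genomically predicted
flowering window, 138 training / ~580 candidates), landrace genotypes for
drought (rrBLUP, observed accession-level flowering within m ± s in each of
four environments, 81 training), and breeding lines for calcareous soil
(standardized yield + lime-tolerance index from a primary site, secondary
site quartile constraints per role, 140 training). Each track validates its
predicted top/mid/bottom trio plus a phenotypically selected training-set
top in a simulated 2 × 2 factorial trial and reports whether the predicted
ordering was realized under stress, with ANOVA, LSD and crossover output.

Two pipeline-specific simulation choices:

* The validation trial's plot error is set to 1 genetic SD (LSD ≈ 0.45 t/ha
  for grain yield at r = 4), the precision of a well-run managed-environment
  trial, rather than the larger h²-derived error of the training
  experiments.
* The top/mid crossover of the drought tracks is implanted through explicit
  water-sensitivity overrides computed from the selected genotypes'
  population-scale genetic values: the top line gets a drought advantage
  and the mid line a moisture-favorable advantage sized ~1.6 LSD, bounded
  so that the mid line stays above the bottom line under drought and the
  top line above the bottom line under favorable water. This preserves the
  selection-induced genetic gaps (the generator's generic pair implant
  would equalize them). In the calcareous track the soil response is made
  genetic instead: grain-yield soil sensitivity is proportional to the
  genotype's lime-tolerance genetic value (0.25 yield-SD per tolerance SD).

Problem sizes for the routine checks (300 markers, 400–720 lines, 150
training genotypes, 20 seeds for the power check) were chosen as the
smallest sizes at which the statistical properties under test are stable.

## Known limitations

* Predictive abilities on synthetic unlinked-loci populations are lower
  than published values from real GBS panels (family structure carries the
  signal here; LD does there). They are not comparable numbers.
* The landrace track reproduces the qualitative "partly successful"
  outcome; with 81 training genotypes its top/mid/bottom ordering is not
  expected to be realized in every seeded run, and the run report says so
  honestly.
* The ANOVA module supports balanced designs only; missing plots must be
  handled upstream.
* `harvest_index` is a plot-level ratio; environment means of harvest
  index are means of ratios, which can differ from the ratio of mean
  weights by ~0.01.
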