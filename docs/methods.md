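# Methods

## Model and procedure

`binkat` tests whether rare genetic variation aggregated over a biological
feature is associated with a quantitative trait, adjusting for covariates.
The workflow is: read genotypes → compute minor-allele frequencies on the
analysis sample → keep functional, rare, polymorphic variants → bin them
per knowledge level → test each bin → FDR per level → influence analysis
of significant bins.

**Genotypes.** VCF genotypes are converted to alt-allele dosages, split
per ALT allele for multiallelic records (the other ALT alleles count as
REF — the common collapsing convention), then oriented to the minor allele:
if the alt frequency among called genotypes exceeds 0.5 the column is
recoded `d → 2 − d` and flagged. The MAF denominator uses called genotypes
only; missing entries are subsequently imputed with the column mean `2·maf`
so the test matrices are complete without biasing the frequency. Sample
subsetting happens *before* MAF computation, so "rare" always means rare in
the analysis sample. Rarity is strict (`0 < maf < threshold`, default
0.05); monomorphic sites carry no information and are dropped.

**Binning.** Feature definitions are flat files: BED4 for positional
levels (genes, conserved regions, regulatory regions; half-open 0-based
coordinates, converted from the VCF's 1-based positions at query time) and
two-column memberships for group levels (pathways, protein families),
which resolve to genomic extent through the gene level. Strand is ignored;
no flanking padding is applied to gene bodies. A variant may belong to any
number of features per level and contributes to all of them. Bins with
fewer than `min_bin_size` variants (default 5) are discarded. Weights are
Madsen–Browning, `w = 1/sqrt(maf(1−maf))`, computed from the pooled
analysis-sample MAF — the trait here is quantitative, so the original
unaffected-only frequency has no analogue; an unweighted mode (`none`)
is available for sensitivity analysis.

**Null model.** OLS of the trait on the covariates (intercept included),
Gaussian errors. The residual variance estimate is unbiased,
`σ̂² = r'r/(n − rank X)`, and enters the SKAT null multiplicatively
through the eigenvalues rather than by dividing Q; either convention works
if used consistently, and this one is fixed throughout. Rank-deficient
designs and traits lying in the design span are refused outright rather
than silently repaired.

**Tests.**

* *Burden*: OLS of `y` on `[X, s]`, `s = G_bin w`; two-sided t, `n − p − 1`
  df. A score with no variation beyond the covariate span yields p = 1
  with an `uninformative-bin` flag.
* *Wilcoxon rank-sum burden* (two-group designs): exact enumeration when
  both groups have ≤ 8 tie-free observations, otherwise the normal
  approximation with tie-corrected variance and no continuity correction
  (the uncorrected version is calibrated essentially exactly at the group
  sizes where the asymptotic branch engages; the correction makes mid-range
  p-values visibly conservative).
* *SKAT*: `Q = ‖Z'r‖²`, null law `Σ λ_k χ²₁` with
  `λ = σ̂² · eig(Z'MZ)`; eigenvalues below `1e-10 ×` the largest are
  discarded, and a bin whose weighted genotypes are annihilated by the
  projection (judged against the pre-projection scale of Z) is flagged
  uninformative with p = 1.

## Mixture-of-chi-squares tails

Three evaluators, tried in order under `method="auto"`:

1. **Characteristic-function inversion** (Davies's approach): the
   real-axis inversion integral is summed by a midpoint rule. The step is
   chosen so the aliasing error is bounded through stochastic domination
   of the mixture by `λ_max χ²_m` (chi-square tail at 1e-11); truncation
   stops when a decay-rate bound on the remaining sum drops below half the
   accuracy target (1e-9), with at most 1e6 terms. Equal-weight mixtures
   reduce to an exact scaled chi-square. Weights are normalized by
   `λ_max` first, which makes the returned p exactly invariant to a common
   rescaling of the weights.
2. **Ruben series**: with `β = λ_min`, the survival function expands as
   `Σ_k c_k P(χ²_{m+2k} > q/β)` with non-negative coefficients summing to
   one, so the truncation error is bounded exactly by the undistributed
   mass. Convergence is geometric at rate `1 − λ_min/λ_max`; this path
   covers the small-`m`, spread-out eigenvalue sets where the inversion
   integrand decays too slowly polynomially to be summed within the term
   budget. Capped at 50,000 terms.
3. **Liu moment matching**: four cumulants matched to a scaled noncentral
   chi-square. Used only when both exact paths fail (extremely spread
   eigenvalues) — on randomized eigenvalue sets of length ≤ 20 it tracks
   the exact value within ~7% relative for p in [0.001, 0.5].

Every result records which evaluator produced it (`p_method`); p-values
are floored at 1e-300.

## Known approximation: plug-in σ̂² versus permutation

The SKAT null treats σ̂² as fixed — the standard plug-in convention. A
residual-permutation reference conditions on the realized residual sum of
squares (every permutation shares it), so the two differ at order `m/n`.
At n = 200 this is visible: for a 20-variant bin a permutation reference
gave 0.0446, an exact scale-free sphere-pivot computation 0.0475, and the
plug-in 0.0555, while an *unconditional* Gaussian Monte-Carlo oracle
matches the plug-in within sampling error. The plug-in convention is kept
(it is what makes a single-variant bin reduce exactly to the classical
score-test chi-square), and its type-I error at the scales the tool
targets (n ≥ 300, bins of ~10) is empirically calibrated: rejection 0.0465
at α = 0.05 over 2,000 null replicates (seed 1 of the acceptance script),
with uniform p-values (KS p = 0.41). Analytic and permutation p agree within a few permutation
standard errors only for bins small relative to n; for influence *ranking*
within a bin the shared bias cancels.

## Synthetic studies

The generator emulates a single-cohort WGS endophenotype study and writes
everything a run needs (VCF, annotation sidecar, five knowledge files,
phenotype table, truth ledger). Defaults, chosen once as the study
conditions:

| parameter | default | rationale |
|---|---|---|
| samples | 750 | a realistic single-cohort imaging-genetics sample |
| MAF | uniform on [0.001, 0.049] | rare spectrum under the 0.05 threshold |
| genotypes | binomial(2, maf), no LD | Hardy–Weinberg; LD is not needed to exercise the contracts |
| covariates | 3 standard normal + 1 binary, effects (0.4, 0.3, −0.2, 0.25) | emulates age/education/ICV-style plus sex/scanner-style confounders |
| noise | N(0, 1) | trait on unit scale |
| causal effect β | 0.25 per minor allele | mid-power regime at n = 500–750, where the burden/dispersion contrast is visible |
| same-sign regime | all bin variants causal, equal +β | the "shared direction, similar magnitude" case that favors burden |
| mixed-sign regime | half the bin causal, alternating ±β | cancellation in the collapsed score; favors the dispersion test |
| influence analysis | one planted variant, β = 2.0, in a 16-variant bin | a decisively large single-variant effect |

Layout: genes tiled along numbered chromosomes; each conserved region
spans the adjacent halves of two neighboring genes (so ECR bins straddle
gene boundaries and variants are multi-members); regulatory regions cover
whole gene bodies; pathways partition the genes; protein families tile
them. Positions are drawn uniformly without replacement inside gene
regions; function classes are sampled from a configurable distribution
(default 80% nonsynonymous, 15% splicing, 5% stop-gain), with per-gene
override lists for structured fixtures.

What the generator does **not** model — linkage disequilibrium, population
structure, genotyping error, annotation error — bounds what passing tests
show: calibration and power orderings hold for independent rare genotypes
with Gaussian traits, and real data can depart from them (e.g. inflation
under cryptic relatedness).

## Numerical and design choices

* Complete-case handling: samples missing the trait or any covariate are
  dropped before MAF computation, so frequencies always describe the
  tested sample.
* FDR is Benjamini–Hochberg within each binning level; the levels ask
  different questions over different feature universes, and correcting
  them jointly would let a densely-binned level dominate the others.
* Deterministic output: bins sort by (chromosome of first region,
  feature id); result rows by (p, feature id); re-running a configuration
  reproduces every output byte-for-byte.
* Leave-one-out tables sort ascending by removal p; the most influential
  variant is the last row.
* Two-sided tests throughout; no genomic-control correction.
* The sidecar annotation table wins over the VCF INFO tag where both are
  present, since external annotation is usually fresher than what was
  embedded at call time.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: 2,000 null replicates (n = 300, 10-variant bins) for type-I
calibration, 200 replicates per power regime (n = 500), 100 replicates for
influence recovery, 50,000 permutations per permutation comparison, 10⁷
Monte-Carlo draws per mixture-tail check, and 50 full pipeline replicates
(n = 750) for end-to-end recovery. These are the package's chosen study
sizes; larger runs only tighten the same estimates.

## Limitations

* Quantitative traits with Gaussian errors only; no logistic/binary-trait
  dispersion test, no mixed models or kinship adjustment, no SKAT-O-style
  omnibus combination, and no small-sample moment adjustment of the SKAT
  null (see the plug-in discussion above).
* Binning is purely positional; exon/intron sub-binning and locus-role
  weighting are out of scope.
* The knowledge store consumes pre-exported flat files; building them from
  primary databases is the user's concern.
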