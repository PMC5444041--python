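# binkat

Knowledge-driven binning and association testing of **rare variants**
against a **quantitative trait**.

Single-variant association tests have essentially no power for rare
variants (minor allele frequency, MAF < 0.05): too few carriers per site.
`binkat` recovers power by *binning* — aggregating the rare variants that
share a biological feature and testing each bin as a unit. Bins are defined
at five levels of biological knowledge supplied as flat files:

| level            | definition file                  | membership |
|------------------|----------------------------------|------------|
| `gene`           | BED4 (`chrom start end gene_id`) | positional |
| `ecr`            | BED4 (evolutionary conserved regions) | positional |
| `regulatory`     | BED4                             | positional |
| `pathway`        | TSV (`gene_id<TAB>pathway_id`)   | via member genes |
| `protein_family` | TSV (`gene_id<TAB>family_id`)    | via member genes |

A variant inside several overlapping features contributes to every one of
their bins, and to every level independently.

## The statistics

Let `y` be the trait, `X` the covariate design (intercept included), and
`G` the `n × m` minor-allele dosage matrix of a bin's variants, weighted by
the Madsen–Browning scheme `w_j = 1 / sqrt(maf_j (1 − maf_j))` that
up-weights the rarest variants. With `Z = G diag(w)`, the null model
`y = Xb + e` is fit once by OLS, giving residuals `r` and
`σ̂² = r'r / (n − rank X)`. Each bin is then tested with one of:

* **Weighted burden regression** — OLS of `y` on `[X, s]` with the
  collapsed score `s_i = Σ_j w_j g_ij`; two-sided t test on the score
  coefficient. Most powerful when the bin's variants push the trait in the
  same direction.
* **Wilcoxon rank-sum burden** — rank test of the scores between two
  sample groups (exact enumeration for tiny groups, tie-corrected normal
  approximation otherwise).
* **SKAT** (dispersion test) — variance-component score statistic
  `Q = ‖Z'r‖²`, whose null law is the mixture `Σ_k λ_k χ²₁` with
  `λ = σ̂² · eig(Z'MZ)`, `M = I − X(X'X)⁻¹X'`. Robust to mixed effect
  directions and to non-causal variants in the bin. The mixture tail is
  evaluated by characteristic-function inversion (Davies's approach) with
  an exact Ruben chi-square series and a Liu moment-matching fallback
  (`p_method` records which was used).

P-values are adjusted per level with Benjamini–Hochberg FDR, and every bin
passing the FDR threshold gets a **leave-one-variant-out** influence table:
the bin is re-tested with each variant removed in turn, and the variant
whose removal weakens the signal the most (largest p) is the most
influential.

## Worked example

Everything needed for a run can be generated synthetically — VCF,
annotation sidecar, knowledge files, phenotype table, and a truth ledger
recording the planted effects:

```sh
cat > sim.cfg <<EOF
n_samples = 750
seed = 11
causal_feature = GENE03
causal_fraction = 0.5
causal_beta = 0.6
causal_sign = same
EOF
binkat simulate --config sim.cfg --out fix/
binkat run --vcf fix/study.vcf --pheno fix/phenotype.tsv --pheno-col trait \
    --covars cov1,cov2,cov3,cov4 --knowledge-dir fix/ \
    --levels gene,pathway,pfam,ecr,regulatory --out out/
binkat summarize --results out/ --top 3
```

The run prints the filter chain and per-level outcomes:

```
counts: {'samples': 750, 'variants_read': 96, 'functional': 96, 'rare': 91,
         'binned': {'gene': 12, 'pathway': 3, 'protein_family': 3, 'ecr': 4, 'regulatory': 4}}
[gene] 12 bins tested; best p = 1.16e-09
```

96 variants were read, 96 carry a functional annotation, and 91 are
polymorphic with sample MAF < 0.05; they fold into 12 gene bins of ≥ 5
variants. The gene summary ranks the planted gene first:

```
level feature_id  n_variants test  statistic      p_value        fdr_q p_method
 gene     GENE03           8 skat   103528.0 1.164390e-09 1.397260e-08   davies
 gene     GENE09           7 skat    29093.9 1.881810e-02 1.129090e-01   davies
```

`GENE03` carries four planted causal variants (per-allele effect 0.6,
listed in `fix/causal.tsv`); its SKAT p of 1.2e-09 survives FDR correction
(q = 1.4e-08) while every other gene stays at q > 0.11. Because the bin is
FDR-significant, a leave-one-out table is written automatically
(`out/loo_gene_GENE03.tsv`, sorted by removal p):

```
variant_id  p_without_variant  function_class
rs53873     3.76509e-10        nonsynonymous
...
1:30698     7.42835e-05        nonsynonymous   <- most influential
```

Removing `1:30698` — one of the planted causal variants — weakens the
association by four orders of magnitude; removing any non-causal variant
leaves p essentially unchanged.

The same analysis is available as a library (`binkat.simulate`,
`binkat.pipeline.run`, and the `binkat.stats` test functions) for use in
notebooks and simulation studies.

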