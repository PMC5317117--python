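# sigvalid

Validation diagnostics for PCA-based gene-expression signature scores.

## The problem

A common way to turn a gene signature — a list of genes with a direction
(−1/+1) and optionally a magnitude per gene — into a single per-sample score
is principal component analysis: restrict the expression matrix to the
signature genes, standardize each gene, and use the first principal
component score *t₁* as the signature score, with the loadings *p₁* giving
each gene's weight and direction. The score behaves like a noise-robust
weighted average, but it inherits PCA's pitfalls: a "signature" of genes
that do not actually co-vary in the new dataset still produces a score; a
signature mixing two independent biological effects yields a PC1 that
describes only one of them (and which one can change between datasets); and
in datasets dominated by one global effect (proliferation, batch, RNA
quality), *random* gene-sets produce scores that track that effect and can
look outcome-associated.

`sigvalid` quantifies whether a PCA-based signature is trustworthy on a
given dataset **before** it is used downstream, via four statistics, each
calibrated against an empirical null distribution built from randomized
gene-sets of the same size:

| statistic | definition | good signature |
|---|---|---|
| coherence | PC1 explained variance (%) of the signature PCA, `100·λ₁/Σλ` | far above the random mean |
| robustness | `λ₁/λ₂`, the PC1/PC2 explained-variance ratio | ≫ 1 (a ratio near 1 flags a mixed, multi-effect signature) |
| uniqueness | \|Pearson r\| between signature PC1 scores and all-gene PC1 scores | low (distinct from the dataset's general direction) |
| transferability | squared Pearson r between PC1 loadings and the signature's reference values | near 1 (the model measures the intended biology) |

Expression values are log2-scale; every gene is mean-centered and scaled to
unit variance first, so the PCA eigenvalues λ are those of the gene–gene
correlation matrix. The null distributions come from N (default 10,000)
gene-sets drawn uniformly from all dataset genes, with add-one empirical
p-values `(1 + #as-or-more-extreme)/(N + 1)`; coherence and robustness are
tested in the upper tail, uniqueness in the lower tail.

## Worked example

The built-in generator plants known structure (a latent-factor model with
closed-form correlations), so a signature's expected behavior is known:

```python
import sigvalid as sv

# a cohort with a 29-gene two-group signal (e.g. gender-like), a dominant
# 100-gene continuous signal (proliferation-like), a mild dataset-wide
# bias, and 500 unstructured background genes
design = sv.SyntheticDesign(
    n_samples=200, n_background_genes=500,
    blocks=[sv.Block(size=29, rho=0.5, factor="two-group"),
            sv.Block(size=100, rho=0.4)],
    bias_fraction=0.3, bias_strength=0.4, seed=0)
matrix, manifest = sv.generate_dataset(design)

signature = sv.make_signature(manifest, [0], name="planted29")
report = sv.validate_signature(matrix, signature, n_random=10000, seed=1,
                               dataset_name="cohort")
print(report.to_text())
```

prints (abridged):

```
coherence_pct         50.38540526
robustness_ratio      11.19521798
uniqueness_abs_r      0.01148593554
transferability_r2    0.9976240715
random_mean_coherence   9.669218587
empirical_p_coherence   9.9990001e-05
random_mean_robustness  1.396871627
empirical_p_robustness  9.9990001e-05
random_mean_uniqueness  0.6486180618
empirical_p_uniqueness  0.004899510049
```

Read: the 29 planted genes explain 50.4% of their variance in PC1 against a
random-set mean of 9.7% (no random set scored higher: p = 1/10001), one
component dominates (ratio 11.2 vs 1.4 for random sets), the score is nearly
orthogonal to the dataset's dominant direction (|r| = 0.011 while random
sets average 0.649), and the fitted loadings reproduce the planted gene
directions (r² = 0.998). All four checks pass; the score measures what it
was meant to.

The same API exposes sklearn-style estimators (`GeneScaler`, `OrientedPCA`,
`SignatureValidator`) that compose with sklearn pipelines; the module
functions above are thin wrappers over them.

## Command line

```bash
sigvalid simulate --config design.yaml --seed 2 --out sim/
sigvalid validate --expression sim/expression.tsv \
                  --signature sim/signature_planted.tsv \
                  --n-random 10000 --seed 1 --figures --out run/
sigvalid report --run run/ --out run/validation.png
```

`validate` writes a Table-style summary TSV (fixed column order), a
key-value report, per-statistic null TSVs, loadings/scores exports, a log,
and optionally the four-panel validation figure (null histograms for
coherence/robustness/uniqueness with the observed value marked, plus the
loadings-vs-reference transferability panel). Identical inputs and seed
give byte-identical tables. Expression input may be TSV, CSV, or GCT 1.2;
signatures are two-column `gene_id<TAB>reference_value` files.

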