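# Methods

## Model and procedure

A gene signature is an ordered list of genes with a reference value per
gene: −1/+1 for direction-only signatures, or a continuous weight (typically
the gene's PC1 loading in the training dataset). Given a genes × samples
log2 expression matrix, the pipeline is:

1. **Matching.** Signature genes are matched to matrix rows by exact,
   case-sensitive identifier equality. Probeset-style duplicate row ids are
   kept and suffixed `.1`, `.2`, … at load; every suffixed copy of a
   signature gene matches and inherits its reference value. The match
   fraction is computed over *distinct* signature genes and must reach
   `min_match_fraction` (default 0.5 — below half the signature, the object
   being validated is materially a different signature). Identifier
   translation (probeset ↔ symbol) is deliberately out of scope: it must be
   applied upstream, and multiple probesets per gene are never aggregated.
2. **Scaling.** Every gene is mean-centered and scaled to unit variance
   across samples (sample sd, ddof=1; the denominator does not affect
   correlations or explained-variance shares, documenting it makes results
   bit-reproducible). Genes with sd < 1e−12 on the log2 scale are dropped
   with a warning. Scaling is always per-gene, never per-sample.
3. **PCA.** The signature-restricted and the all-gene PCA are computed by
   SVD of the scaled samples × genes matrix; eigenvalues λᵢ = sᵢ²/(n−1) are
   those of the gene–gene correlation matrix, and explained variance is
   100·λᵢ/Σλ. Default k = 5 components (capped by the rank bound
   min(#genes, n−1)) to feed the scree-style profile. Requesting components
   beyond the rank bound is an error; a numerically rank-deficient input
   (e.g. perfectly correlated genes) fits with ~zero trailing eigenvalues
   and a warning instead of crashing, and robustness then reports a +inf
   sentinel.
4. **Orientation.** Component signs are arbitrary; scores and loadings are
   always flipped together. Policy: if a reference vector is supplied and
   its Pearson correlation with a component's loadings is nonzero, the sign
   making the correlation positive is chosen; otherwise the
   largest-magnitude loading is made positive (exact-zero tie → positive
   first element, logged). All four statistics are invariant to
   orientation; the policy only stabilizes exported scores/loadings.
5. **Statistics.** Coherence = PC1 explained variance (%); robustness =
   λ₁/λ₂; uniqueness = |Pearson r| between signature PC1 scores and
   all-gene PC1 scores (the all-gene model excludes nothing — removing the
   signature genes would change the very "general direction" being compared
   against); transferability = squared Pearson r between PC1 loadings and
   the matched reference values. Pearson is used throughout, including for
   ±1 references (a point-biserial-style correlation; plain Pearson is
   reported, not an adjusted variant). Transferability is squared to be
   orientation-free, and is computed for PC1 only — the signature score is
   always PC1. Reference magnitudes are only ever the comparison vector;
   they never re-weight expression before PCA.
6. **Null engine.** N randomized gene-sets (default 10,000) of exactly the
   matched signature-row count are drawn uniformly without replacement from
   all dataset rows — signature genes included, as the unbiased reading of
   "random equal-size sets". One shared draw stream serves all statistics.
   Per draw, a signature-restricted PCA yields coherence, robustness and
   uniqueness; transferability has no random analogue because random sets
   carry no reference values. Draws whose PCA fails are retried and
   counted; more than 1% failures aborts. Empirical p-values use the
   add-one estimator (1 + b)/(N + 1), so "no random set scored higher"
   yields 1/(N+1), never 0. Coherence and robustness are upper-tail tests;
   uniqueness is lower-tail (a distinct signature correlates *less* with
   the general direction than random sets do). Infinite robustness draws
   are recorded apart and excluded from the null mean but count as extreme
   in the upper-tail p.

## Synthetic data generator

The generator is a latent factor model: gene g in block b is
`x = s_g·√ρ_b·f_b + β·h·[bias-loaded] + √(1−ρ_b)·σ·ε + baseline_g`, with one
standard-normal factor f_b per block per sample, a single dataset-wide bias
factor h (the stand-in for a dominant proliferation/batch direction), sign
s_g ∈ {−1,+1} per gene, independent noise ε, and a per-gene baseline making
values look like log2 intensities (removed by standardization). Two-group
factors are ±1 labels standardized to mean 0, variance 1, so coherence
formulas hold regardless of group balance. This construction was chosen
because it has closed forms: at σ=1 the within-block correlation is exactly
ρ and a k-gene block's leading correlation eigenvalues are 1+(k−1)ρ and
1−ρ, giving analytic targets (coherence → 100·(1+(k−1)ρ)/k %, robustness →
(1+(k−1)ρ)/(1−ρ)).

`make_signature` builds signatures from planted blocks (reference = planted
sign, or planted loading s·√ρ), optionally diluted: a fraction d of block
genes is *replaced* by background genes with random ±1 references (keeping
the nominal size fixed); an append mode is also provided, since
"adding unrelated genes" and "X/Y percent of a fixed size" suggest
different constructions — replace is the default. Dilutions leaving fewer
than 3 true genes warn rather than fail; that extreme is a deliberate
stress case.

What the generator does **not** emulate: platform/probe effects, count
noise, multiple batch axes, heavy-tailed expression, or — importantly —
reference values that misalign with a dataset's realized loadings. In the
factor model, a block's PC1 loadings are proportional to its planted signs,
so transferability of any signature whose PC1 locks onto one intact block
is high by construction (≈ k_block/k_total when locked). Real mixed
signatures can show near-zero transferability because real training-set
loadings do not survive transfer so cleanly; passing tests on synthetic
data therefore demonstrate the *diagnostics'* behavior (coherence/
robustness collapse, uniqueness tracking bias, PC1 locking), not the full
range of real-data transferability failures. For two planted blocks of
exactly equal size and strength, the top eigenvalue is degenerate and the
sample PC1 is an essentially uniform rotation within that 2-D eigenspace:
PC1 then locks to a *single* block's factor only at imbalanced sizes, and
switches blocks across the balance point — mirroring how a mixed
signature's meaning flips between datasets.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| `n_random` (N) | 10,000 | resolves p down to 1/10,001; reduce for exploration, at the cost of Monte-Carlo error in null means |
| `min_match_fraction` | 0.5 | below half the signature, validation targets a different object |
| `n_components` | 5 | feeds the scree profile; statistics use only PC1/PC2 |
| scaling ddof | 1 | sample sd; affects nothing but bit-reproducibility |
| zero-variance tol | 1e−12 (sd, log2 scale) | constant rows carry no correlation signal |
| block ρ | [0,1) | within-block population correlation; 0.4–0.6 emulates strong published-signature coherence |
| bias β, fraction | 0, 0 | dataset-wide confounded direction; β≈0.3–0.6 on 30–50% of genes reproduces the random-signatures-track-PC1 regime |

## Numerical choices and degenerate inputs

SVD rather than explicit correlation matrices; exact eigenvalue ties keep
SVD output order (the robustness ratio ≈ 1 is then itself the correct
diagnostic). Empirical p is add-one. Constant reference vectors are
rejected at signature load (transferability undefined). Matrices need ≥ 2
genes and ≥ 3 samples; matches need ≥ 3 distinct genes. Missing values are
rejected unless per-gene mean imputation is explicitly enabled. Null
histograms use a fixed 50-bin rule for reproducible figures.

## Problem sizes used in the test and acceptance runs

Simulated cohorts use 50–250 samples and a few hundred background genes,
nulls of N = 150–2,000 in tests (10,000 remains the analysis default), a
single n = 100,000-sample run for the closed-form equicorrelation check,
and 200–500 calibration replicates at N = 199. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

- Exact-id matching only; no identifier translation or probeset
  aggregation.
- The null draws from matrix rows as-is (probeset level if the matrix is);
  whether to collapse to unique genes first is the user's modelling call.
- No parametric nulls (Tracy–Widom/Marchenko–Pastur); the calibration is
  purely resampling-based.
- No normalization, batch correction, or survival/outcome analysis —
  validation here is deliberately upstream of, and independent from,
  outcome association.
- Thresholds for "good" values are not built in: the statistics and their
  nulls are reported; the verdict is the analyst's.
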