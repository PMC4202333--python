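# Methods

## Model and procedure

The analysis treats each gene set *s* (autosomal, X-linked, X-hemizygous)
as a sample of annotated genes, each independently belonging to a target
category *c* (N-mt: GO:0005739; N-cp: GO:0009507) with some per-set
probability. The null hypothesis is homogeneity: one common probability
across sets, estimated by the pooled proportion
`p_c = Σ_s O_sc / Σ_s n_s` over annotated genes.

Three complementary views of the same question are computed:

1. **Enrichment ratios** `R_sc = O_sc / (p_c · n_s)` with percentile
   bootstrap CIs (default 10,000 replicates, level 0.95).
2. **An exact 2×3 test** (Freeman–Halton): conditioning on all margins of
   the in-category/not-in-category × gene-set table, the two-sided
   p-value sums multivariate hypergeometric probabilities of every
   margin-consistent table no more probable than the observed one. Full
   enumeration over the two free cells of row 1; at the default sample
   sizes this is ~2.5–2.9 × 10⁴ tables and runs in milliseconds.
3. **Pairwise exact 2×2 tests** between set pairs, of separate interest
   for the hemizygous-specific comparisons; these are reported but the
   2×3 test is the primary analysis.

### Category membership

A gene is in a category iff the category's GO identifier is literally a
member of its GO term set. No propagation through the ontology is
performed: Blast2GO-style annotation pipelines already emit the
cellular-component assignment itself, and exact membership keeps the
classification transparent and data-independent. Genes whose annotation
failed are retained in tables but excluded from every statistical
denominator — an unannotated gene carries no information about category
membership. A gene may be both N-mt and N-cp; the two categories are
analysed independently throughout.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `target_terms` | GO:0005739 / GO:0009507 | category-defining GO identifiers |
| `n_boot` | 10,000 | bootstrap replicates per CI |
| `level` | 0.95 | CI level |
| `alpha` | 0.05 | test level used in power/calibration work |
| `tie_rel_tol` | 1e-7 | relative tolerance for probability ties in the two-sided sum |
| `max_tables` | 1e7 | enumeration cap; beyond it the exact test refuses and the chi-square fallback applies |

## Numerical choices

- All factorials are evaluated as log-gamma; probabilities are
  exponentiated only at the final sum, so grand totals of a few thousand
  genes are nowhere near overflow.
- Probability ties: a candidate table counts toward the two-sided sum when
  `log P(table) ≤ log P(observed) + log1p(1e-7)`, the usual floating-point
  tie convention for probability-ordering exact tests. The p-value is
  clamped to `(0, 1]` and never falls below the observed table's own
  probability.
- The bootstrap resamples gene indices in fixed-size chunks; all
  randomness derives from a single integer seed through
  `numpy.random.SeedSequence` substreams (one per gene set × category),
  so reports are bit-reproducible and independent of evaluation order,
  and changing `n_boot` cannot alter counts, ratios, or p-values.
- Degenerate inputs fail loudly: empty tables, zero annotated genes, zero
  expected counts, inconsistent margins and malformed GO identifiers all
  raise typed validation errors rather than producing NaNs.

## Bootstrap design

The CI describes sampling variation of the observed count: the focal
set's annotated genes are resampled with replacement at the same size and
the expected count stays fixed at its full-data value. An option
(`refit_expected=True`) also resamples the other sets and recomputes the
pooled proportion per replicate, propagating denominator uncertainty, as
a sensitivity analysis. Percentile bounds (not BCa) are used: they make
the fewest assumptions, and the ratio statistic is a smooth monotone
transform of a binomial count for which percentile intervals are
well-behaved at these sample sizes.

Coverage was validated in the regime the intervals are used in (set size
~500, membership probability ~0.2) against a *known* expected count via
the `expected` override: semi-analytic calculation puts true coverage of
a 95% interval at ≈0.956, and the simulation check in the test suite
requires 0.93–0.97 over 500 simulated datasets. When the expected count
is instead estimated from the pooled data under a global null, measured
coverage rises to ≈0.98, because the pooled proportion is positively
correlated with the focal set's observed count; the fixed-denominator
design is therefore the one with calibrated coverage, and the pooled
variant should be read as descriptive.

## Synthetic data generator

The generator emulates the annotation-table level of the study: three
gene sets with configurable sizes (default 1,167 / 624 / 107), a per-set
annotation success probability (default 0.90), and independent Bernoulli
category membership among annotated genes at baseline proportions
(default 301/1735 ≈ 0.173 for N-mt, 346/1735 ≈ 0.199 for N-cp) scaled by
per-(category, set) multiplicative effects ρ (1.0 = null). Configurations
that push any effective probability outside [0, 1] are rejected rather
than clamped. Flagged genes receive the target GO identifier plus 0–3
decoy terms; decoys include identifiers one digit away from the targets,
so exact matching is exercised against near-misses. An optional
Gaussian-copula correlation couples the two category memberships for
robustness experiments; the default is independence, matching the
analysis's treatment of the categories as separate tests.

What the generator does **not** model: sequences, reads, assembly or
SNP-segregation errors in sex-linkage assignment, ontology structure
beyond flat identifier sets, and any dependence between genes. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated for Bernoulli-sampled annotation tables, not that upstream
annotation or linkage assignment is error-free.

Effect attenuation is a structural property worth noting: with effect ρ
on one set, the recovered ratio converges not to ρ but to
`ρ / (1 + w(ρ − 1))`, where *w* is the enriched set's share of annotated
genes, because the enriched set inflates the pooled proportion in the
denominator. At default sizes (w ≈ 0.33) a planted ρ = 1.5 yields a ratio
near 1.29, and ρ = 2.0 near 1.5; tests recover the attenuated value.

## Power analysis

Power for detecting an absolute difference δ between two sets' category
proportions is estimated by simulation: counts drawn as Binomial(n1, p0)
and Binomial(n2, p0 + δ), each replicate tested with the package's own
exact 2×2 test, two-sided α = 0.05, default 10,000 replicates (2,000 in
the routine checks). The baseline defaults to the pooled category
proportion of the data under analysis (0.1735 for N-mt at the default
counts). δ is an absolute difference in proportions. Duplicate count
pairs share one p-value evaluation, keeping large replicate numbers
cheap. Published power figures for this design ("about 60%/80%") are
treated as qualitative orderings — the exact baseline and test variant
behind them are not recoverable — and the checks assert monotonicity in
δ, n2 and α plus the orderings implied by the study's sample sizes.

## Problem sizes in routine checks

Calibration and recovery checks run at the study's set sizes with 500
null datasets and 200 effect datasets; coverage uses 500 simulations of a
500-gene set with 2,000 bootstrap replicates; power points use 2,000
replicates. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping the full suite fast on one core.

## Known limitations

- The exact-test enumeration is exponential in K; it is intended for the
  2×3 (and 2×2) tables of this design. The chi-square fallback covers
  larger layouts, at the usual asymptotic caveats.
- Expected counts assume the autosomal gene sample is representative of
  autosomes as a whole; per-chromosome expectations are out of scope
  (the study design lacks chromosome assignments for autosomal genes).
- The printed two-sided p-values of the original analysis carry
  Monte-Carlo jitter of order 0.005 (they are consistent with a simulated
  exact test); this package's enumeration is deterministic, so its values
  (0.4974 / 0.3076 at the default counts) are exact for the stated tables
  and differ from the printed figures in the third decimal place.
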