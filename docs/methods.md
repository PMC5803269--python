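# Methods

This note documents the statistical models implemented in `humisig`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Signature model

The target quantity is the set of genes preferentially expressed by a
minority cell type (microglia, ~12% of cortical cells) relative to bulk
tissue. Writing `x_gs` for log2 expression of gene `g` in sample `s`, the
pipeline computes

    log2FC_g = mean_{s in purified}(x_gs) − mean_{s in bulk}(x_gs)

after preprocessing and artifact normalization, and defines the signature as
`{g : log2FC_g ≥ log2(4)}` (the *FC set*; one-sided, boundary inclusive,
because the object of interest is genes *above* bulk, not merely different).
A stricter *PVAL set* additionally requires a BH-adjusted moderated-t
p < 0.05. The FC set is the primary output: statistical significance at
n = 10 purified donors depends on between-donor variability, which partly
reflects genuine biology (responses to varying pathology), so screening on
significance would discard environment-responsive genes.

Under the mixture model for bulk tissue (see below), a marker expressed at
ratio `2^e` in microglia versus other cell types appears in bulk at roughly
`f·2^e + (1−f)` times its baseline, with `f` the microglia fraction. At the
default `e = 4`, `f = 0.12` this yields an expected purified:bulk ratio of
`16 / (0.88 + 0.12·16) ≈ 5.7` (log2 ≈ 2.5), comfortably above the 4-fold
threshold — which is why the threshold is a fold change of 4 rather than 16.

### Preprocessing

- Low-expression filter: a gene is dropped when its abundance is below 0.1
  (FPKM-like units) in more than 2 samples, counting absolute sample
  numbers; applied per dataset; idempotent. Both parameters configurable.
- log2(x + 1). Pseudocount 1 keeps zeros at zero and is standard for
  abundance data bounded below at 0; configurable.
- UniProt filter: genes lacking a protein identifier are removed to make the
  purified and bulk gene universes comparable; genes missing from the
  annotation are treated as lacking one (conservative).
- Optional precision weights: a lowess trend (span 0.5) of sqrt(per-gene SD)
  on per-gene mean, evaluated at the gene mean; weight = predicted^(−4).
  This is a deliberate simplification of voom — no library-size model, the
  trend is evaluated per gene rather than per observation — and the weights
  are optional inputs downstream, not part of the default path.

### Residual GC/length normalization

Sequencing chemistry and library construction leave sample-specific biases
correlated with GC content and transcript length. For each sample the
log-ratio `r_gs = x_gs − mean_s'(x_gs')` is fit as

    r_gs ~ intercept + gc_g + log10(length_g)

with a Huber M-estimator (tuning constant 1.345, ≈95% gaussian efficiency;
IRLS, max 50 iterations, tol 1e-8; statsmodels `RLM`), and the full fitted
component is subtracted from `x_gs`. Length enters as log10 — bias scales
with order of magnitude of transcript length, and the robust loss guards the
fit against the heavy-tailed ratio distribution produced by genuinely
cell-type-specific genes (which are exactly the signal the downstream
contrast must keep). M-estimators are regression-equivariant, so any bias of
the form `a·gc + b·log10(length)` added to one dataset cancels exactly in
the purified-vs-bulk contrast (verified to 1e-6 in the noiseless case).
Fitting is refused below 10 genes.

### Moderated t and multiple testing

Per gene, a two-group comparison with pooled variance `s²_g` on
`d = n₁ + n₂ − 2` degrees of freedom. Variances are shrunk toward a prior:

    s²_post = (d₀·s₀² + d·s²_g) / (d₀ + d)

with `(d₀, s₀²)` estimated from the empirical distribution of `log s²_g` by
method of moments: `e_g = log s²_g − ψ(d/2) + log(d/2)` has variance
`ψ'(d/2) + ψ'(d₀/2)` under the scaled-F model, so `d₀` comes from inverting
the trigamma function (Newton) on the excess variance of `e_g`, and
`log s₀²` from its mean. When the observed spread of `log s²` does not
exceed the chi-square sampling contribution, `d₀ = ∞` and every gene gets
`s²_post = s₀²`. The statistic `Δ/(s_post·√(1/n₁+1/n₂))` is referred to a t
distribution on `d + d₀` df. With `prior_df = 0` the ordinary two-sample t
is recovered exactly. This estimation scheme coincides with limma's
`eBayes`; a test compares the two through `Rscript` and they agree to
~1e-14. Genes with zero variance in both groups get p = 1 when the mean
difference is 0, otherwise the shrunk variance applies (no infinities).
Optional precision weights enter through weighted group means and weighted
residual sums of squares, with weights normalized to mean 1 per gene.

Multiple testing uses Benjamini–Hochberg step-up, implemented directly
(the contract includes a domain error for p outside [0, 1]); it is verified
against statsmodels and hand-applied step-up cases.

## Gene-set statistics

**Over-representation.** With universe size `N`, disease-set size `K` (in
universe), signature size `n` (in universe) and overlap `k`, the p-value is
the exact hypergeometric upper tail `P(X ≥ k)` (scipy `hypergeom.sf(k−1)`),
one-sided, no correction across sets by default (a handful of disease sets
are tested; the raw p-values are reported). The universe is an explicit
argument — the default pipeline uses the genes surviving preprocessing in
both datasets — and is recorded in the output, because ORA p-values are
meaningless without it.

**Pre-ranked GSEA.** Given a score-ranked gene list (descending; ties keep
input order), the running sum gains `|score|^w / Σ_hits |score|^w` at set
members (`w = 1` default) and loses `1/(N − |S|)` at non-members; ES is the
signed maximum deviation, with |running-sum| ties between the positive and
negative extremum resolved toward the earlier list position (1e-12 margin).
The null permutes gene labels (`n_perm` = 1000 default): NES = ES divided by
the mean |null ES| of the same sign, and the permutation p-value is
`(1 + #{same-sign nulls at least as extreme}) / (#same-sign nulls + 1)`,
which is valid (never zero) by construction. If every hit score is zero
under a positive weight, hits fall back to equal increments.

## Meta-feature and trait association

Each signature gene is divided by its across-sample standard deviation
(ddof = 1) — standardized to unit variance *without centering*, following
the construction this emulates — and the standardized values are averaged
per sample. Centering each gene would shift every sample's score by the same
constant, so regression slopes are unchanged either way: for gene constants
`c_g`, the score shift is `mean_g(c_g)`, identical for all samples, and OLS
slopes are invariant to adding a constant to the response. A centering flag
exists for users who want mean-zero scores. Zero-variance genes cannot be
standardized and are dropped with a warning.

Each trait is tested univariately (`score ~ trait`, OLS with intercept):
continuous traits as-is, binary traits 0/1 (sex reference male), APOE allele
counts as 0/1/2 numeric dosages. Missing values are dropped pairwise;
constant traits and traits with < 3 observations are reported as not
estimable rather than raising; exact fits (residual SS ≈ 0) are flagged
degenerate with SE 0. The primary-analysis significance threshold of
p < 0.01 for five hypotheses is reported, not enforced.

## Aging differential expression

Two purified-cell datasets measured under different protocols are compared
on the genes reliably detected in both: value ≥ 0.1 in ≥ 50% of samples of
*each* dataset (the detection rule parameters are exposed and logged, since
no canonical values exist). By default the pooled samples are then quantile
normalized to a common reference distribution — the two studies differ in
isolation chemistry and library construction, so distribution-level
alignment is applied before testing; it can be disabled. Classification uses
the moderated t from the signature machinery with strict thresholds:
up iff `log2FC > 2` and adjusted p < 0.05, down symmetrically. Swapping the
datasets negates every fold change and swaps the classes exactly.

## Proteome concordance

Protein identifiers are mapped to gene space through a user-supplied
two-column table (no online ID service, for reproducibility); unmapped
identifiers are reported, never silently dropped. The overlap with the
signature is an exact set intersection. Rank correlation uses Spearman with
average ranks for ties and the t-approximation p-value, comparing protein
abundance with the mean (optionally median) log2 mRNA value over the
purified samples.

## Synthetic data generator

The generator emulates the statistical structure the pipeline must cope
with, with every planted feature recorded as ground truth:

- **Profiles.** Per-gene baseline log2 expression ~ N(4, 1.5²). Each of 3
  cell types receives 50 disjoint marker genes elevated by log2 effect 4 in
  its own type. Cell type 1 is "microglia".
- **Bulk.** Per-sample mixing proportions ~ Dirichlet centred on
  (0.12, 0.44, 0.44) with concentration 200 (microglia fraction
  0.12 ± ~0.023); bulk = proportions × profiles.
- **Technical artifacts.** GC ~ U(0.3, 0.7), length log-uniform on
  [500, 100000] bp; bulk values are multiplied by
  `2^(0.5·(gc − mean gc) + 0.2·(log10 len − mean))`. The bias is applied to
  the bulk dataset only: a bias common to every sample of a matrix cancels
  in the sample-vs-grand-mean ratio, so a dataset-level offset is the form
  the residual normalization can actually see and remove. The default
  magnitudes are moderate (worst-case ~0.25 log2 across the GC/length range)
  — large enough to bias a naive contrast, small enough to be realistic.
- **Noise.** Multiplicative lognormal: × 2^N(0, 0.25) per measurement.
- **Samples.** 540 bulk samples and 10 purified replicates by default,
  matching the study scale the generator emulates; a synthetic "middle-aged"
  comparison dataset (N = 3) plants 50 up- and 50 down-regulated aging genes
  at log2 effect 3.
- **Traits.** Each trait (or latent, for binary/dosage traits) is
  `intercept + slope·program + noise`, where the program is the z-scored
  true microglia proportion. Default slopes encode the emulated biology:
  positive for age at death and amyloid, negative for APOE ε2, zero for
  clinical diagnosis, tau and APOE ε4. Allele counts cut the latent at
  plausible allele-frequency quantiles (ε2 ≈ 8%, ε4 ≈ 14%).
- **Disease sets and proteins.** A disease set shares an exact planted
  number of genes with the microglia markers (20 of 60 by default); the
  synthetic protein table (200 proteins) is detection-biased toward abundant
  transcripts, forces 30 marker genes in, and adds heavy (sd 2.5 log2)
  noise so protein–mRNA correlation is moderate, as in shotgun proteomics.

What it does **not** emulate: count-level statistics (no negative-binomial
mean-variance relation), read-level artifacts, batch structure beyond the
GC/length model, correlated gene–gene co-expression modules, or realistic
trait marginals. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability under a faithful mixture-plus-bias
model — not performance on any particular real cohort.

## Calibration checks and problem sizes

The acceptance checks run at sizes chosen to make the statistics sharp while
keeping the whole suite fast: exhaustive hypergeometric enumeration for all
universes up to N = 12 (1727 instances); 100 random GSEA instances against a
brute-force oracle plus 500 null sets at 99 permutations for type-I
calibration; the full signature path at the default design (2000 genes, 540
bulk samples); 200 + 2000 regression replicates for slope coverage; 1000
null simulations for trait type-I; 2000 genes for moderated-t null
uniformity. One calibration note: the coverage of a ±2·SE interval under a
correctly calibrated OLS is P(|t₅₃₈| ≤ 2) = 95.4%, so a 200-replicate
estimate of it sits within Monte-Carlo noise of 95%; the suite therefore
also checks coverage over 2000 replicates against the nominal value within
its 99% binomial confidence interval, which is the statistically meaningful
assertion.

## Known limitations

- The voom-style weighting is a simplified trend; exact limma-voom
  reproduction is a non-goal (the moderated t itself does match limma).
- Gene matching across datasets is by identifier; duplicate symbols are
  dropped rather than resolved.
- The ORA universe choice materially changes p-values; the package forces
  the caller to state it but cannot validate that it is scientifically
  appropriate.
- Quantile alignment before cross-dataset testing removes genuine global
  shifts along with protocol effects; it is the default because protocol
  confounding is total (dataset = protocol), but it is a choice, not a fact.
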