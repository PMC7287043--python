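# Methods

This note records the models, the numerical choices, and the design
decisions behind `receptormine`, including what the synthetic data can
and cannot certify about behavior on real arrays.

## Data model and ingestion

The unit of data is a single-channel microarray: one hybridized
biological sample whose probe fluorescence intensities are digitized
into a probe × 1 vector. Experiments pool such arrays from several
deposited series (studies) into biological categories. Only one
platform may be pooled at a time — cross-platform probe matching is out
of scope and mixing platforms is a hard error. Two-channel
(competitive) arrays are rejected at parse time.

Missing intensities: a sample with more than 1% of probes missing is
rejected; below that, entries are imputed by the probe's median across
the remaining samples (logged). Rationale: the downstream quantile
normalization and median polish require complete matrices, and a >1%
missing rate on a single-channel array indicates a corrupted record
rather than sporadic nulls.

Gene symbols are compared case-insensitively but stored as given, since
mouse (`Acvr2a`) and human (`ACVR2A`) conventions differ and the tool is
species-agnostic.

**Confound check.** For every category whose samples all share one
series id, a warning names the category and series. This is a design
diagnostic, not a correction: when category and series coincide, no
normalization can separate biology from batch.

## Normalization (RMA chain)

Per array, observed intensity is modelled as S = X + Y, signal
X ~ Exponential(mean α) and background Y ~ Normal(μ, σ²). The
correction replaces S with

    E[X | S=s] = m + σ φ(m/σ)/Φ(m/σ),   m = s − μ − σ²/α,

which is strictly positive and strictly increasing in s. For
m/σ < −30 the asymptotic form σ(1/|t| − 2/|t|³) avoids catastrophic
cancellation; elsewhere the Mills ratio is evaluated in log space.

**Parameter estimation** is per array, by maximum likelihood on the
closed-form convolution density (Nelder–Mead on (μ, log σ, log α)),
started from a mode-based scheme: kernel-density mode for μ, RMS of
sub-mode deviations for σ, mean excess of supra-mode points for α. The
mode-based start is not used as the final estimate because it is badly
biased precisely in the common regime α ≫ σ: the density mode of the
convolution sits at μ + σ²/α + t*σ where t* solves φ(t*)/Φ(t*) = σ/α,
roughly two background standard deviations above μ. The likelihood
refinement removes this bias; simulation recovery is a few percent at
50 000 probes (tested at a 15% tolerance).

**Quantile normalization** maps every column onto the across-column
mean of order statistics. Ties receive the mean of the reference values
at their tied ranks, so tied entries stay tied. Two caveats are worth
recording because they shaped the tests: (i) the tie policy makes the
transform exactly idempotent only on tie-free input; (ii) quantile
normalization flattens genes that dominate the extreme tail of a single
group's intensity distribution — a known fold-change-compression
pathology of the method, visible in the simulations as planted 2.0
log2-fold changes recovered at ≈1.8.

**Median polish** (per probeset, on log2 data): alternating row- and
column-median sweeps, row sweep first, accumulating overall + column
effects; expression per sample = overall + column effect. Stopping rule:
sum of absolute residual change < tol (default 0.01) or max_iter
(default 10) — classic defaults. On exactly additive matrices the
decomposition is exact. On random matrices with even-length axes the
polish can cycle at a small nonzero level because even-length medians
are midpoint averages; residual row/column medians are guaranteed to
vanish only for odd-length axes, and the tests state the invariant that
way.

**Gene collapse** averages a gene's probesets (strategies `median` and
`max` — the probeset with the highest average expression — are
selectable). Averaging was chosen over selection because the screen
reports per-gene distributions pooled across probes, and the mean is
the aggregation consistent with that reading. Unannotated probesets
are dropped at this step with a logged count.

## Differential expression

Groups are the user categories; the per-row model is the group-means
parameterization fitted by OLS (per-category means; pooled residual
variance s²_g with d_g = n − K). Contrasts are exactly all unordered
category pairs; contrast (a, b) is mean(a) − mean(b).

**Moderation.** With z_g = log s²_g, e_g = z_g − ψ(d_g/2) + log(d_g/2)
estimates log s²₀ up to prior spread; solving
ψ′(d₀/2) = Var(e) − ψ′(d_g/2) (Newton on the trigamma inverse) gives the
prior df, and s²₀ = exp(ē + ψ(d₀/2) − log(d₀/2)). If the spread of e is
no larger than its sampling noise the rows are consistent with one
common variance: d₀ is capped at 10⁶ and s²₀ is taken as the plain mean
of the s²_g (the log-scale back-transform is the wrong estimate for a
point-mass prior). Posterior variances are the convex combination
s̃²_g = (d₀s²₀ + d_g s²_g)/(d₀ + d_g). Rows with s²_g = 0 are floored at
the 1st percentile of the positive variances before moderation and
flagged in the output.

**Threshold test.** Significance is assessed against a log2 fold-change
threshold τ (default 1.0): p = P(T ≥ (|β̂|−τ)/u) + P(T ≥ (|β̂|+τ)/u)
with df = d₀ + d_g. At τ = 0 this is the ordinary two-sided moderated
t; with moderation weight removed (d₀ = 0) it reduces to the classical
pooled-variance two-sample t-test, which the tests verify to 1e−10. The
default τ = 1 is deliberately permissive for an exploratory screen whose
hits are expected to be validated externally.

**Multiple testing** is Benjamini–Hochberg within each contrast
(`bonferroni` and `holm` are config options); flags are adjusted
p < 0.05 by default. BH within contrast, rather than pooled across
contrasts, keeps each pairwise comparison's FDR interpretable on its
own, which is how the per-contrast report columns are read.

**Testing level.** Testing defaults to the gene-level matrix (collapse
first, then test). Testing each probeset separately and flagging a gene
when any of its probesets passes was evaluated and rejected as the
default: each probeset is a noisier summary than the gene mean of 3–4
probesets, and the probeset-level BH burden is ~3× larger, which
measurably costs power. Probeset-level testing remains available
(`deg: {level: probeset}`), in which case a gene's reported adjusted p
is the best across its probesets and the flag rule (`any`/`all`) is
configurable.

## Sparse PLS-DA

X is samples × genes, centered and unit-scaled per gene; Y is the
centered/scaled one-hot category matrix. Per component, M = XᵀY is
initialized at its dominant singular pair and iterated
a ← normalize(soft-threshold(Mb)), b ← normalize(Mᵀa); the threshold is
the (keepX+1)-th largest |Mb|, with boundary ties broken by gene order
(earlier gene wins a slot), so exactly keepX genes survive,
reproducibly. Convergence: max loading change < 1e−6 or 500 iterations
(non-convergence warns and returns the partial fit). X and Y are
deflated by regression on the component score; loading signs are fixed
so the largest-magnitude entry is positive. Defaults: ncomp = K − 1,
keepX = min(50, p/10). With keepX = p the first component equals the
dominant singular vector of XᵀY (tested to 1e−8). The model is used for
gene selection and score plots only; class-prediction rules are
deliberately absent. sPLS-DA selections are reported in parallel with
the pairwise tests (a column in the report), not as a gate on them.

## Receptor screen

The report joins, per receptor-annotated gene present in the matrix:
per-category mean log2 expression, overall rank by the target-category
mean (ties broken by symbol), rank within each of the gene's receptor
classes, the DEG flag and best adjusted p per contrast, and the sPLS-DA
selection flag. There is no hard "highly expressed" threshold — the
report ranks, and an optional `min_expression` filter is off by
default, because no principled absolute cutoff exists on the normalized
scale. Clustering for heatmaps: samples by Euclidean distance, genes by
1 − Pearson correlation, both with average linkage; zero-variance gene
rows get the maximal distance (2.0) and a warning. Everything
downstream of ingestion is deterministic, so regenerated reports are
byte-identical.

## Synthetic data

The generator draws probe intensity = N(μ, σ²) background +
Exponential(mean α·2^L) signal with
L = θ_gc + batch_{g,series} + affinity_p + ε_gs: true log2 means θ,
gene-specific per-series batch offsets, per-probe affinities, and
per-(gene, sample) biological noise. The exponential draw is
independent per probe and sample; on the log scale it contributes
heavy-tailed measurement noise of ≈1.85 log2 units sd, which the
multi-probe median polish averages down — this is why the default
design gives each gene 3–4 probesets of 16–20 probes (≈50–80 probes per
gene, the precision of a well-covered gene on multi-probeset designs).
Planted differential expression shifts 5% of genes by ±2 log2 units
with balanced signs; one-sided planting was rejected because it skews
one group's global intensity distribution, which quantile normalization
then partially undoes (fold-change compression beyond what balanced
effects suffer). Remaining defaults: two categories of 6 samples drawn
from 2 series each, batch sd 0.1, affinity sd 0.5, noise sd 0.15,
baseline θ ~ N(8, 1), background μ = 50, σ = 10, α = 1. Under these
conditions the full simulate → RMA → collapse → test chain recovers
planted genes at ≈90% recall (FDR ≈ 0) — the regression tests assert
the average over three fixed seeds.

One global seed expands into named per-purpose streams (structure,
baseline, DE placement, batch, affinity, noise, signal, background), so
enlarging one dimension does not reshuffle unrelated draws. The
`spike_receptor` option plants a known-answer receptor gene: +2 log2
baseline (high but inside the bulk distribution, so quantile
normalization does not flatten it) plus the DE effect in the last
category; end-to-end tests assert it ranks first in its category's
report and is flagged.

What the simulations do **not** emulate: real probe sequences and
GC-dependent background, probe-level correlation across arrays beyond
shared affinity, annotation errors, cross-hybridization, and the
platform-specific probeset composition of real chips. Passing the
recovery tests therefore certifies the statistical machinery under the
convolution model the normalization assumes, not performance on any
particular GEO platform.

## Known limitations

- Probe-level matrices are the entry point; CEL parsing and live GEO
  retrieval are out of scope (inputs are local series-matrix/TSV files).
- No covariates, blocking factors, or duplicate-probe correlation in
  the linear model; no user-defined contrast algebra beyond all pairs.
- Quantile normalization's fold-change compression (above) means
  reported log2FCs are mildly conservative for strongly expressed,
  strongly differential genes.
- keepX/ncomp are not tuned by cross-validation; defaults are stated
  and configurable.
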