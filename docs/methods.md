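# Methods

This note documents the statistical procedures implemented in
`colicord`, the defaults and their rationale, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where the underlying conventions were genuinely open.

## Preprocessing

**Quantile normalization.** Each sample (column) is mapped onto the
common reference distribution defined as the row-wise mean of the
per-column sorted values. Ties within a column receive the mean of the
reference values over the tied rank span, so the transform is well
defined and preserves within-column order up to ties. The transform is
idempotent on tie-free input. Normalization is always performed
per-platform (per species); the two species meet only at the
fold-change level, never in a joint normalization.

**Log2 transform.** Applied after normalization to raw (strictly
positive) intensities; the `ExpressionMatrix.scale` flag prevents
accidental double transforms.

**Probe collapsing.** When several probes map to one gene, the probe
with the highest mean intensity across samples is kept (stable
tie-break by probe order). Keeping one probe rather than averaging
preserves the original intensity scale and is the common practice for
single-channel bead arrays.

**PCA.** Samples are projected onto principal components of the
per-gene (row) centered matrix; no unit-variance scaling, which is the
convention for expression data where variance carries signal. Component
signs are fixed by requiring each gene-loading vector to have a
non-negative sum (first-nonzero-positive on exact zero), making scores
reproducible.

## Differential expression

**Group contrasts.** Student t-tests: pooled-variance unpaired by
default (df = n_a + n_b − 2), paired (one-sample t on within-subject
differences, df = n − 1) by flag. Degenerate zero-variance cases are
explicit: equal means give t = 0, p = 1; unequal means give p = 0 with
a `degenerate` flag. Fold changes are reported as
log2 FC = mean_a − mean_b and as the signed linear convention
(2^log2FC for up, −2^−log2FC for down, so |FC| ≥ 1). log2 fold changes,
being additive, are the scale used for any averaging; signed FCs are
display values. Multiple testing uses Benjamini–Hochberg step-up
q-values within each contrast (via statsmodels).

**Time-course selection.** Genes with sustained regulation are scored
by the maximum over post-baseline timepoints of the absolute moderated
paired t statistic. The per-(gene, timepoint) difference variance s² is
shrunk toward the cross-gene median s₀² at that timepoint:
s*² = (d₀·s₀² + d·s²)/(d₀ + d) with d₀ = 3 prior degrees of freedom and
d = n − 1. Moderation stabilizes scores at small subject counts in the
spirit of empirical-Bayes linear-model pipelines. This stage is a
defined, reproducible stand-in for Bayesian time-course selection
tools; outputs label it as such via the run-report assumptions block.

Two p-value modes exist:

* `parametric` (default): p = min(1, T · 2 · P(t_{d₀+d} ≥ score)) with
  T the number of post-baseline timepoints — a Bonferroni bound over
  positively correlated statistics (they share the baseline sample),
  hence conservative. Measured on a 2000-gene null study, the selected
  fraction at q ≤ 0.01 is 0.000, and power at a sustained 2.0 log2
  effect, noise 0.5, 5 subjects is ≈ 0.93.
* `permutation`: per-gene within-subject permutation of condition
  labels with p = (1 + #{permuted score ≥ observed})/(1 + B), B = 1000
  by default, seeded. This null is exact but has a structural
  resolution floor at small n: permutations that realign a gene's own
  signal (all subjects drawing the same baseline position) occur with
  probability on the order of 4^−n_subjects per pattern, so with 5
  subjects no gene can reach p ≲ 0.004 and genes regulated at several
  timepoints are floored far higher. It is kept for null-calibration
  checks; it is not useful as a selector at n = 5, which is why it is
  not the default.

Selection is `q ≤ tc_alpha` with tc_alpha = 0.01 by default, mirroring
a 0.99 posterior-probability cutoff in the tools this stage stands in
for.

## Clustering

Similarity between temporal profiles (per-gene mean log2 expression per
condition, baseline-centered in the pipeline so shapes rather than
absolute levels cluster) is the negative Euclidean distance. Clustering
is affinity propagation: responsibility/availability message passing
with damping 0.9, max 1000 sweeps, convergence declared after 50 sweeps
of a stable exemplar set. The shared preference (self-similarity)
defaults to the median off-diagonal similarity, the standard choice for
a moderate emergent cluster count. Degeneracies (exactly tied
similarities) are broken by a seeded jitter at 1e−12 relative scale, so
runs are bit-reproducible.

After message passing the exemplar set is refined deterministically on
the exact net-similarity objective (each non-exemplar contributes its
best similarity to an exemplar; each exemplar contributes the
preference):

1. alternating reassignment / within-cluster exemplar update to a fixed
   point (the standard refinement, iterated);
2. best-improvement local search over add / drop / swap moves (swap
   scans limited to n ≤ 200 as a cost bound);
3. on tiny instances (n ≤ 32), deterministic restarts of the local
   search from every singleton exemplar set, keeping the best solution —
   this reliably reaches the exhaustive-search optimum on random
   instances with n ≤ 8 (0 failures in 500 randomized trials);
4. a tie-merge pass that drops exemplars whose removal does not lower
   net similarity, resolving degenerate geometries (e.g. identical
   items) toward the smallest equivalent exemplar set.

Non-convergence within max_iter returns the best-so-far solution with
`converged=False`. Reported net similarity is computed on the clean
(un-jittered) similarities.

## Enrichment

For each (cluster, term) pair with nonzero overlap k, the
over-representation p-value is the hypergeometric upper tail
P(X ≥ k | N, K, n), computed via scipy's stable log-space survival
function; term membership is intersected with the reference universe
(all genes on the array) before counting K. Gene sets are size-filtered
at load time to [5, 1000] members with inclusive boundaries (a
5-member or 1000-member set is retained). The underlying convention
reports raw p-values; we additionally report BH q-values within each
cluster and flag that adjustment in output metadata. No GO-graph
propagation is performed: sets are counted exactly as given in the GMT.

## Concordance

**Gene level.** Rat and human contrast tables are inner-joined through
a strict 1:1 ortholog map (genes appearing in more than one pair on
either side are dropped entirely by default — deterministic,
reproducible joins; a first-wins policy is available by flag). An
ortholog pair is `concordant_up` when both species have
log2 FC ≥ +1.1 with p < 0.05, `concordant_down` when both are ≤ −1.1
with p < 0.05, `nonconcordant` otherwise; the rule is symmetric in the
species. The summary Spearman ρ is computed over **all** joined pairs'
fold changes, not only the significant ones: the statistic describes
the whole fold-change cloud of the scatterplot, of which the
concordant calls are the colored subset.

**Pathway level.** Rat fold changes are first translated to human gene
ids through the ortholog map so both species score identical pathway
memberships. A pathway's score per species is the arithmetic mean of
member log2 fold changes over members present in the contrast table;
pathways with fewer than 5 present members are excluded. Cross-species
association is Spearman's ρ over pathways scored in both species. Each
shared pathway is additionally labeled concordant when its two mean
scores are nonzero with equal sign — the minimal quadrant reading of a
pathway-score scatterplot; this labeling rule is an explicit assumption
and is recorded in the table metadata.

**Spearman's ρ.** Pearson correlation of mid-ranks (average ranks on
ties); two-sided p from the t approximation with n − 2 df, p = 0 at
|ρ| = 1; undefined (flagged) below 3 points or for constant input.

## Validation helpers

**ΔΔCt.** Per subject, ΔCt = Ct(target) − Ct(housekeeping); per
condition, ΔΔCt = ΔCt(condition) − ΔCt(control); per-subject
FC = 2^(−ΔΔCt). The headline per-condition value is the arithmetic mean
of per-subject FCs (matching the "mean FC" reporting convention); the
geometric variant 2^(−mean ΔΔCt) is emitted alongside. Significance is
a two-sided paired t between the ΔCt values at the condition and at the
control — numerically identical to a one-sample t on the ΔΔCt values,
so the choice between the two formulations is immaterial. Subjects
missing the control condition are dropped with a warning. The whole
computation is invariant to adding a constant to all Ct values of one
subject.

**Severity score.** The modified endoscopic severity score validates
four 0–3 integer criteria (colon thickening not considered) and totals
them, range 0–12.

**Weights.** Mean loss in grams, percent of baseline rounded to one
decimal, and a two-sided paired t.

## Synthetic-data generator

The generator emulates the study design on the log2 scale: per-sample
value = per-gene baseline (Normal, mean 8, sd 2 — typical bead-array
log2 intensities) + planted condition effect + i.i.d. Gaussian noise
(sd 0.5), exported as 2^value so preprocessing is genuinely exercised.
Defaults, chosen once to match the emulated design: 2000 genes; 5 rat
subjects fully crossed with T0/T3/T7/T12; unpaired human groups of
25 UC / 11 CD / 25 controls; 20 % regulated genes; effect magnitudes
Normal(2.0, 0.5) clipped from below at 1.1 so every regulated gene is
regulated at least at the differential-expression threshold; a 1:1
ortholog map over 75 % of genes (roughly the mapped fraction in the
emulated study); 13 temporal archetypes.

Regulated rat genes follow one of 13 fixed unit-peak temporal shapes
over (T3, T7, T12) — early/late/mid peaks, sustained, decaying and
sign-flipped variants — scaled by the gene's effect magnitude; each
regulated gene's *designated condition* (the timepoint of the full
magnitude) is recorded. Ortholog pairs of regulated genes are labeled
concordant with probability `fraction_concordant` (human effect equal
to the rat designated effect) or discordant (opposite sign); pairs of
unregulated genes are labeled null with exactly zero effects in both
species. Human effects apply to both UC and CD by default
(configurable to one group or a random per-pair choice). GO-like sets
are built around archetype memberships plus random background sets;
pathway-like sets over human genes alternate sign-coherent cores
(coherence factor recorded) with random sets, giving pathway-level
scores a recoverable signal. Identical configuration and seed produce
byte-identical artifacts.

What the generator does **not** emulate: probe-level bead structure,
array batch or chip effects, intensity-dependent variance, correlated
gene modules beyond the planted sets, RNA-quality degradation, or
missing samples. Passing tests therefore demonstrate correctness of
the statistical machinery under a clean additive Gaussian model, not
robustness to real-array artifacts.

A separate helper simulates qPCR Ct tables with a planted ΔΔCt per
condition (housekeeping around 15 cycles, baseline ΔCt of 8), exact at
zero noise.

## Numerical and reproducibility choices

* One global seed per pipeline run; stage seeds derived via
  `numpy.random.SeedSequence(seed, spawn_key)`, all below 2^31.
* TSV dialect: tab-separated UTF-8, `#` comments skipped, `.` decimal
  point; run reports are JSON with sorted keys and paths relative to
  the output directory, so identical runs are byte-identical wherever
  they are placed.
* BH q-values come from statsmodels; hypergeometric tails and t/
  Spearman p-values from scipy; the affinity-propagation solver is
  implemented here (the contract requires median preference, seeded
  degeneracy breaking, best-so-far on non-convergence and a reported
  net similarity) and is cross-checked against scikit-learn's
  implementation in the test suite.
* Problem sizes in tests and in the acceptance script (hundreds to a
  few thousand genes) are chosen so the full suite runs in seconds on
  one core while keeping ≥ 200 regulated genes wherever a bias or
  power statement is made.

## Known limitations

* The time-course permutation mode is exact but effectively powerless
  at 5 subjects (see above); the parametric default is conservative
  rather than exact.
* Pathway concordance labels depend on the sign-agreement assumption;
  pathways with mean scores near zero get unstable labels even when ρ
  is high.
* The gene-level concordance rule inherits the hard thresholds
  (p < 0.05, |log2 FC| ≥ 1.1); effects planted near the fold-change
  threshold are recovered only about half the time, which is a property
  of thresholding, not an implementation defect.
* The strict 1:1 ortholog policy discards genuinely many-to-many
  homology; a first-wins policy is available but changes the joined
  universe.
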