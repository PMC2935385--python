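# Methods

This note describes the models and procedures implemented in `cimpscan`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## The measurement model

An Infinium-style methylation array reports, per CpG locus and sample, a
methylated-channel intensity M and an unmethylated-channel intensity U.
The methylation level is summarized as the β-value

    β = M / (M + U)  ∈ [0, 1],

0 meaning unmethylated and 1 fully methylated. β is undefined (missing)
when M + U = 0; probes with any missing study value are dropped before
downstream stages, keeping the matrices complete. β is invariant to
rescaling both channels, so chip-level intensity differences cancel.

## Control-anchored probe QC

Three filters remove unreliable probes, each evaluated independently on the
full probe set and combined as a union (the exclusion sets may overlap —
reported counts are per set plus the union):

1. **Detection** — detection p > 0.05 in ≥ 25% of study samples. "Study"
   means the non-control cohort; the controls are QC anchors, not cohort
   members. A `detection_over="all"` switch includes them, since published
   descriptions of this filter are usually ambiguous on the point.
2. **Methylated control** — β < 0.5 in the fully-methylated cell-line
   control (mean over controls when several, mirroring the DKO rule).
3. **DKO control** — mean β > 0.2 across the DNMT1/DNMT3B double-knockout
   controls. DKO DNA is approximately unmethylated, so probes that still
   read methylated there are unreliable.

Replicate concordance is the squared Pearson correlation of β between
members of a replicate pair; a constant vector (no dynamic range) makes r
undefined and is reported as NA with a warning. In the pipeline the
concordance is computed on the pre-filter matrix: the DKO replicate is
exactly constant on the QC'd set, because the DKO filter removes precisely
the probes that give that sample dynamic range.

## Cluster discovery

Loci are ranked by sample standard deviation and the top K kept (K = 1,000
for tumor+normal, 500 for tumor-only analyses); ties at the cutoff resolve
to the lexicographically smaller probe id, making selection deterministic.
Samples are agglomerated with Euclidean distance and complete linkage. The
agglomeration is implemented in the package (cohorts are at most a few
hundred samples, so the O(n³) schedule is negligible) with a fully
specified tie-break: among all minimal-distance cluster pairs, the
lexicographically smallest pair of cluster indices merges, indices assigned
in creation order. The emitted linkage matrix follows the scipy convention
and is cut with scipy's tree utilities; tests verify merge heights and all
cut partitions against `scipy.cluster.hierarchy.linkage` on tie-free data.
Complete-linkage heights are non-decreasing along the schedule (the metric
is reducible), which is asserted as a property.

Partition quality is the average silhouette width under Euclidean distance;
samples in singleton clusters contribute 0 (the sklearn convention,
documented here as the package's convention too). The number of groups k is
a user parameter — analyses of this design typically use k = 3 with normals
and k = 2 tumor-only — with `select_k_by_silhouette` as an optional
automatic mode maximizing s̄ over k ∈ {2..6}.

**Permutation significance.** The p-value for cluster separation shuffles
each locus's values across samples independently, destroying sample-level
correlation while preserving per-locus marginals, and re-runs the full
select → cluster → silhouette chain at the same k;
p = (1 + #{s̄_perm ≥ s̄_obs}) / (1 + n_perm). This null is a design choice of
this package (published cluster-separation p-values of this kind rarely
state their null) and is flagged in the result metadata. Under an i.i.d.
null generator the p-value is uniform, which the test suite checks by KS
test over 200 repetitions × 99 permutations.

## Differential methylation

Per locus, a two-sided t-test between two sample groups. Welch (unequal
variance) is the default because the designs of interest are strongly
unbalanced (e.g. 49 vs 13, 62 vs 10); a pooled-variance mode is available
by flag and the result records which was used. A locus passes when both
|Δβ| > 0.17 (Δβ = mean_B − mean_A) and p < 10⁻⁴. The pass rule deliberately
uses raw p — matching the convention of the analyses this package
implements — while BH q-values are reported alongside for transparency.
Degenerate loci with zero variance in both groups get p = 1 at equal means
and p = 0 otherwise (documented convention). Passing probes collapse to
gene symbols, counting a probe once per distinct symbol when it maps to
several ( ';'-separated annotation).

Direction is "gain" (B hypermethylated) when Δβ > 0. The gain/loss ×
island/non-island 2×2 table is tested with Fisher's exact test, two-sided
by the point-probability rule.

## Nearest shrunken centroids

The classifier is implemented from scratch in `nsc.py`:

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s₀)),   m_k = √(1/n_k − 1/n)
    d'_ik = sign(d_ik) · max(|d_ik| − Δ, 0)
    x̄'_ik = x̄_i + m_k (s_i + s₀) d'_ik

with s_i the pooled within-class standard deviation (n − K degrees of
freedom), s₀ = median(s_i) a variance-stabilizing offset, and priors
π_k = n_k/n. Prediction minimizes
δ_k(x) = Σ_i (x_i − x̄'_ik)²/(s_i + s₀)² − 2 log π_k, with posteriors
∝ exp(−δ_k/2). Features "survive" at Δ when any class keeps d'_ik ≠ 0; the
surviving count is non-increasing in Δ (soft-thresholding is monotone),
asserted as a property.

Δ is selected on a 30-point grid from 0 to max|d_ik| by stratified k-fold
cross-validation (folds reduced gracefully when a class is smaller than the
fold count), choosing the **largest** Δ attaining the minimal CV
misclassification count — the sparsest model on the error plateau. Folds
are seeded; a fixed seed reproduces the CV path exactly. With strongly
separable classes the zero-error plateau is wide and the sparsest-model
rule keeps only a *sufficient* subset of informative loci; the planted
16-locus recovery scenario therefore uses a planted contrast of Δβ = 0.2,
the weakest contrast that still yields a zero-error classifier — the regime
in which a small fixed-size locus panel with near-perfect accuracy is the
natural description of the data.

## Gene-set enrichment

Upper-tail hypergeometric test per set: p = P(X ≥ k) with
X ~ Hypergeom(N, K, n), where the universe (N) is all distinct symbols on
the post-QC array — the analysis can only observe array genes, so a
whole-genome universe would overstate enrichment. Sets are intersected with
the universe before counting; symbols are uppercased and deduplicated
(GMT files vary in case); hits outside the universe are dropped with a
warning and counted. BH q-values are reported across sets.

## Expression integration

Pearson r between β and log2 expression per mapped (CpG probe, expression
probe) pair over shared samples, two-sided p, BH q across all pairs;
a pair is called negative/positive by the sign of r when q < FDR (default
0.01). FDR is controlled directly rather than through a fixed p cutoff.
A gene is "significant" when any of its pairs is — the simplest roll-up
that reproduces gene-level counting without inventing a combination
statistic. Constant vectors give NA pairs, excluded from BH.

DNMT contrasts are Welch t-tests of designated expression rows between the
low and high methylation groups, raw and normalized by PCNA as a log2
difference (a ratio in linear space — the standard choice for
log2-transformed data, since "normalization" by a proliferation marker is
otherwise underdefined). Equal planted shifts on gene and normalizer cancel
in the normalized contrast, which is the diagnostic pattern separating a
methyltransferase signal from proliferation.

## Contingency statistics

Pearson chi-square without continuity correction is the default: on the
package's reference clinicopathological tables (hormone receptors, HER2,
grade) it reproduces the printed p-values exactly. Yates correction is
available for 2×2 tables and every result names the test used. Fisher's
exact test is two-sided by the point-probability rule (sum of all
fixed-margin tables no more probable than the observed one). The common
claim that chi-square and Fisher p agree within 0.05 when expected counts
are ≥ 5 holds on average but **not** pointwise — individual tables disagree
by up to ~0.2 even at large expected counts, due to the exact test's
discreteness — so the test suite asserts the average-agreement version.

## The synthetic-data generator

`generate_dataset` emulates the data structure of a two-channel ~27K
methylation array study of breast tissue. Defaults are the emulated study
conditions: 10 normals, 49 low- and 13 high-methylation tumors, one
methylated and two DKO controls, three replicate pairs, 27,578 probes with
80% inside CpG islands, and (island, non-island) group means
(0.15, 0.65) / (0.33, 0.58) / (0.54, 0.44) — giving overall group means
0.25 / 0.38 / 0.52 and the island inversion. Components:

- **True β**: Beta(mc, (1−m)c) per probe × sample with concentration
  c = 50 (s.d. ≈ 0.06 at m = 0.3). A single global concentration cannot
  simultaneously give tumors realistic spread and normals the very tight
  per-locus s.d. (~0.02) such studies report; the tumor-realistic choice
  was made since every inferential stage operates on tumors. Means of
  exactly 0/1 are kept degenerate so noise-free limits are exact.
- **Intensities**: M = scale·β·ε, U = scale·(1−β)·ε′ with independent
  unit-mean log-normal factors, σ = 0.035 — calibrated so replicate-pair
  r² averages ≈ 0.97, the chip-to-chip reliability such arrays exhibit.
- **Detection p**: near 0, with Bernoulli failures drawn on (0.05, 1]; a
  small planted probe subset fails in ~half the samples (detection-filter
  targets). Planted fractions of probes misbehave in the controls
  (β ≈ 0.2 in the methylated control, β ≈ 0.6 in DKO) at rates matching a
  27K study's exclusion ledger (68 / 28 / 4,067 of 27,578).
- **Replicates** share true β with their origin sample (two tumors and one
  DKO, round-robin) and differ only in intensity noise.
- **Subtypes**: IBC labels are Bernoulli per group (0.54 high / 0.24 low);
  four planted loci carry an IBC effect of Δβ = 0.2, so the IBC-vs-non-IBC
  comparison recovers a handful of loci rather than a global signature.
  Clinicopathological features are categorical draws, some enriched in the
  high group (metastasis, prognosis, genomic grade), some identically
  distributed (ER, PR, HER2).
- **Focal planting**: `n_diff_loci`/`diff_delta` shift the high group's
  mean at chosen loci relative to the low group's, for differential and
  classifier recovery scenarios with known truth.
- **Expression** (`generate_expression`): one expression probe per gene,
  paired with a representative CpG probe; 45% of genes inversely coupled
  (log2 expr = 8 − 3β + N(0, 0.5)), 12% positively, the rest independent
  noise. Slope and noise were set so coupled pairs land at |r| ≈ 0.5–0.8,
  inside the correlation range such integrations report, and are
  detectable at FDR 0.01. Designated DNMT3B/DNMT1/DNMT3A/PCNA rows carry
  configurable high-group shifts (defaults +0.76/+0.4/0/+0.5 log2).

One integer seed drives a single numpy Generator; identical configuration
and seed give bit-identical output, and the pipeline's stage outputs are
byte-identical across runs at the same seed.

### What the generator does *not* emulate

- **Per-locus heterogeneity.** All loci of a (group, context) stratum share
  one mean, so every island locus carries the planted tumor contrast: the
  tumor-vs-normal comparison flags most of the island stratum rather than a
  ~6% subset, variance-ranked selection returns essentially only island
  probes, and cohort-level loss-of-methylation loci (non-island contrast
  > 0.17) do not arise under the defaults — the loss direction and its
  island-context enrichment are exercised in the high-vs-low comparison
  and on constructed fixtures instead. Passing recovery tests therefore
  demonstrates that the stages recover *planted* structure, not that real
  arrays would yield these pass counts.
- No dye bias, batch effects, copy-number confounding, or bead-level
  simulation; detection p-values are an abstract quality mask, not the
  vendor statistic.
- Probe–gene mapping is one pair per gene; real integrations map several
  CpG loci and probe sets per gene, which decouples pair-level and
  gene-level significance fractions.

## Problem sizes in tests and the acceptance script

Tests and the acceptance script run the generator at reduced probe counts
(500–3,000 probes; full cohort sizes) — the statistical structure is
per-probe i.i.d. within strata, so recovery behavior is unchanged while
runs stay fast. The silhouette-calibration check uses 200 repetitions × 99
permutations on 30-locus, 16-sample null data; classifier recovery is
averaged over three replicate cohorts in the acceptance script because a
single 16-locus cohort quantizes recall in 6.25-point steps.

## Known limitations

- The permutation null for silhouette significance is per-locus
  exchangeable; it does not preserve locus–locus correlation, so its p is
  anti-conservative when loci are strongly co-methylated under the null of
  no sample structure.
- NSC posteriors are softmax transforms of discriminants, not calibrated
  probabilities.
- Gene collapsing and the any-pair gene significance rule are counting
  conventions, not inference; region-level differential methylation and
  covariate adjustment are out of scope.
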