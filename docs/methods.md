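# Methods

This note documents the statistical procedures `metabosig` implements,
the choices made where several readings were defensible, and what the
synthetic-data validation does and does not establish.

## Preprocessing

Raw peak areas are positive intensities with missing cells interpreted
as below-detection dropouts (missing-not-at-random, left-censored).
Three steps, in order:

1. **Batch median scaling.** For each metabolite, the values of each
   instrument batch are divided by that batch's median of observed
   values, so every (metabolite, batch) block — and hence the
   metabolite — has median 1. This removes any batch-level
   multiplicative factor exactly (a property test confirms bit-level
   agreement, tolerance 1e-10, between scaled data generated with and
   without batch effects when there is no dropout). The median of an
   even number of values is the midpoint of the two central ones.
   A metabolite entirely missing in one batch keeps its NaNs there; a
   metabolite with no observed value anywhere is dropped with a logged
   warning, as are metabolites observed in fewer than 2 samples overall
   (no variance estimate is possible).
2. **Minimum imputation.** Each missing cell is set to its metabolite's
   minimum observed scaled value across all batches, the appropriate
   choice for left-censored dropout. An imputed-cell mask is kept so
   downstream consumers can distinguish observed from filled values.
3. **Log transform.** Natural log of the complete matrix. The base is a
   convention only: two-group test p-values are invariant to it, and
   fold changes are computed on the pre-log scale, so no reported
   number depends on the base. Non-positive cells (impossible after
   validation + imputation) abort with the offending cell named.

A caution that follows from the arithmetic: dividing by a median
*estimated from the batch's own samples* perturbs the downstream test
statistic's null distribution when batches contain only a handful of
samples. Real instrument batches contain dozens of samples, so the
per-batch median is effectively a constant; the calibration test below
therefore uses the single-batch configuration, and multi-batch scaling
is validated by its exact-removal property instead.

## Differential metabolites

Each metabolite is tested on logged data with a two-group fixed-effect
linear model, numerically identical to the pooled-variance two-sided
t-test (a regression test asserts equality with the group-coefficient
p-value of an OLS fit). The design has one observation per animal per
tissue, so there is no random-effect structure to model. Degenerate
rows (zero pooled variance) get p = 1 when the group means are equal
and p = 0 otherwise.

Fold change is the ratio of group arithmetic means on the scaled,
imputed, pre-log scale — the quantification platform's convention —
rather than the anti-log of the mean log difference; absolute fold
change is max(FC, 1/FC), symmetric in direction. A metabolite is a
**differential metabolite (DM)** when p < 0.05 (strict) and absolute
fold change ≥ 1.5 (inclusive). No multiple-testing correction enters
the call, mirroring the original analysis convention; a
Benjamini–Hochberg q-value column is emitted for information only.
An exact FC of 1 is labelled "up" by tie-break but can never be a DM.

Sensitivity to the variance estimator is regression-tested: switching
the pooled test to Welch flips DM status for under 2% of metabolites on
default simulations.

Overview products: PCA of samples (full SVD; component signs fixed so
each component's largest-magnitude loading is positive; explained
variances must be non-increasing and sum to the total variance),
average-linkage hierarchical clustering on Euclidean distances of
per-metabolite z-scored logged values (ids sorted before linkage so
leaf order is deterministic), volcano data (log2 FC vs −log10 p) and
exact 3-way Venn region counts keyed by metabolite id.

## Pathway statistics

Let a tissue's *background* be its detected **named** metabolites
(unnamed "X-#####" compounds remain DMs for volcano/Venn purposes but
are excluded from pathway margins, including the DM total n, for
consistency with the named background N).

- **Direction zscore.** For a pathway with `up` increased and `down`
  decreased DMs, zscore = (up − down)/√(up + down) — the binomial
  sign-test form. This is the package default; the plain-count
  denominator (up − down)/(up + down), which bounds the statistic in
  [−1, 1], is available via `denominator="count"` for auditability.
  Values are rounded to 2 decimals only at reporting time; tests
  compare pre-rounding with tolerance 5e-3.
- **Enrichment Value.** EV = (k/m) / ((n − k)/(N − m)) with k ≤ m ≤ N
  and k ≤ n ≤ N enforced. EV = 1 exactly when the in-pathway and
  out-of-pathway DM proportions match; n = k (every DM in the pathway)
  returns +inf as a flagged sentinel. A property test checks the
  directional agreement with hypergeometric tails: EV > 1 iff the
  enrichment tail probability is smaller than the depletion tail,
  whenever k is at least one unit away from its null expectation
  m·n/N (exactly at the expectation the two discrete tails can
  straddle either way — verified by exhaustive scan of small tables).
- **Signature call.** A sub-pathway is a signature when |zscore| ≥ 2.5,
  EV ≥ 1.5 and k ≥ 5. Pathways failing the k cutoff are still listed
  (with is_signature = False) so small but interesting sets such as
  TCA-cycle members remain reportable.

## MSEA

Metabolite set enrichment uses the GSEA-style weighted
Kolmogorov–Smirnov running sum. Metabolites are ranked by
sign(log FC)·(−log10 p) (ties broken by id for determinism; p clipped
at 1e-300). Walking down the ranked list, set hits add
|stat|/Σ|stat over the set| and misses subtract 1/(N_bg − n_set); the
enrichment score ES is the maximum-magnitude excursion. The null is
set-label permutation: random same-size sets, 1000 permutations by
default (minimum 100), seeded. NES = ES / mean(|permuted ES| of the
same sign); p is the add-one-corrected one-sided tail among same-sign
permutations, so p ∈ (0, 1] and is never exactly 0. Sets with fewer
than 2 detected members are skipped with a warning; a set equal to the
whole background has no contrast and is flagged degenerate (ES = 0,
p = 1). The permutation p is mildly conservative by construction
(add-one correction and sign conditioning); the null-uniformity test
bounds the false-positive fraction rather than asserting exact
uniformity. The ranking statistic is an assumption: the original web
tools do not publish theirs, and signed −log10 p is the conventional
choice for two-group designs.

Cross-tissue comparison keeps the union of pathways with ≥ 5 DMs in
any tissue; a pathway absent from a tissue's detected panel is marked
*not detected*, distinct from detected-but-not-significant.

## Interaction networks

DM ids are projected onto a user-supplied chemical–chemical edge list
(STITCH convention: integer confidence 0–1000). "High confidence"
means score ≥ 700 (the database's documented tier), configurable.
Duplicate pairs keep the maximum score; self-loops are discarded;
DMs without a surviving edge are reported as isolated rather than
kept as degree-0 nodes. Betweenness is computed exactly on the
unweighted graph (scores are used only for filtering) with the
standard (n−1)(n−2)/2 normalization, and verified against a
brute-force shortest-path-counting oracle on random graphs of ≤ 15
nodes across 100 seeds. Hubs are the top-4 nodes by betweenness, ties
broken by degree (descending) then id (ascending); the composite
"betweenness/association" of the source tooling is not further
specified, so betweenness-with-degree-tie-break is the documented
reading. Disconnected components are ranked jointly.

## Synthetic-data generator

`simulate_study` draws, per metabolite i and sample j,

    peak_area[i, j] = exp( base_i + effect_i·[group_j = D5] + batch_{b(j)} + ε_ij )

with base_i ~ N(base_log_mean = 15, base_log_sd = 1.5) (natural-log
scale; typical platform intensities), metabolite-shared batch factors
batch_b ~ N(0, batch_effect_sd = 0.5) — exactly the structure per-batch
median scaling removes — and residual ε ~ N(0, noise_sd = 0.25).
Planted sets assign effect_i = ±log(fold) to named members of a
designated sub-pathway; defaults plant a 15-member all-up and an
11-member all-down set at fold 3 with 5 samples per group, the scale
of effect the pipeline is designed to detect. Values below each
metabolite's dropout_quantile (default 0.1) detection limit go missing,
making dropout left-censored and group-dependent for down-regulated
metabolites. Batches default to 1 (ten samples fit one instrument
run; see the preprocessing caution above); multi-batch configs assign
samples round-robin within each group, keeping batches group-balanced.
Annotations place 15% of compounds as unnamed "X-#####" entries and
distribute named nulls across a catalogue of sub-pathways under the
platform's nine super-pathway categories.

`simulate_multi_tissue` builds a shared detection core of
round(tissue_overlap_fraction · smallest panel) metabolites plus
tissue-private remainders; default panels are 817/786/941 with overlap
fraction 0.865, giving a 680-metabolite three-way core. Planted
members live in the core so every tissue carries them. Each tissue's
matrix comes from an RNG stream derived from (seed, tissue) via a
stable checksum, so adding or removing a tissue never perturbs another
tissue's draw. `simulate_edge_list` overlays designated high-degree
hubs (high-confidence edges to 60% of nodes) on a sparse
Erdős–Rényi-like background (mean degree 2).

**What passing tests show — and do not.** The generator matches the
pipeline's own modelling assumptions (log-normal intensities, shared
multiplicative batch effects, left-censored dropout), so recovery
results demonstrate internal correctness: calibrated p-values on null
data, ≥ 85% sensitivity at fold 3 with n = 5/group, planted pathways
called signatures, planted NES signs recovered. They do not establish
performance on real data, where heavy-tailed intensities, correlated
metabolites, batch-by-metabolite interactions, and chemistry-driven
missingness all violate the generator's independence assumptions. The
generator makes no attempt to simulate chromatography, adducts,
isotopes or real metabolite chemistry. Construction also makes the
pairwise-only Venn regions of multi-tissue panels empty (core +
private, no two-tissue-only block); only the three-way core count is
a designed quantity.

## Replicate sizes used in validation

The statistical suites run 200 replicates at compact problem sizes
chosen to estimate rates precisely while staying quick: null
calibration pools 200 × 100 no-effect metabolites (single batch, no
dropout) and checks the p < 0.05 rate against a 99.9% binomial band;
recovery runs 200 replicates of 200-metabolite studies with the
default planted sets; MSEA direction-sign agreement uses 100
replicates at 150 metabolites with 100 permutations. The betweenness
oracle covers 100 random graphs of 4–15 nodes.

## Numerical conventions

- TSV floats are written with 12 significant digits ("%.12g"); round
  trips are tested at rtol 1e-11. Missing cells read as "" or "NA",
  written as "NA".
- Pipeline runs are byte-identical under re-runs with the same config
  (no timestamps in outputs; stage timings go to the log only).
- All randomness flows through numpy Generators seeded from explicit
  integers; derived streams use stable CRC32 label hashing, never
  Python's salted `hash`.
- Degenerate inputs are errors, not silent coercions: mismatched ids,
  unknown group labels, non-positive peak areas, super-pathways
  outside the nine-category vocabulary, exclusions that leave a group
  below 2 samples, malformed edge rows (reported with line numbers).

## Known limitations

- Raw p-values drive DM calling by design; at 900 tested metabolites
  the null expectation is ~45 chance calls, which the FDR column
  quantifies but does not remove.
- Minimum imputation compresses within-group variance for heavily
  censored metabolites and can bias their tests in either direction;
  the calibration suite therefore isolates the censoring-free case.
- EV's named-only background is a convention; whether the DM total n
  should also exclude unnamed compounds is not externally specified,
  and the named-only reading is used for consistency with N.
- The MSEA permutation null permutes set labels, not samples, so it
  conditions on the observed ranking; with few samples a
  sample-permutation null is not informative (≤ 252 distinct
  relabellings at n = 5/group).
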