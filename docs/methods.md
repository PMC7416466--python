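# Methods

This note records the models, parameter choices, and numerical conventions
behind `enrichtraj`, and what the synthetic-data experiments do and do not
demonstrate.

## Study design emulated by the generator

The generator reproduces the shape of a stress time-course transcriptome
study of brain endothelial cells: five conditions — home-cage control (HC)
and an ordered treatment series (CSD1, CSD7, CSD14, CSDrec) — with default
per-condition sample counts HC 9, CSD1 5, CSD7 5, CSD14 8, CSDrec 9, and
on the order of 10⁴ gene-level log2 intensities per sample.

Baseline log2 expression is drawn once per gene from Normal(6, 1.5),
matching the scale of RMA-summarized microarray data; per-sample noise is
Normal(0, 0.3) on the log2 scale by default. Neither the baseline spread
nor the residual SD can be estimated from published summaries alone, so
both are exposed in `SyntheticConfig` and chosen once at values typical
for array data of this kind.

**Planted programs.** Each program is a block of `genes_per_program`
(default 20) genes shifted by `effect_log2` (default +1.0) in its active
condition(s), annotated to a clique of `terms_per_program` (default 3)
ontology terms; programs use disjoint gene blocks and are assigned
round-robin to the treatment conditions. Each term carries ~90% of its
program's genes (every gene is guaranteed at least one term), so
within-program term pairs have high kappa while cross-program pairs share
no genes. A configurable fraction of genes (default 2%) is shifted *down*
in all treatment conditions without any term linkage, mirroring the
empirical pattern that downregulated transcripts yield no enriched
processes.

**Ontology.** A random rooted DAG whose term level is the shortest-path
(BFS) distance from the root; a root-anchored chain guarantees that the
level range [0, max_depth] is realized. Program terms are drawn from the
level band that the enrichment stage tests (default 3–9). "Level" by
shortest path is a deterministic, testable choice; annotation tools do not
agree on a single definition.

**Behavior.** Per-animal social-interaction times and light:dark crossing
counts are normal draws (times clipped at zero; crossings rounded and
clipped) with group means that put control SI quotients near 2 and
stressed near 0.5. Count data are modeled as rounded normals rather than
Poisson because the interface is parameterized by means/SDs.

**Images.** Two-channel images are painted from known masks: exactly
`round(frac · n_pixels)` pixels per channel, background Normal(10, 1),
foreground at 100 ± 1. A configurable fraction of the stain mask (default
all of it) lies inside the vessel mask. Because foreground and background
are well separated, the median + 2 SD rule recovers the truth masks
exactly for foreground fractions well below one half — which is the
regime the quantification targets.

**Determinism.** Every stage draws from `default_rng([seed,
crc32(stage_name)])`, so adding or removing a stage never perturbs the
draws of another, and a bundle is bitwise reproducible from its seed.

What passing these synthetic tests does *not* show: robustness to probe-
level artifacts, batch effects, correlated gene-gene noise, annotation
incompleteness, imaging backgrounds with structured autofluorescence, or
cell-type contamination. The generator's genes are independent given the
planted structure; real arrays are not.

## Differential expression

One-way ANOVA per gene across all conditions (vectorized `f_oneway`),
Benjamini–Hochberg q over genes. Degenerate rows: all samples identical →
F = 0, p = q = 1; zero within-group variance with unequal means → p = 0
with a `zero_within_var` flag rather than an exception. Per-condition
contrasts vs control use Welch's t by default (`welch_t=False` restores
the pooled Student statistic); fold changes are differences of group means
on the log2 scale, thresholded on the linear scale (2^Δ ≥ 1.3 means
"1.3×"). DE membership requires both the ANOVA q gate and the fold
threshold; `require_fdr=False` gives fold-only lists for analyses where
the gating convention is unknown. BH (not BY) is used throughout.

Heatmap ordering z-scores each gene row (zero-variance rows become zeros,
flagged) and clusters genes and samples with Euclidean distance and
average linkage.

## Enrichment

Tail probabilities are computed as exact integer binomial-coefficient sums
over the hypergeometric support; the only floating-point rounding is the
final division, so values agree with exhaustive enumeration to ~1e-15 at
any universe size. The two-sided p doubles the smaller tail (capped at 1);
the minimum-likelihood rule is available via `two_sided="minlike"`. The
default universe is the set of expression-table genes carrying at least
one annotation (`expression_universe`); the Bonferroni factor is the
number of terms actually tested for the list at hand (level band 3–9,
≥ 3 annotated universe genes — the minimum-size default is a package
choice). Significance at 0.05 is applied downstream as a display/network
filter, not inside the test.

Annotations can be true-path propagated to ancestors
(`AnnotationSet.propagated`) but are used as given by default; both
behaviors are exposed because annotation tools differ.

## Term network and communities

Kappa is computed over the union of all conditions' DE genes — the genes
actually uploaded — with term gene sets restricted to that universe.
Communities are connected components of the κ ≥ 0.5 graph. This is a
deliberate, documented departure from iterative group-merging heuristics
whose parameters are not reproducible; component grouping is deterministic
and refinement-monotone (raising the threshold can only split, never
merge). The leading term minimizes the best Bonferroni p across
conditions; ties break toward the larger restricted gene set, then
lexicographic id. A community's per-condition gene share is the fraction
of its pooled genes present in that condition's list; a condition with
share ≥ 0.5 is recorded as dominant.

## Dominance

The counts are interpreted as: *group* = the condition's DE genes
annotated to the term; *unique* = distinct such genes across conditions;
*total* = the per-condition sum (a gene counts once per condition carrying
it). Under this reading the log-ratio correction equals 1 for
condition-exclusive terms (dominance 100) and falls below 1 as sharing
grows, which is the quantity the trajectory uses as "specificity of a
time point for a term". The expression is base-invariant (a ratio of
logs); natural log is used. Degenerate n_total = 1 is defined as 100.
Dominance lies in [0, 100] for all valid count triples (verified
exhaustively for totals ≤ 30).

The per-cell Fisher exact test uses the 2×2 table of term membership ×
list membership over the same pooled-DE universe as the kappa score; the
two-sided p sums fixed-margin tables with point probability ≤ the observed
one, compared on exact integers so ties are decided exactly. Trajectory
rows default to the leading terms of multi-term communities (automating a
manual curation step); a user-supplied term list overrides.

## GSEA

Weighted running sum with weight exponent 1 by default (exponent 0 gives
the unweighted KS-style statistic; hit increments fall back to equal steps
if all member weights are zero). The reported ES is the profile value of
maximal absolute deviation, earliest position winning ties. The null is
gene-set permutation: same-size uniform draws from the ranked universe,
with null ES evaluated by a closed form over hit entry/exit candidates
(verified against the brute-force profile). p = (1 + #{|null ES| ≥
|ES|})/(1 + n_perm) — two-sided in |ES|, floor 1/(n_perm+1), exact under
an exchangeable metric. NES divides ES by the mean |null ES| of matching
sign; FDR q is the sign-split pooled-null scheme (null fraction at least
as extreme over observed fraction at least as extreme, clipped to [0, 1],
cumulative-minimum so q is monotone non-increasing in |NES| within each
sign). Phenotype permutation and leading-edge reporting are out of scope.

## Histology and association

Thresholds are median + 2·SD with the population (ddof = 0) SD over all
pixels of the slice (per channel, per slice); the difference from the
sample SD is negligible at image scale. Masks take pixels strictly above
the threshold, so a constant channel yields an empty mask. Stain and
vessel masks are not intersected — total areas are divided, as in
whole-slice scans — with an ROI-restricted variant available. On a
pure-noise channel the rule necessarily marks the upper ~2.3% tail; the
quantification is meaningful when a bright foreground dominates the
statistics, which the generator's sweep covers. `count_blobs` is a
connected-component utility on masks and is explicitly not equivalent to
blinded manual microbleed annotation.

Association is ordinary least squares of the behavioral score on the
per-animal stain readout plus Pearson correlation; for simple linear
regression F = t² of the slope and R² = r², which the tests assert.
Animals with undefined SI quotients (zero empty-cylinder time) are
excluded.

## Problem sizes in the test suite

The acceptance-style tests use the scales their guarantees are stated at:
exhaustive enumeration for universes ≤ 25 and dominance totals ≤ 30; null
calibration on one 5000-gene matrix (KS) plus 200 replicate 1000-gene
matrices (realized FDR); trajectory recovery on 20 seeded 2000-gene
bundles with 5 planted programs each; GSEA calibration on 200 null sets
at 1000 permutations; a 12-point vessel/stain fraction sweep at 256×256.
`scripts/acceptance.py` re-runs the same machinery at slightly reduced
replicate counts and reports every quantity it computes.

## Known limitations

- Communities are κ-threshold components, not overlap-merged groups; very
  dense term graphs can chain distinct processes into one component.
- The dominance count interpretation, the Fisher contingency design, and
  the GSEA q scheme are documented package choices where the field's tools
  leave the convention unspecified.
- No moderated-variance (empirical Bayes) testing; with 2–3 samples per
  group the plain ANOVA screen is underpowered relative to limma-style
  approaches.
- Gene identifiers are matched exactly and case-sensitively; no symbol
  aliasing.
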