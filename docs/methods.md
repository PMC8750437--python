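# Methods

## Data model and normalization

The package operates on genes × samples matrices of log2-ratios (sample
hybridization intensity relative to a common reference pool; 0 means no
change).  Raw two-color deposits are often log10-ratios; `log10_to_log2`
multiplies by log2(10) ≈ 3.3219.  Quantile normalization forces every
sample onto the cross-sample mean of sorted value vectors; ties within a
sample receive the mean of the quantile values they span (the common
"ties = mean" dialect — deterministic, and matching the dominant
implementation convention).  Exact idempotence of quantile normalization
holds on tie-free data; tied groups are collapsed to their quantile mean,
after which a second pass can shift values slightly (a property of the tie
convention itself, not of this implementation).

Missing-value policy (readers): genes with more than 50% missing cells are
dropped (and logged); remaining missing cells are imputed with the gene's
median across samples.  This keeps downstream linear algebra dense and
deterministic.  TSV output uses 6 significant digits, which exceeds
microarray measurement precision.

## Moderated differential expression

One joint one-way group-means model is fitted over all included phases (and
the resistant group when requested), so every pairwise contrast shares the
pooled per-gene residual variance s_g² with d_g = n − k degrees of freedom.
The variances get an empirical-Bayes scaled-inverse-χ² prior (d0, s0²),
fitted by moment matching on e_g = log s_g²: if s² ~ s0²·F(d_g, d0) then
E[e] and Var[e] are digamma/trigamma expressions in (d_g, d0), and the
trigamma equation is inverted by Newton iteration.  When the empirical
variance of e does not exceed the pure sampling variance trigamma(d_g/2),
the prior is degenerate (d0 = ∞, full shrinkage).  The moderated statistic

t_g = (mean_a − mean_b) / (s̃_g √(1/n_a + 1/n_b)),
s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g),

is referred to a t distribution with d0 + d_g df.  Setting d0 = 0 recovers
the ordinary pooled two-sample t-test exactly (the oracle used in tests).
Zero-variance degenerate genes follow the convention p = 0 if the fold
change is nonzero, else p = 1.

Storey q-values: π̂0(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05…0.95; a
cubic polynomial fit of π̂0(λ) is evaluated at λ = 0.95 and clipped to
(0, 1] (a deterministic stand-in for the natural-spline smoother that agrees
closely with it on these 19 grid points); for m < 100 the smoother is
unstable and the conservative max over the grid is used instead.  With
π̂0 = 1 the q-values coincide exactly with Benjamini–Hochberg.  Calls:
`under`/`over` at q ≤ 0.05, optionally requiring |log2FC| ≥ 1; the
signature is the union of calls over the three phase contrasts (no
magnitude filter — the network stage wants every differential gene).

The accelerated-subtype check runs the same machinery on blast-count vs
cytogenetic AP samples and recommends merging when fewer than 10 genes are
called — mirroring the design decision taken for the real cohort, where
only two genes separated the subtypes.

## Enrichment

One-sided (greater) Fisher exact tests per category and direction —
enrichment, not depletion, is the question asked of these catalogs.  The
universe is the full analyzed matrix, not the signature.  The FDR family is
all categories × both directions within one contrast (the family scope is a
documented choice; adjusted p-values are additionally floored at the raw p
to keep p_adj ≥ p under this family definition).  Stars: `**` at
p_adj ≤ 0.01, `*` at ≤ 0.05.  Pathway alteration profiles report the
percentage of each category's genes called under/over.

## Clustering and PCA

PCA centers genes and does not rescale them (the convention of the standard
R implementation with default arguments); component signs are fixed by
making each component's largest-magnitude loading positive.  Clustering
uses 1 − r (Pearson) dissimilarity with Ward's ward.D2 linkage; scipy's
`linkage(method="ward")` on the condensed dissimilarity matrix applies
exactly the ward.D2 Lance–Williams recurrence (verified against a naive
O(n³) implementation in the tests).  Both heatmap axes use the same
distance/linkage (only the sample axis is dictated by the analysis design;
the gene axis mirrors it).  The resistant-vs-phase analysis reports the full
resistant × phase-sample Pearson correlation matrix and per-resistant-sample
phase means.

## Network inference

Per target gene: predictors are all other signature genes, z-scored with
training-sample statistics; the response is centered.  The LARS-lasso path
is computed with a cap of 15 steps per gene (`max_steps`; bounds runtime
without affecting the top-of-path entries that dominate link selection).
Each first entry event is scored with the covariance test
T = (⟨y, Xβ̂(λ_next)⟩ − ⟨y, X_A β̃_A(λ_next)⟩)/σ², p = exp(−T).  The
restricted lasso solution β̃_A is obtained by coordinate descent on the Gram
matrix (numba-compiled; verified equal to exact path interpolation to
1e−8).  σ² is the df-corrected residual variance of an OLS refit on the
final active set, falling back to the smallest-penalty lasso residual
variance when the active set is too large, and floored near zero so that
perfect fits yield p → 0 rather than an undefined test.

Link p-values from all genes are pooled into one network-wide Storey
q-value family ("q ≤ 0.01" then means the same thing for every link);
retained links (q ≤ 0.01) define each gene's model, with weights read at
the path knot following the last retained entry.  The ensemble repeats
inference on 100 random training subsets of floor(0.75·n) samples (65 of
87), testing on the complementary 22; per-gene prediction r is averaged
over the ensemble.  Each learned network is compared against 10
degree-preserving random rewirings (directed double-edge swaps, 10·|E|
accepted swaps, weights traveling with edges; in-/out-degree sequences
preserved exactly), using a one-sided Mann–Whitney U test of the per-gene
mean correlations and a Wilcoxon signed-rank test of the learned
correlations against zero.  The consensus keeps links supported by ≥ 90 of
100 networks; hubs are consensus genes with out-degree ≥ 3 (≥ 2 for
display purposes).

Seeding: replicate i uses seed master + i; randomization instance j of
replicate i uses master + 10⁶ + i·n_random + j.  All tie-breaks (LARS
entries, hub sorting) resolve by lowest index/identifier, making ensembles
bit-reproducible.

### Hub phase-behavior classification

A hub's sign pattern (s1, s2, s3) holds its calls for AP vs CP, BC vs AP
and BC vs CP at q ≤ 0.05.  Classification rule: *accelerated-distinct* iff
s1·s2 = −1 (opposite changes around AP), or s1 ≠ 0 and s2 = 0 (a change
into AP that does not continue), or s1 = 0, s2 ≠ 0, s3 = 0 (a change out
of AP that cancels over the full progression); otherwise the BC-vs-CP call
decides *toward-blast down* (s3 = −) or *toward-blast up* (s3 = +); all-flat
patterns are unclassified.  This rule reproduces the published grouping of
all 24 CML hub genes bundled in `phasenet.datasets` (verbatim input data,
not a computed result).

## Synthetic-data generator

The generator emulates a phase-labelled cohort at the study design sizes:
42 chronic, 17 accelerated (9 blast-count, 8 cytogenetic) and 28 blast
samples, optionally 15 resistant.  Defaults: 200 genes, 15 hubs with
out-degree 3–10, effect size 1.5 log2 units, noise SD 0.5 — a
desk-runnable stand-in for the 14,914-gene cohort that keeps the
group-size geometry and signal-to-noise of normalized log-ratio data.

Topology is one layer (hubs → targets, no chains), targets drawn without
replacement globally so each target has exactly one regulator — this makes
recovery scoring exact and edges identifiable.  Edge weights are
±Uniform(0.5, 1.5).  Phase effects enter the network at its sources: all
hubs, plus half of the *unconnected* genes, get accelerated/blast mean
shifts of magnitude effect_size × Uniform(0.5, 1) with random signs
(chronic is the reference).  Connected targets inherit phase structure
through their regulators — the premise of the inference model is precisely
that a signature gene's phase behavior is explained by its regulators, so
planting independent target effects would make the generator contradict the
estimand (and, because all group-mean profiles live in a 2-dimensional
space, would let unrelated genes proxy a target's mean profile better than
its true regulator).  Target genes still receive their own additive effect
term in the model equation; it is zero under the default assignment and
exercised through configuration.

What the generator does **not** emulate: empirical correlation structure of
real cohorts (cell-composition gradients, batch effects), heavy-tailed
noise, probe-level artifacts, regulatory chains or feedback, and
many-regulator targets.  Passing recovery tests therefore demonstrates
correctness of the inference machinery under the planted model, not
real-data performance.  Two inherent behaviors to expect on any data: (i)
direction is not identifiable from observational covariance — each hub's
own model stably selects its strongest target, contributing roughly one
reversed edge per hub to the consensus (the dominant false-positive class
in recovery scoring); (ii) with zero noise all phase profiles are collinear
in the group-mean space, so *which* gene serves as predictor is arbitrary
even though prediction is perfect.

## Numerical and calibration notes

- The covariance test's Exp(1) reference is asymptotic in the number of
  predictors.  At p = 10 the exact first-knot statistic (orthogonal-design
  closed form z₁(z₁ − z₂)) sits slightly below Exp(1) (KS distance ≈ 0.05,
  median p ≈ 0.55): p-values are mildly conservative at small predictor
  counts.  The implementation matches the closed form to machine precision;
  the sample mean of T under the null is 1.00.  At the signature scale
  (hundreds of predictors) the approximation is much closer.
- Realized FDR of the DE stage at q ≤ 0.05 on a 10%-non-null simulation is
  ≈ 0.05 (50 replicates), i.e. within 1.2× nominal.
- Problem sizes used by the test suite and the acceptance script — 200
  genes / 15 hubs / 87 samples with 100 resampled networks (and a 60-gene
  fixture for module tests) — are the package's chosen desk-scale study
  conditions; the full-cohort configuration (14,914 genes) is provided in
  `scripts/reproduce_cohort_study.py` and takes hours, requiring the
  externally deposited data.
- Degenerate inputs are handled by documented conventions: constant
  responses yield empty lasso paths; constant vectors are rejected where a
  correlation is undefined; single-sample matrices cannot be
  quantile-normalized; groups need ≥ 2 samples for any contrast.

## Known limitations

- Inferred links are statistical dependencies; they can reflect indirect
  regulation or mere correlation and carry no causal claim.
- The q-value family for links is network-wide by design; per-gene families
  would change the meaning of the link cutoff (exposed for comparison via
  the single-gene `fit_gene_model`, which uses a per-gene family).
- The enrichment FDR family scope (per contrast, categories × directions)
  is one of several defensible choices and is logged prominently in the
  output tables' construction.
- No array-weight estimation, duplicate-spot correlation or
  intensity-dependent (loess) normalization; catalogs are user-supplied
  files, no live GO/KEGG retrieval; no raw GEO SOFT/CEL parsing.
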