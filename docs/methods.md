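# Methods

This note documents the statistical models behind `synovnet`, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model and preprocessing

The unit of measurement is an aptamer: a DNA reagent reporting the
relative abundance (RFU) of one protein target; several aptamers may map
to one UniProt protein. Matrices arrive on the linear scale and all
statistics are computed on log2 values. The input is assumed already
normalized by the platform's internal steps (hybridization control,
intraplate median, plate calibration); those are out of scope.

**Limit of detection.** Per aptamer, LOD = mean + 5·SD of the log2 buffer
(no-sample) wells, with the n−1 SD denominator (a convention choice; at
least two buffer wells are required). Aptamer filtering applies three
criteria *sequentially* — (1) no UniProt mapping, (2) non-human target
organism (case-insensitive allow-list, default {"Human", "Homo sapiens"}),
(3) any *study-sample* log2 value below LOD — so an aptamer failing
several criteria is counted once, at the first failing stage. Sequential
attribution makes the stage counts deterministic; buffer and replicate
rows are excluded from the below-LOD test.

**Repeatability.** For m replicate pairs with log2 differences d_i, the
within-pair SD is s_w = √(Σ d_i²/(2m)) and the repeatability coefficient
is RC = 1.96·√2·s_w on the log2 scale, reported as 100·(2^RC − 1) percent
on the fold scale. Only aptamers above LOD in *all* replicate samples are
eligible; ineligible aptamers are excluded rather than zeroed. The RC
definition is not standardized in the field; this formula (95% limit of a
test–retest difference, mapped to fold percent) is a committed,
documented choice — a within-pair CV on the linear scale would be a
defensible alternative and would give similar low-teens percentages at
this noise level.

## Differential abundance

Fitting one model per aptamer would forgo variance pooling; fitting all
aptamers at once is intractable. The compromise is a random partition
into batches of 50 aptamers (batch size and partition seed are recorded),
each fit as one REML linear mixed model on long-format data:

    y_{s,a} = aptamer_a + group_{g(s)} + sex_s + age_s
              + (group×aptamer) + (sex×aptamer) + (age×aptamer)
              + u_{subject(s)} + ε_{s,a},

with u ~ N(0, σ²_u) and ε ~ N(0, σ²_e) pooled within the batch. The
random intercept absorbs the correlation among one donor's measurements.
Because group interacts only with aptamer (not with sex or age), the
adjusted mild−healthy contrast for aptamer *a* is exactly the sum of the
group main coefficient and its group×aptamer interaction, independent of
the covariate values at which means are taken.

Estimation uses statsmodels' MixedLM; coefficient covariance is then
re-derived in closed form on the compound-symmetry GLS surface at the
estimated variance components. Degrees of freedom use the Satterthwaite
approximation, df = 2g²/(∇gᵀ·Var(θ̂)·∇g) with g the contrast variance and
Var(θ̂) the inverse REML information (finite differences on the
closed-form restricted likelihood). Kenward–Roger would give slightly
wider intervals in very small samples; Satterthwaite was chosen for
availability and is one known source of small CI discrepancies. Singular
fits (e.g. zero residual variance) fall back to OLS with residual df and
are flagged, never silently dropped; rank-deficient designs go through a
pseudoinverse with a per-contrast estimability check.

All three study groups are always included in the fit — the extra group
improves estimation of the age and sex confounders and of σ²_e — even
though the network stage uses only two. An aptamer/protein is called "up"
or "down" when the 95% CI excludes zero; protein-level counts collapse
aptamers by UniProt ID (a protein qualifies if any of its aptamers does).
No multiple-testing correction is applied; the output is estimates with
raw CIs.

## Joint Gaussian graphical model

For groups k = 1..K (here 2) with standardized data X⁽ᵏ⁾ (per group, per
column: mean 0, sample SD 1), the estimator solves

    min_{Ω, Γ}  Σ_k 1/(2n_k)·‖X⁽ᵏ⁾ − X⁽ᵏ⁾(Ω + Γ⁽ᵏ⁾)‖²_F
                + λ₁ Σ_{i<j} ‖(Ω_ij, Ω_ji)‖₂
                + λ₂ Σ_k Σ_{i<j} ‖(Γ⁽ᵏ⁾_ij, Γ⁽ᵏ⁾_ji)‖₂,   diag(Ω)=diag(Γ⁽ᵏ⁾)=0.

This is node-wise neighborhood regression with a group-lasso penalty on
symmetric coefficient pairs, so an edge enters or leaves both directions
jointly; Ω carries structure shared by all groups, Γ⁽ᵏ⁾ the group-specific
deviations. Optimization is block coordinate descent with group
soft-thresholding, zero initialization, and a fixed sweep order (common
blocks in lexicographic order, then each group's specific blocks) for
determinism; the inner kernel is numba-compiled. When the two block
curvatures differ (columns with unequal norms), the thresholding scalar is
found by bisection on the monotone secular equation; with standardized
inputs the closed form applies. Convergence is declared when the largest
coefficient change in a sweep is below `tol` (default 1e−4); the objective
is non-increasing across sweeps (assertable via `track_objective`), and a
KKT checker is provided for verification.

**Regularization.** Defaults λ₁ = 0.1, λ₂ = 0.001 (λ₂ near zero means
group deviations are barely penalized, so single fits are dense and the
burden of sparsification falls on stability selection). `bic_select`
reproduces a two-stage scan: λ₁ over [0.01, 0.25] at fixed λ₂ = 0.001,
then λ₂ over [0.0001, 0.1] at the chosen λ₁, minimizing
BIC = Σ_k [Σ_j n_k·log(RSS_jk/n_k) + log(n_k)·df_k] with df_k the number
of nonzero coefficient blocks in group k, reporting edge counts alongside
(sparsity is part of the judgment). Stability selection is not applied
during the scan.

**Stability selection** draws B = 1000 random subsets of ⌈0.8·p⌉
*variables* (the resampling unit is the variable, not the sample; the 0.8
subset fraction is a configurable choice, as the subset size is otherwise
unspecified). Each subset is refit from scratch; an edge's frequency is
its presence count divided by the number of subsets containing both
endpoints — dividing by B would bias against all edges and was rejected.
Edges with frequency ≥ 0.8 are retained; nodes stay only with at least
one retained edge; edges whose endpoints never co-occurred have undefined
frequency, are never retained, and are counted in a diagnostics field.
Because the same samples underlie every subset, this procedure prunes
edges that are unstable to the conditioning set, not sampling noise — at
near-zero λ₂ it is the main guard against false positives.

Estimation runs at the aptamer level; duplicate-protein nodes are merged
afterwards by edge union (`collapse_by_label`), which is why a network can
have one fewer protein than aptamers. Feature selection ahead of the GGM
takes the top-n aptamers (default 800) by |log2FC| of the mild−healthy
contrast — the two groups the networks compare — with ties broken by
smaller SE, then seq_id.

## Network characterization

Edges of the two group graphs are partitioned into shared (present in
both) and group-unique sets; unique-edge subgraphs drop isolated nodes.
Degree is the incident-edge count. Betweenness is unnormalized with
fractional geodesic counting over unordered pairs, endpoints excluded
(Brandes accumulation via networkx); disconnected pairs contribute
nothing. Centralities are reported on both the full and the unique-edge
views — differences between groups are concentrated in the latter.
Communities are the most frequent Louvain partition across 20 seeded
runs, compared label-free as sets of node sets; ties break by higher
modularity, then canonical order. Communities of ≥ 3 members are labeled
alphabetically, ordered by decreasing size then smallest member name
(the ordering within "alphabetically" was unspecified; this one is the
committed choice). Protein-class annotation is a local left join against
a user-supplied class table with an extracellular-matrix rollup; no live
ontology service is queried.

## Cross-platform validation

Network proteins found in the MS table pass three sequential filters:
proteotypic peptide present; more than one stripped peptide *in the
dataset as a whole* (per-sample counting would be a stricter alternative;
dataset-wide is the committed reading); strictly more than 50% non-missing
values. Per-protein agreement is the Pearson correlation of z-scored log2
values over pairwise-complete shared samples (≥ 3 required, else NA) —
"standardized" is read as z-scoring, making the correlation invariant to
affine rescaling of either platform. Fold-change comparison refits the
differential-abundance model with protein-level MS quantities as the
outcome and proteins in place of aptamers; rows with missing MS values
drop out of the long-format fit, which the unbalanced-block machinery
handles.

## Synthetic data

`synthio` generates what the analysis assumes: per-group log2 MVN draws
with sparse precision matrices built from sampled disjoint shared and
unique edge positions, partial-correlation magnitudes in (0.3, 0.5) with
random signs (shared edges keep one value across groups), unit diagonal,
and diagonal loading δ·I with the smallest δ ≥ 0 bringing the minimum
eigenvalue to 0.1 — loading preserves the zero pattern exactly but
shrinks realized partial correlations (on the default recovery
configuration, nominal 0.3–0.5 magnitudes realize as ≈ 0.24–0.39). On top
of the network component: baseline abundances Uniform(9, 15) log2 (the
floor sits ~3.5 SD above the buffer noise floor so a few percent of
aptamers fail the LOD rule, matching the platform's typical filtering
rate); group shifts on a chosen subset (log2 magnitudes 0.5–2); sex
effects and age slopes on a subset; one donor intercept per sample
(σ = 0.3; each donor is an independent subject, but the intercept still
correlates that donor's thousands of aptamer measurements); buffer wells
i.i.d. Normal(4, 0.3) per aptamer on the log2 scale (the real buffer
distribution is unpublished; this noise-floor stand-in exists to exercise
the LOD rule, nothing more); replicate rows that re-noise existing
samples with SD 0.09 log2, placing repeatability coefficients near the
low-teens percent range reported for the platform; and annotation defects
(UniProt-less and non-human aptamers, plus a fraction of aptamers sharing
a protein). Cohort defaults mirror the emulated design: groups of
12/13/14 donors, ages Normal(71, 8) truncated to [50, 95], balanced sex.

What the generator does *not* emulate: plate structure and calibrator
normalization, heavy-tailed or skewed abundance distributions,
missingness on the affinity platform, dilution-bin heteroscedasticity,
and biological pathway structure in which edges are not exchangeable.
Passing recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not performance on real synovial
fluid.

## Numerical choices and problem sizes

- Coordinate descent: tol 1e−4 on the max coefficient change, max 1000
  sweeps, non-convergence returns a flagged result. Ties in the BIC scan
  take the smallest grid value.
- Satterthwaite: variance-scale finite differences with relative step
  1e−4, df clipped to [1, residual df]; information-matrix failures (e.g.
  boundary σ²_u = 0) fall back to residual df.
- Mixed-model calibration experiments use 50 datasets × 10 aptamers with
  400 donors per compared group: at these sizes the Monte-Carlo SE of the
  mean bias (~0.005 log2) is small enough that the ±0.02 bias check tests
  the estimator rather than simulation noise. Graph-recovery experiments
  use p = 30–40 variables, 150 donors per group, and stability selection
  with B = 100–200 at λ₁ = λ₂ = 0.3 — a sparsity level chosen once
  against a graphical-lasso reference and frozen; the full-scale
  configuration (p = 800, B = 1000) runs the same code path and is
  reserved for real analyses.
- The pipeline derives per-stage sub-seeds by hashing the stage name with
  the global seed, so stages can be re-run in isolation and identical
  configs reproduce identical artifacts (checksummed in the manifest).

## Known limitations

- λ₂ = 0.001 (the literature default mirrored here) leaves single fits
  dense; interpretation should rest on the stability-selected graphs.
- Group-lasso shrinkage biases active coefficients toward zero, which can
  induce residual correlation along true paths and occasionally admits a
  chained false edge; stability selection mitigates but does not remove
  this.
- The batched mixed model pools residual variance within a batch; truly
  heteroscedastic aptamers borrow an averaged variance, which the CI
  calibration experiment (homoscedastic by construction) does not probe.
- Betweenness on graphs with many tied geodesics is sensitive to edge
  presence/absence; small-count differences between groups should not be
  over-read.
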