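# Methods

## Functional connectivity construction

Each subject contributes a T×R matrix of region-mean time courses (from
`parcellation.parcellate` when starting from a labelled 4D volume, or
directly). FC between two regions is the Pearson correlation over the full
scan duration, Fisher z-transformed (z = atanh r) to stabilise variance.
|r| is clipped at 1−10⁻¹² before the transform so degenerate, perfectly
correlated columns give a large finite z rather than ±∞; clips are counted
and logged. Edges are enumerated once — upper triangle, row-major, 1-based
(i, j) with i < j — and every downstream table keys on (edge_id, i, j), so
the ordering convention is auditable. The group FC table stacks one edge
vector per subject (494 × 6670 at study scale).

The parcellation scheme assigns each region one of seven lobe labels
(FR, PA, TE, ME, OC, SU, CE) and a display order used to permute FC
matrices into lobe blocks for reporting. The ROI-homogeneity QC tests each
voxel's Pearson correlation with its region-mean series (two-sided t,
T−2 d.f.) and reports the per-region fraction significant plus the count
of regions above 50%. The voxel's own contribution to the region mean is
included by default (the test as usually stated); `exclude_self=True`
gives the leave-one-out variant, which is slightly conservative for small
regions.

## Edge-wise regression and model selection

The full model per edge is
F = β⁰ + βˢ·sex + βᵃ·age + βⁱⁿᵗ·sex×age + ε, sex coded female=0/male=1,
age in raw years (centring optional; it changes main-effect tests only
when the interaction is present). Backward elimination removes, at each
step, the removable term with the largest removal p-value while that
p-value is ≥ α_remove = 0.05. For a single-term removal the partial F
equals the squared coefficient t, so removal p-values are read from the
current fit. The marginality rule makes the interaction removable at any
time but a main effect only once the interaction is gone; the reachable
model set is therefore exactly {M1, M2, M3, M4, M5}. Exact ties remove
the interaction first, then the later-declared term, so runs are
bit-reproducible.

All edges share one design matrix, so the mass-univariate path fits all
five candidate models for every edge in a handful of batched least-squares
solves and replays the elimination logic on the precomputed p-value
tables; this is algebraically identical to the per-edge loop (tested) and
orders of magnitude faster.

Significance: the selected model must pass its overall F-test (vs.
intercept-only) at the Bonferroni threshold α/n_edges, and a term is
flagged only if additionally its own two-sided p passes the same
threshold. The threshold for α=0.05 over 6670 edges is reported in 10⁻⁶
units truncated to two decimals (7.49). Benjamini–Hochberg FDR is
available as an alternative. The Bonferroni denominator defaults to the
full edge count and is configurable.

Two calibration facts about this best-model-then-test procedure, measured
by the test suite under the global null:

* The probability of reaching M1 on a pure-noise edge is ≈ (1−α_remove)³
  ≈ 0.857 — three removal decisions must all clear (interaction, then each
  main effect) — not (1−α_remove)².
* The per-covariate-family family-wise error (any spurious Bonferroni-level
  sex finding; any spurious age finding) is controlled near α, as the
  α/n_edges threshold guarantees. The rate of *any* flag including the
  model-level F is ≈ 2–3×α, because the selected model's F-statistic is
  the best of several correlated candidates; this selection bias is
  intrinsic to gating on the best model and affects the descriptive count
  of "significant models", not the per-family effect detections.

Degenerate (exact-fit) responses are handled explicitly: when the residual
sum of squares is ≤10⁻¹⁰ of max(total SS, response scale²), coefficients
below 10⁻⁸ of the response scale are treated as zero (p=1) and the rest
as exact (p=0), so noise-free planted signals select their generating
model deterministically.

Covariate augmentation refits each edge's already-selected model with
extra covariates appended (no re-selection), reporting which corrected
effects survive. Sex-stratified age slopes are simple per-group OLS of z
on age with per-group Bonferroni flags and the count of edges where both
slopes are negative with the female slope steeper. FC–cognition screening
is the direct Pearson correlation per edge with t-based p-values.

## Graph analysis

Proportional thresholding keeps the k = round(d·R(R−1)/2) largest signed
z-values (round half away from zero; ranking by |z| optional), with ties
at the cutoff broken by ascending (i, j) so k is exact and deterministic.
On the binary graph:

* nodal clustering c_i = 2t_i/(k_i(k_i−1)) (t_i = triangles through i),
  0 when k_i < 2; the network coefficient C is the mean over **all** R
  nodes, zero-degree nodes contributing 0;
* nodal local efficiency e_i is the global efficiency (mean inverse
  distance over ordered pairs, 1/∞ = 0) of the subgraph induced by i's
  neighbours, 0 when k_i < 2;
* characteristic path length L is the harmonic mean of geodesic distances,
  L = R(R−1)/Σ(1/d) — the reciprocal of global efficiency — which remains
  finite for disconnected graphs and is undefined (error) only for an
  edgeless graph;
* the largest connected component size is reported per density.

Null networks are generated by double-edge swaps ((a,b),(c,d) →
(a,d),(c,b)) that reject self-loops and duplicates, preserving every
node's degree exactly. The default ensemble is 30 nulls at 10 *successful*
swaps per edge, attempts capped at 100× the target with a logged
shortfall; a flag counts attempts instead, since "rewiring each edge ~10
times" is ambiguous. σ = (C/C_rand)/(L/L_rand) with C_rand, L_rand the
ensemble means; triangle-free ensembles give σ = NaN (flagged) rather
than ∞. For the complete graph no legal swap exists, the nulls equal the
graph, and σ = 1 exactly.

Randomness is counter-derived: each (subject, density) cell seeds its own
generator from SeedSequence([master, subject_index, density_index]), so
results are independent of execution order.

## Group statistics

Two-sample comparisons default to Student's pooled-variance t (Welch
optional). Nodal metrics are compared per node × density; only cells with
p < α/R enter the stacked sign(t)·(−log₁₀ p) summary, summed over all
grid densities per node (positive = male > female). Global metrics
(largest component, C/C_rand, L/L_rand, σ) are compared per density at
nominal α with no across-density correction, matching the per-density
presentation convention. An OLS variant with sex + age covariates
confirms sex contrasts are not age-driven, and motion checks report the
frame-displacement sex t-test and FD–age correlation. Zero variance in
both groups with equal means yields t=0, p=1; with unequal means it is an
error rather than a silent ±∞.

## Synthetic cohort generator

The generator emulates the statistical structure of a young-adult
resting-state cohort: 203 males / 291 females by default, ages uniform on
[22, 36] (only the range and moments of the real cohort are known, so a
uniform is the least-committal choice), 116 regions / 6670 edges, 1200
timepoints. Optional covariates: seven cognition scores ~ Normal(100, 15)
(the age-adjusted NIH-toolbox scale), intracranial volume with a male
mean shift, and mean frame displacement with no sex difference.

Direct-z mode draws each edge from the generative inverse of the
regression model with configurable per-edge μ (Normal(0.3, 0.1), a typical
resting FC z-level), disjoint sets of sex/age/interaction edges, and
noise σ=1. With σ→0 every coefficient is recovered to ≤10⁻¹⁰ downstream.
Planted directions follow the phenomena being emulated: sex effects
positive (male>female), age effects negative.

Effect magnitudes are free parameters calibrated for detection power, as
no empirical effect sizes are available — only p-values. The default sex
effect is 0.55 z-units: the noncentral-t oracle gives
δ = 0.55/√(1/203+1/291) ≈ 6.0 and ~93% nominal power at the 7.49×10⁻⁶
threshold, leaving margin for the ~5-point loss from best-model selection
(edges that retain a null age/interaction term face a diluted model-F
gate) so end-to-end detection stays above the 80% target. The power
acceptance check brackets the empirical rate between a selection-mixture
lower bound (M2 selected w.p. 0.95², detection by noncentral t; M4 w.p.
0.95·0.05, detection by noncentral F(2); M5 counted as missed) and the
pure noncentral-t upper bound. The default age slope is −0.06
z-units/year, similarly powered given the age SD of ≈4.0 years.

Time-series mode draws zero-mean multivariate normal T×R series with a
within-lobe block / between-lobe floor correlation target, plus an
optional male-only correlation shift on designated edges; targets are
repaired to positive definiteness by shrinking toward the identity
(factor 0.95/iteration, max 200, smallest eigenvalue > 10⁻⁸). Effects
planted here live on the correlation scale and appear only approximately
on the z scale. The generator does not model BOLD autocorrelation,
scanner drift, or motion artifacts: passing tests demonstrate that the
*statistical* machinery recovers what it assumes, not robustness to fMRI
physics or preprocessing choices.

## Problem sizes in the test and acceptance runs

Regression recovery runs at full study scale (494 × 6670; the batched
solver makes this cheap). Null-calibration replicates use 494 subjects ×
528 edges (33 regions) per replicate, 100–200 replicates. Graph-metric
oracle checks use 200 random graphs with R ≤ 15 against exhaustive
enumeration; small-world regime checks use R = 60 (rewired ring lattice
k = 6, p = 0.1; Erdős–Rényi p = 0.15) with the full 30-null ensemble. The
end-to-end determinism check uses 20 subjects, 10 regions, 3 densities
and 5 nulls. These sizes keep the whole suite under a minute of compute
while retaining the full-scale regression path.

## Known limitations

* Static, full-duration Pearson FC only; no partial correlation, tangent
  space, or windowed dynamics.
* OLS inference assumes i.i.d. Gaussian errors per edge; no robust or
  permutation alternatives.
* The "significant model" count inherits the selection bias described
  above; treat it as descriptive.
* Time-series mode plants effects on the correlation scale, so exact
  coefficient recovery guarantees apply to direct-z mode only.
* The homogeneity QC and parcellation assume pre-aligned, preprocessed
  volumes; no resampling or denoising is performed.
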