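# Methods

## Connectome model

A subject's structural network is an undirected weighted graph over a
fixed parcellation (default: the 90 cerebral AAL regions). The weight
of edge (i, j) is

    w(i, j) = scale × Σ_streamlines 1/length_mm

summed over streamlines whose endpoints fall in regions i and j.
Summing inverse lengths corrects the linear bias of deterministic
tractography toward long fibers; `scale` is a per-subject seed-density
correction. Its algebraic form depends on acquisition geometry that is
out of scope here, so it is accepted as a given positive constant
(default 1) rather than derived. Weights are in scaled mm⁻¹; edges
below the threshold (default 1) are set to zero to suppress
noise-driven false positives. Thresholding is idempotent and monotone;
building is additive over streamline subsets and equivariant under
region relabeling — these are tested properties, not assumptions.

Edge lists are exchanged as TSV (`region_a`, `region_b`, `weight`),
one row per undirected edge with lexicographically ordered labels;
inconsistent duplicate rows are an error, absent pairs are weight 0.

## Network measures

Degree, density (edges / n(n−1)/2), total strength (sum of edge
weights, each edge once) and weighted global efficiency

    E = 1/(n(n−1)) × Σ_{i≠j} 1/d(i, j)

where d is the shortest-path length with per-edge travel length 1/w
(the standard weighted-connectome convention: stronger = shorter) and
disconnected pairs contribute 0. A binarized variant (unit lengths) is
available via `binary=True`. Shortest paths use
`scipy.sparse.csgraph.dijkstra`; the test suite checks the result
against an explicit Floyd–Warshall oracle to 1e−9 on hundreds of
random graphs.

The rich club is fixed a priori as eight regions — bilateral superior
frontal gyrus, precuneus, superior parietal gyrus and insula — rather
than detected from normalized rich-club coefficient curves; the
`degree_rank_report` diagnostic verifies these nodes rank among the
highest degrees. Edges are classified by endpoint membership: both in
the rich club → rich-club connection, exactly one → feeder, neither →
peripheral. Class strength is the mean weight over *present* edges of
that class; an empty class is reported as missing (NaN), never as 0,
because a mean over no edges is undefined, not small.

## Cognition scores

Timed tests are reduced to speed–accuracy trade-off (SAT) scores,
defined as correct responses per second (higher = better); the Stroop
interference score divides the color-word SAT by the mean of the
reading and naming SATs. Under this convention the interference ratio
*decreases* with more interference; it is used unflipped, and the
verbal-series-attention SAT likewise enters executive function without
a sign flip (the SAT form already makes higher better). Every derived
test score is z-scored against the mean and SD of the *baseline* study
population — follow-up scores use the same baseline norms, so change is
preserved on the z scale. Domain composites are arithmetic means of
available constituent z-scores (memory: RAVLT and RCFT immediate and
delayed recall, 2- and 3-letter memory-scanning SATs; psychomotor
speed: 1-letter memory-scanning SAT, Stroop reading and naming SATs,
symbol–digit substitution; executive function: Stroop interference,
verbal fluency, verbal-series-attention SAT), and the cognitive index
averages the whole battery. A composite is missing only when all its
constituents are; complete-case handling happens at the statistics
layer, not here. Change scores are follow-up minus baseline.

## Statistical layer

* **Paired change test**: mean within-subject change with t-based 95%
  CI and p. With two time points the one-way repeated-measures ANOVA
  is algebraically the squared paired t (F = t²); the suite verifies
  this against statsmodels' AnovaRM to 1e−8.
* **Group × time interaction**: subject-fixed-effects OLS with a
  wave-by-group term; for two waves it equals the two-sample t-test on
  per-subject change scores (verified identity).
* **Adjusted group difference**: ANCOVA — OLS of the outcome on a
  group indicator plus covariates; the group coefficient is the
  adjusted mean difference. (The alternative reading, residualization
  against covariates before a plain ANOVA, gives attenuated estimates
  when group and covariates correlate; the ANCOVA reading was chosen.)
* **Standardized regression**: outcome and continuous predictors are
  z-scored on the complete-case sample, categorical covariates (0/1
  sex) enter unscaled; OLS coefficients are then standardized betas
  with 95% CIs. Zero-variance columns are an error naming the column.
* **Median split**: values ≤ median → mild, above → severe. Ties go to
  mild — deterministic and conservative for the severe stratum.
* **WMH log transform**: natural log, positive volumes only (WMH
  volumes are strongly right-skewed).
* **Mediation**: single-mediator path model. Path a from OLS
  m ~ x + covariates; paths b and c′ from y ~ m + x + covariates; all
  continuous variables standardized first; indirect effect = a·b. A
  binary outcome stays on its 0/1 scale in a linear probability model,
  which keeps the decomposition total = c′ + a·b exact (verified to
  1e−9); a probit outcome model is available behind `y_model="probit"`
  for sensitivity analysis (latent-scale paths, approximate
  decomposition). Inference for the indirect and direct effects is a
  nonparametric percentile bootstrap over subjects (default 2000
  resamples, seeded, vectorized via batched normal equations); the
  Sobel normal-theory test is reported alongside. No multiple-testing
  correction is applied anywhere; raw p-values are reported with
  conventional star thresholds (0.05 / 0.01 / 0.001). Every result
  carries the n actually used after complete-case filtering.

## Synthetic cohort generator

The generator is the package's ground-truth test bed: every injected
parameter is recorded, so each analysis stage can be validated by
parameter recovery. Defaults describe a realistic elderly SVD cohort:
270 subjects with two imaging waves 3.4 ± 0.2 years apart, age
67.9 ± 7.8, 59.6% male, education 10.1 ± 1.5 years, WMH volumes
log-normal with median 2.8 ml and IQR 1.3–7.8 ml, lacune and microbleed
counts Poisson with burden-dependent rates, dementia incidence 7.0%.

Causal structure, in order:

1. **Latent burden** z ~ N(0,1) per subject drives WMH volume
   (exactly log-linear in z), lesion counts, brain volumes and network
   degradation. The log-normal is parameterized as mu = ln(median) and
   sigma = ln(q75/q25)/(2·0.6745): the printed quartiles are not
   exactly symmetric about the median on the log scale, so a
   two-parameter fit matches the median and the IQR ratio, not each
   quartile separately.
2. **Baseline networks** perturb a cohort-level template drawn from
   class-wise edge probabilities: rich–rich pairs connect with p=0.9,
   feeder pairs with p=0.35, and the peripheral probability is solved
   to hit the overall density target (0.15); an unsatisfiable
   combination raises an error. Class-wise log-normal weights (means
   12 / 5 / 3 mm⁻¹, log-SD 0.3) give hub edges a strength premium.
   Per subject, 3% of edges are rewired, weights jitter (log-SD 0.15),
   a global log-normal factor (log-SD 0.10) models individual
   differences, and all weights shrink by exp(−0.15 z) with burden.
   This makes all 8 rich nodes rank in the top-12 degrees in ≥95% of
   subjects (a tested property) and induces the negative
   burden–network associations the regression layer should find.
3. **Decline**: per subject and class, a change d ~ N(mean_c, sd_c) in
   the class-mean strength is applied multiplicatively to that class's
   edges. Default means (−0.44, −0.03, −0.02) are the change over the
   follow-up interval; the SDs (1.55, 0.40, 0.18) are back-computed
   from the calibration CIs as SE·√n. Additionally 1% of edges drop
   out at follow-up so density and efficiency decline too; random
   dropout leaves the class-mean change unbiased (tested: the pooled
   change estimate over 50 cohorts recovers each configured mean
   within 2 Monte-Carlo SEs).
4. **Cognition** is generated at the composite level: change scores
   load on the standardized injected peripheral-strength decline
   (default loadings 0.15 / 0 / 0.15 / 0.12 for index / memory /
   speed / executive — memory deliberately null) plus a configurable
   *direct* WMH effect, default 0, making the network the complete
   mediator of WMH-related cognitive decline by construction. A
   raw-score mode synthesizes per-test scores (SAT tests as integer
   counts with time = count/SAT, so derived scores are exact) and then
   recomputes the stored composites through the cognition module
   itself, guaranteeing self-consistency for cognition-module tests.
5. **Dementia** ~ Bernoulli(expit(c + s_eff·z(efficiency) +
   s_per·z(peripheral strength))), both at baseline, with the
   intercept solved numerically so the cohort-average risk equals the
   configured base rate. The slopes are not given by any calibration
   source; they were fixed by an a-priori design scan at (−1.75, −0.9)
   log-odds per SD: weak slopes starve the indirect path of power,
   while very strong slopes inject so much logistic curvature that a
   linear-probability analysis attributes a spurious *positive* direct
   WMH effect — an artifact of approximating a convex risk curve, not
   of an omitted mediator (it appears even when the exact linear
   predictor is used as the mediator). The chosen values yield a
   significant indirect and a null direct effect in ≥90% of seeds.

All randomness flows from one seed through named substreams
(demographics, template, networks, cognition, dementia), so a module's
draws are unaffected by changes elsewhere.

### What the generator does not emulate

Real tractography artifacts (gyral bias, crossing-fiber failures,
distance-dependent false negatives), spatial lesion–tract anatomy (WMH
damage here scales all weights uniformly rather than hitting specific
tracts), practice effects and parallel test versions, attrition and
missingness (generated cohorts are complete; exclusion accounting in
the pipeline is exercised only when data are deliberately removed), and
competing mortality risk for dementia. Passing recovery tests therefore
show the *analysis chain* is correct and unbiased under the injected
model — not that the model captures every property of real cohorts.

## Numerical and design choices

* Problem sizes in the test suite (200 random graphs for oracle
  equivalence, 200 simulation replicates for regression and mediation
  recovery, 50 cohorts for generator consistency, n = 2000 for the
  WMH concentration check) keep Monte-Carlo error comfortably below
  each asserted tolerance while keeping the default run fast.
* Bootstrap CIs are percentile (2.5/97.5); the two-sided bootstrap p
  is twice the smaller tail relative to zero, capped at 1.
* Degenerate inputs fail loudly: self-loops, nonpositive lengths or
  times, zero-variance regressors, all-identical median splits,
  sub-minimum sample sizes all raise with the offending record named.
* Matrices are validated on construction (symmetry, zero diagonal,
  nonnegativity); mediation seeds derived inside the pipeline stay
  below 2³¹.
* Pipeline tables are written with a fixed float format, making
  identical config + seed byte-identical across runs (tested).

## Known limitations

* The linear probability model for binary mediation is exact for the
  effect decomposition but its direct-effect estimate inherits the
  curvature artifact described above when risk heterogeneity is large;
  the probit flag exists for sensitivity checks.
* Class strengths condition on present edges, so strong edge dropout
  would couple strength and density changes; at the default 1% this
  effect is negligible.
* The generator's cognition raw-score mode targets self-consistency,
  not test-level realism (e.g., integer item counts are plausible but
  norms are nominal).
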