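# Methods

This note records the models, estimators and numerical conventions the
package implements, the study conditions its synthetic generators emulate,
and the design choices made where the procedure was genuinely open.

## Tipping-point scan (dynamic network biomarkers)

A disease progressing through ordered stages is modeled as a dynamical
system approaching a critical transition. Near the tipping point, theory
predicts a dominant group of variables — the DNB module — whose
fluctuations grow, whose internal correlation strengthens, and whose
correlation with the remaining variables weakens. The scan operationalizes
this per non-reference stage:

1. **SD filter.** Keep genes with `SD(stage) ≥ fold · SD(reference)`,
   `fold = 2`, boundary inclusive. Genes with zero reference SD pass iff
   their stage SD is positive and are flagged. Stages need ≥ 3 samples.
2. **Candidate modules.** Agglomerative clustering of the surviving genes
   with complete linkage on `d = 1 − |r|` (Pearson, stage samples only).
   Every cluster appearing at any cut height of the dendrogram with at
   least `min_size = 5` members is a candidate; harvesting all heights
   avoids an arbitrary cut parameter and is deterministic.
3. **Normalization.** Genes are standardized per stage before correlation
   (Pearson r is invariant to this) and, materially, the SD term of the
   index is *gauged*: each gene's stage SD is divided by its own
   reference-stage SD. What signals criticality is the rise of a gene's
   fluctuation over its own baseline; ungauged, the average-SD term is
   dominated by whichever genes have the largest raw variance, and module
   selection degenerates into picking high-variance subclusters. The raw
   scale remains available (`sd_scale="raw"`). The correlation-scale
   Fisher transform `atanh(r)` is exposed as `fisher_z` for pooling
   correlations.
4. **Indices.** For members M in universe U at stage s:
   `SD_avg = mean_g∈M SD_g(s)/SD_g(ref)`, `PCC_in = mean |r|` over member
   pairs, `PCC_out = mean |r|` over member × non-member pairs,
   `CI = SD_avg · PCC_in / max(PCC_out, ε)`, `ε = 1e-8` (guards an
   all-orthogonal background). The same three indices are recomputed at
   the reference stage for the same gene set.
5. **Criteria and selection.** In the deterministic `ratio` mode a
   candidate satisfies the DNB criteria iff `SD_avg ≥ fold · SD_avg_ref`,
   `PCC_in ≥ 1.5 · PCC_in_ref`, and `PCC_out ≤ 0.75 · PCC_out_ref`; a
   `bootstrap` mode (B = 200 resamples, one-sided α = 0.05) is available
   when a statistical reading of "significantly increased/decreased" is
   preferred. Among satisfying candidates the highest CI wins. CI values
   within 15% (relative) of the maximum are treated as ties: for a
   minimum-size module at ~60 samples/stage the relative sampling error of
   CI is roughly 8–9% (SD-ratio noise ≈ 13%/√5 plus correlated |r| noise),
   so a one-sided ~95% allowance is ~15%, and inside that band the larger
   module wins, then the lexicographically smallest member list. Nested
   sub-modules therefore cannot displace their parent on estimation noise.

CI is scale-covariant: multiplying member expression at the stage by c > 0
multiplies `SD_avg` and CI by c (the gauge uses reference-stage SDs only)
and leaves both correlation terms unchanged.

## Rank conservation (DIRAC)

For an m-gene pathway, each unordered gene pair (a, b) (a lexicographically
smaller) receives the orientation held in a strict majority of a
phenotype's samples; exact ties and tie-dominated pairs default to the
lexicographic orientation, making templates deterministic. A sample's
matching score is the fraction of template pairs it satisfies, with
within-sample expression ties counting as unsatisfied (conservative; the
formulation assumes continuous data). RCI is the mean matching score of
the phenotype's samples against their own template; being a pure rank
statistic it is invariant to any strictly monotone per-sample transform.
Own-template RCI is optimistic: for i.i.d. data the majority orientation
agrees with ~`0.5 + sqrt(2/(πn))/2` of samples, ≈ 0.53 at n = 200, which
is the expected null level rather than exactly 0.5.

Differential conservation uses the statistic `RCI_a − RCI_b` (two-sided
|Δ| by default; one-sided modes by flag), a group-label permutation null,
and the add-one estimator `p = (1 + #{T_perm ≥ T_obs}) / (1 + n_perm)`
(valid, slightly conservative); q-values by Benjamini–Hochberg across
pathways. Default `n_perm` is 1000 in the CLI; the calibration tests use
500.

## Global divergence

`RMSD(x, y) = sqrt(Σ (log2 xᵢ − log2 yᵢ)²/n)` — a metric on log-space
profiles. The summary reports mean pairwise RMSD within each phenotype and
between two designated phenotypes, each as a percentage of the between
mean (100% by construction). Note that the characteristic tumor pattern
*between > within-tumor > within-normal* requires tumors to be displaced
from the normal baseline, not merely dispersed: with equal means,
`between² = σ_t² + σ_n² < 2σ_t² = within-tumor²`. The synthetic check
therefore displaces per-gene tumor means (N(0, 2²) log2 units) in addition
to inflating tumor variance.

## Per-sample enrichment

The per-sample score is the ssGSEA running-sum integral: rank statistic
`s_g = N + 1 − rank_g` (descending ranks, average for ties; ties walked in
row order), weight `s_g^α` with α = 0.25 by default (α = 0 gives a pure
rank statistic invariant to monotone per-sample transforms), score
`Σ_i [cum_in_weight(i)/total_in_weight − cum_out_count(i)/(N − m)]`, then a
whole-matrix (max − min) normalization. This is a deliberate, fully
specified stand-in for kernel-CDF GSVA scores: downstream clustering
consumes z-scored scores, where the two agree qualitatively. Scaling is
per pathway across samples by default — clustering distances need
comparable pathway axes — with a per-sample mode available; scaling uses
ddof = 1 and is idempotent. The pathway universe used after a tipping-point
scan is the sets containing at least one module gene
(`sets_containing`), scored over each set's full present-gene list.
Preranked enrichment uses the classic weighted Kolmogorov–Smirnov maximal
deviation (weight |stat|), gene-label permutation null and BH across sets.
Differential genes use Welch t-tests per stage pair with BH within pair
(no variance moderation), selecting genes significant in ≥ 1 pair.

## Subtype discovery

Samples are points in z-scaled pathway-score space; the base learner is
Euclidean k-means (best of 25 initializations; single initialization per
consensus draw). Consensus clustering draws `⌈0.8 n⌉` samples without
replacement per iteration; the consensus entry of a pair is its
co-assignment count over its co-selection count, with never-co-selected
pairs reported as missing (NaN), not 0. PAC is the fraction of
off-diagonal, non-missing entries in (0.1, 0.9). The cluster number is a
majority vote of minimal PAC, maximal mean silhouette (singleton clusters
score 0) and maximal Calinski–Harabasz — a compact, fully specified
replacement for a 21-index battery whose only role is choosing one k; a
three-way split falls back to the smallest voted k with a flag.

## Cross-cohort projection

The classifier is nearest shrunken centroids with
`m_k = sqrt(1/n_k − 1/n)`, `s0 = median(s_i)`, soft threshold
`d'_ik = sign(d_ik)·max(|d_ik| − Δ, 0)`, discriminant
`δ_k(x) = Σ (xᵢ − x̄'_ik)²/(sᵢ + s0)² − 2 log π_k`, and posterior
`softmax(−δ/2)` reported as heuristic confidence, not a calibrated
probability. Δ is chosen from 30 evenly spaced values in [0, max |d|] by
stratified cross-validated error, ties toward the largest (most
parsimonious) Δ. Discriminant differences below 1e-9 are ties resolved to
the first class in sorted order, so predictions are reproducible across
algebraically equivalent evaluation orders. Features with all `d'_ik = 0`
contribute nothing; the active set is non-increasing in Δ, and the
`(sᵢ + s0)` normalization makes predictions invariant to feature-wise
affine maps applied consistently to training and test.

Batch alignment is a reference-anchored standardization, replacing
empirical-Bayes batch correction: every cohort is z-scored per gene by its
own per-gene mean/SD, with the training (reference) cohort's statistics
recorded as the transformation that defines the score space. Subtracting
the *training* mean from a shifted cohort would leave the shift in place;
per-cohort standardization cancels additive, gene-specific platform
offsets exactly, which is the property the classifier's contract needs.
Projection restricts the new cohort to the reference gene universe, drops
pathways with more than half their genes missing (warning), requires ≥ 80%
feature overlap (missing features imputed at the overall centroid), and
maps raw scores into the training space with the training per-pathway
mean/SD.

## Trend clustering

Genes are reduced to standardized stage-mean profiles (mean per ordered
stage, z-scored across stages with ddof = 1; constant genes dropped).
Fuzzy c-means minimizes `Σ_g Σ_k u_gk^m ||x_g − v_k||²` with fuzzifier
m = 2 (conventional default), k-means++-sampled initial centers, and a
per-iteration assertion that the objective is non-increasing. Memberships
are computed from distances scaled by the row minimum before
exponentiation, so small fuzzifiers (large exponents 1/(m−1)) cannot
overflow; distances are floored at 1e-12. The trend count comes from the
Dmin curve (minimum inter-centroid distance per c): while every centroid
can occupy its own trend Dmin stays on the inter-trend scale, and it
collapses to a persistently lower level once two centroids must share a
trend. The elbow is the boundary maximizing the ratio of the pre-elbow
Dmin minimum to the post-elbow Dmin maximum; if that ratio is below 2 the
curve is considered structureless (on noise, Dmin wiggles non-monotonically
by ±30%) and the smallest candidate c is returned with a low-confidence
flag.

## Synthetic cohorts: what they emulate and what they do not

`simulate_staged_expression` emulates a staged bulk cohort on log2 scale:
per-gene baselines `μ_g ~ U(4, 12)`, `σ_g ~ U(0.3, 0.8)`, one weak
cohort-wide factor giving background co-expression `ρ_baseline = 0.2`
(chosen once: the PCC_out criterion is meaningful only against a
materially correlated background for the module to decouple from; 0.2 is a
typical bulk co-expression level). The planted module behaves as
background except at the critical stage, where each member is
`μ_g + σ_g·f·(√ρ_in z_s + √(1−ρ_in) ε)` with one latent z per sample —
an exchangeable correlation structure matching the "strongly correlated
module" picture — so its SD is multiplied by `f = sd_inflation` (default 3)
and its pairwise correlation is `ρ_in = 0.7`. Default cohort: four stages
(Normal, I, II, III) × 60 samples, 2,000 genes, 30-gene module, critical
stage II. Optional trend genes add stage-mean offsets of 2 log2 units
following six fixed patterns; an optional global stage drift stresses the
SD filter. One master seed deterministically splits per sub-generator.

`simulate_cluster_cohort` assigns samples round-robin to k clusters and
shifts cluster k's disjoint signature pathway by `effect_size · noise_sd`
(default 3 pooled SDs) in its samples; 8 pathways × 25 genes plus 300
unassigned background genes, 120 samples by default. A second platform is
simulated by gene-specific additive offsets `N(shift, (1.5·shift)²)`:
platform effects vary strongly from gene to gene, and it is exactly this
dispersion that perturbs within-sample rankings — a constant offset would
be invisible to rank-based scores. Survival annotations are exponential
filler only.

Passing tests on these cohorts demonstrates the estimators' correctness
and calibration under the generating model; real cohorts additionally
carry library-size and composition effects, heavy-tailed and count-based
noise, correlated pathway overlap, missing data and confounded batches
that the generators deliberately do not model (missing values are handled
by the documented drop/impute policy, but are not simulated by default).

## Problem sizes in the test and acceptance runs

Simulation-backed checks use the default study conditions above with 10–25
replicate seeds per claim (25 for tipping-point recovery and its null, 20
for cluster-number recovery, projection and divergence geometry, 10 per
inflation level for CI monotonicity and for trends); consensus clustering
uses 200 iterations at 80% resampling (the CLI default is 1,000);
permutation tests use 500 permutations for calibration runs and 1,000 as
the CLI default; oracle-equivalence checks use 50 random small instances
per operation. The full suite and the acceptance script each complete in
about a minute on one CPU.

## Known limitations

- The scan reports one winning module (plus all candidates); unioning
  satisfying modules across stages is left to the caller.
- Permutation p-values are bounded below by 1/(n_perm + 1); BH across a
  few hundred pathways at n_perm = 500 is near that resolution limit.
- The ssGSEA stand-in is not numerically interchangeable with kernel-CDF
  GSVA scores; only their z-scored forms are comparable.
- Reference-anchored standardization removes additive/multiplicative
  per-gene platform effects but not nonlinear or sample-dependent batch
  structure.
- The NSC posterior is a monotone transform of the discriminant, not a
  calibrated probability.
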