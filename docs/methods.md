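# Methods

This note documents the models, statistical procedures, parameter choices,
and known limitations of the `conngrad` pipeline.

## Problem setting

The pipeline analyzes resting-state functional connectomes of a six-group
cohort ordered along a *suicidality gradient*: healthy controls (HC) and
five depression groups defined by the 17-item HAMD suicide-item score —
no suicidal ideation (MDDNSI, score 0), mild (MDDmSI, 1), moderate
(MDDmoSI, 2), severe ideation (MDDSSI, 3), and suicidal behavior (MDDSB, 4).
Each subject contributes a T×N regional time-series matrix (or a precomputed
N×N connectivity matrix) over a 226-node parcellation assigned to ten
resting-state networks (AUD, CON, DAN, DMN, FPN, SAN, SMN, SUB, VAN, VIS).
Subjects with mean framewise displacement above 0.2 mm are excluded
(retention uses ≤, matching the convention that *greater than* 0.2 mm is
excluded).

## Connectivity summaries

Functional connectivity is the Pearson correlation between regional time
series. Three summaries condense a connectome over the partition:

- **WNC** — mean FC over node pairs within one network (10 values);
- **BNC** — mean FC over node pairs spanning each unordered network pair
  (45 values);
- **OVO** — mean FC between one network and all nodes of the other nine
  (10 values).

All are plain arithmetic means over node pairs, so OVO equals the
pair-count-weighted mean of the corresponding nine BNC values — an identity
asserted in the tests rather than assumed. Negative correlations enter
as-is; there is no thresholding or absolute value. Averaging operates on raw
r by default; the Fisher z transform is available as an option and
propagates through every summary. The matrix diagonal is stored as NaN so
self-correlations cannot leak into any mean. The **FCI** (FC index) of an
edge set is the mean FC over those edges, used as a subject-level composite.

The family of 10 + 10 + 45 = 65 metrics is derived from the partition at
run time (k + k + C(k,2)), never hard-coded.

## Network roles

Per group, each network receives one of four roles from its group-mean WNC
(cohesion) and OVO (connectedness): cohesive/incohesive ×
connector/province. The role cutoffs are not standardized anywhere in the
field's reporting, so the default policy is the least-parameterized reading
of "based on the distribution": the median of the ten group-mean values,
computed separately for WNC and OVO within each group, with ties resolving
upward. A fixed-cut policy is available, and the cuts actually used are
always recorded in the output. Because a median split always places five
networks on each side, a role flip is a rank crossing at the 5/6 boundary —
which shapes how the synthetic generator plants role dynamics (below).

## Covariate-adjusted inference

Group comparisons of the 65 metrics use the ANCOVA reading of a generalized
linear model: ordinary least squares of the metric on group indicators plus
age, sex, education, and study site (site as categorical indicators), with
the omnibus group effect tested by the partial F of the full model against
the covariates-only model. With no covariates this reduces exactly to
one-way ANOVA (tested against `scipy.stats.f_oneway`). Rank-deficient
designs (e.g. site confounded with group) are an error naming the collinear
columns. Multiple comparisons are corrected by Benjamini–Hochberg FDR over
the 65-metric family of each contrast.

Demographic tables use one-way ANOVA with LSD post-hoc comparisons
(pairwise t tests on the pooled error term, uncorrected — that is what LSD
means) and chi-squared tests without Yates continuity correction by default
(configurable for 2×2). Metric–behavior correlations are partial Pearson
correlations: both variables residualized on the covariates, with a t test
on n − k − 2 degrees of freedom; the no-covariate case reduces to plain
Pearson r. Heterogeneity screens use two-sided Wilcoxon rank-sum tests on
sex (female/male) and age strata (closed ranges 18–37 vs 38–65), with exact
enumeration when both strata have n ≤ 10 and no ties, and the tie-corrected
normal approximation otherwise; results are reported as log10(p) against
the conventional −1.301 line.

## Network-based statistic (NBS)

Edge-wise statistics are the t of the group indicator in an OLS of each
upper-triangle edge on group + covariates, vectorized as a single
normal-equations solve shared across all ~25k edges (this is what makes
hundreds of permutations per contrast affordable on one CPU). Edges with
zero residual variance are flagged degenerate with statistic 0. Positive
statistic means first-group mean above second-group mean.

Suprathreshold edges (|t| at or beyond the primary threshold) are grouped
into connected components; family-wise error is controlled by comparing
each component's extent (edge count) with the permutation distribution of
the maximal null extent: p = (1 + #{null ≥ observed}) / (1 + n_perm).
Positive and negative directions are tested separately and
Bonferroni-corrected by the number of directions (the family size is a
parameter, because the convention is ambiguous). The default primary
threshold is the two-sided p = 0.001 critical t at the model's residual
degrees of freedom; it is always recorded in the result. Permutations
exchange group labels by default (covariates stay with their subjects),
with a Freedman–Lane residual-permutation option and an optional
within-stratum restriction (e.g. within site). Component extent only; the
intensity variant is not implemented.

At stringent primary thresholds on small graphs the null max-extent
distribution is nearly all mass at zero, which makes the test conservative
(empirical family-wise error well below nominal). The calibration
experiment in the acceptance suite therefore sets the edge-forming
threshold to the two-sided p = 0.05 critical t, where the null distribution
has spread; the measured family-wise error at α = 0.05 is then close to
nominal (and still conservative, as expected from discreteness plus the
direction correction).

Conjunction is implemented two ways: strict intersection across all input
edge sets, and the pairwise-overlap reading (edges flagged by at least two
contrasts), which matches "common connections between arbitrary two
groups". The demo uses the pairwise overlap, because planted (and
reported) effects reverse direction at the severe end of the gradient,
making the all-way intersection empty by construction; if no edge overlaps
the demo falls back to the union of flagged edges and records which source
was used.

## Classification

Binary linear soft-margin SVM over connectivity features, in three contrast
families along the gradient: each MDD subgroup vs HC (5), each suicidal
subgroup vs MDDNSI (4), and all pairs among the four suicidal subgroups
(6) — 15 contrasts. Features are either one column per edge or FCI
composites (selected edges grouped by the network block they span, one
mean-FC feature per block; the demo uses FCI mode).

Protocol per contrast: 10 stratified 80/20 train/test splits; within each
training set, features are standardized with training statistics only and C
is chosen by stratified cross-validation over a log grid
{0.01, 0.1, 1, 10, 100}; accuracy, sensitivity, specificity, and AUC (from
decision values) are measured on the held-out test set and aggregated as
mean ± SD. The split ratio is a design choice (conventional companion to
10-fold inner CV) and is recorded in the report. The permutation test
shuffles labels *before the entire split/CV procedure* — the conservative
reading — and compares permuted mean accuracies with the observed one.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test. Each
subject's time series are drawn from a hierarchical factor model: node i in
network k is

    x_i = sqrt(lam_k) * f_k + sqrt(1 - lam_k) * e_i,
    f_k = phi_k * g + sqrt(1 - phi_k^2) * h_k,

with a global factor g, network factors h_k, and node noise e_i, all
standard normal. The implied correlation matrix is exactly block-constant —
within-network r = lam_k ("cohesion"), between-network
r = sqrt(lam_a lam_b) phi_a phi_b ("coupling") — and is positive definite by
construction for any lam in [0, 1), phi in [−1, 1]. An earlier additive
block-shift parameterization was abandoned because the planted
one-versus-others deficits produce strongly indefinite matrices (a network
cannot coherently anticorrelate with everything at once); the factor form
makes that geometric constraint explicit instead of silently repairing it,
and no spectral clipping is ever applied.

Defaults (the study conditions): 226 nodes, T = 200 timepoints, four sites
with ±0.005–0.01 additive shifts on cohesion and coupling, group sizes
50/30/30/25/20/15 (HC→MDDSB; a scaled-down multi-site cohort), female
fraction 0.6, ages uniform 18–65, mean FD 0.04 + Exp(0.035) truncated at
0.5 (so a few percent of subjects exceed the 0.2 mm QC cut). Baseline
cohesion places three clearly cohesive networks (CON .45, VIS .42,
SMN .40), four clearly incohesive (DAN .14, VAN .13, FPN .12, DMN .11), and
the three *affected* networks straddling the median (AUD .24, SUB .23,
SAN .22); the coupling profile does the same on the OVO axis (strong:
CON/SMN/VIS; weak: DAN/VAN/FPN/DMN; middle: the affected trio).

The planted gradient: per affected network, cohesion follows an inverted-U
along HC→MDDSB (rising to a peak at moderate ideation, dipping below
baseline at suicidal behavior; amplitudes 0.07–0.14), while coupling
follows a U whose trough sits at moderate ideation for AUD/SAN but at
severe ideation for SUB. Amplitudes were chosen so that (a) every
successive group-mean difference is at least ~3 standard errors of the
group-mean summaries at the default sample sizes (per-subject SD ≈ 0.022
for WNC, ≈ 0.013 for OVO at T = 200), so the sign pattern of the curves is
recoverable; and (b) the affected trio reorders *among itself* around the
median role cut while staying clear of the unaffected bands — because a
median split conserves the number of networks on each side, role flips are
paired rank crossings, and confining the crossings to the trio is the only
way to make exactly the affected networks divergent and the other seven
stable. The exact planted group-level WNC/OVO trajectories are computed
from the target correlation matrices (site-averaged) and stored in the
ground truth, which suffices to re-derive every planted effect (a closure
property the tests assert).

Clinical scores are generated from each subject's *realized* connectivity:
the FCI over the planted (within-trio) edges is z-scored across the cohort
and enters each HAMD subfactor linearly (defaults: anxiety −1.5, weight
+0.6, retardation and sleep 0) on top of group baselines, with noise and
integer clipping to plausible ranges; HAMD total rises with the suicide
item through the group baselines. Reproducibility: one global seed; each
subject uses a substream keyed by (seed, group index, subject index), so a
subject's data do not change when other groups are resized.

What the generator does *not* emulate: hemodynamic autocorrelation and
filtering, node-level heterogeneity within blocks (a single r per block),
motion artifacts beyond the FD covariate, non-Gaussian tails, and
site-by-group interactions. Passing tests therefore demonstrate that the
pipeline recovers the planted block-level structure under Gaussian
stationary noise — not that the real-data effect sizes or the specific
reported edge sets would be reproduced.

## Pipeline and problem sizes

The demo runs simulate → QC → connectomes → summaries → roles → 65-metric
tests (omnibus + five HC-vs-subgroup contrasts, FDR within each) →
metric–behavior partial correlations (pooled MDD) → NBS per HC-vs-subgroup
contrast → conjunction (pairwise overlap) → FCI features → 15 SVM
contrasts → sex/age heterogeneity screens, writing plain-text outputs and a
manifest with SHA-256 digests of every file. Scaled-down counts used by the
demo, chosen to keep a full run in a few minutes on one CPU and recorded in
every output: 200 NBS permutations per contrast, 10 SVM splits with 5-fold
inner CV over C ∈ {0.1, 1, 10}, and 50 label permutations per contrast.
The acceptance experiments use 200 null datasets (20 nodes, 15 vs 15) for
NBS calibration, 20 replicates (30 nodes, 30 vs 30, 1000 permutations) for
NBS recovery, 20 cohort seeds for trajectory recovery, and 200 label
permutations for the classifier-sanity check.

## Numerical choices and degenerate inputs

- Constant time series: correlation undefined → error naming the node.
- |r| = 1 off-diagonal under Fisher z → error (infinite z).
- Singleton network → WNC undefined → error, never silent NaN.
- Degenerate edges (zero residual variance relative to the edge's own
  scale) → statistic 0.
- Matrix files: symmetrized on read only when asymmetry < 1e−8; larger
  asymmetry is an error.
- Node indexing: 1-based in all files, 0-based in memory.
- Permutation p-values use the add-one convention, so they are never below
  1/(n_perm + 1).
- Role ties (value exactly at the cut) resolve to cohesive/connector.

## Known limitations

- The one-factor-per-network covariance cannot express "incohesive
  connector" extremes (very low within-network coherence combined with very
  high coupling everywhere); baseline roles are arranged within what the
  geometry allows.
- NBS component p-values are conservative at stringent primary thresholds
  on small graphs (discreteness of the null max extent).
- LSD post-hoc p-values are intentionally uncorrected.
- The classifier's permutation test at the demo's 50 permutations has a
  p floor of 1/51; use more permutations for publication-grade inference.
- Replication on a second subject table is a re-run of the same pipeline,
  not a distinct method.
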