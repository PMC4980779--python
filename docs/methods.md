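# Methods

`flowpops` implements a two-stage clustering method for automated gating of
flow cytometry data, and a cohort-level extension that flags subjects whose
overall cellular profile is anomalous. This note records the model, the
numerical choices, the defaults and the known limitations.

## Single-sample cell-type identification

### Stage 0 — how many clusters to start from

The number of cell populations is unknown a priori, so an upper-ish bound K
is estimated first. The sample covariance matrix of the (column-centered)
cell × marker matrix is diagonalised and the cells are projected onto each
eigenvector. On every 1-D projection `e` a Gaussian kernel density estimate

    f(l)  = (1 / (N h)) Σ_i κ((l − e_i)/h),     κ = standard normal pdf

is formed with the Scott-type bandwidth `h = (7/2) σ* N^(−1/3)` (σ* = sample
standard deviation of the projection). Modes are counted as statistically
significant sign changes (+ → −) of the analytic gradient

    f'(l) = −(1 / (N h³)) Σ_i (l − e_i) κ((l − e_i)/h)

evaluated on a 512-point grid spanning the projection range ± 3h. At each
grid point the gradient is the mean over cells of a per-cell summand, so its
plug-in standard error is the sample standard deviation of the summands
divided by √N; a point is significant when |gradient|/SE exceeds the
two-sided Bonferroni normal quantile z(1 − α/(2·512)), α = 0.05 by default
(a SiZer-style simultaneous test). K is the sum of the per-eigenvector mode
counts, floored at 1.

Deliberate properties and caveats:

* A population that projects onto several eigenvectors is counted once per
  axis, so K over-estimates the number of populations — the merge stage
  removes the excess. K can also *under*-count: Scott's rule is calibrated
  for unimodal data, and on a projection containing many separated groups the
  bandwidth is inflated by the between-group variance, so at a few thousand
  cells roughly four groups per axis is the practical resolution limit.
  Because `h ∝ σ*`, this limit is scale-free: spreading the groups farther
  apart does not help, only more cells do.
* Only the gradient test is performed. A curvature-based (second-derivative)
  test could sharpen shallow shoulders but there is no standard plug-in
  decision rule; it is left out.
* Eigenvector sign is arbitrary and irrelevant: mode counts are invariant to
  flipping, shifting and positive rescaling of a projection.

### Stage 1 — fuzzy C-means with Mahalanobis distances

Cells are soft-assigned to the K initial clusters by minimising the fuzzy
objective

    J_m = Σ_i Σ_j u_ij^m D(x_i, μ_j)²,    Σ_j u_ij = 1,

with fuzzifier m = 2 and the standard alternating updates

    μ_j ← Σ_i u_ij^m x_i / Σ_i u_ij^m
    u_ij ← 1 / Σ_k (D_ij / D_ik)^(2/(m−1)).

D is by default the per-cluster Mahalanobis distance; each cluster's
covariance S_j is re-estimated every iteration as the u^m-weighted scatter
about μ_j, then regularised with a ridge ε·I, ε = 10⁻⁶·trace(S)/M (and the
off-diagonal zeroed when the effective weight count is ≤ M). The
regularisation is what keeps the distance defined for small or
lower-dimensional populations — the failure mode that breaks
covariance-based merging in comparable gating tools when a rare population
has fewer cells than markers. A plain Euclidean mode is available and is the
cross-check against an independently coded reference FCM in the tests.

Numerical conventions: centers are initialised by k-means++ seeding with an
explicit seed; iteration stops when the largest membership change falls
below 10⁻⁵ or after 100 iterations; a cell at zero distance from one or more
centers splits its membership equally among exactly those centers; an
emptied cluster is reseeded at the cell farthest from all current centers.
Crisp labels, when needed, are argmax memberships with ties to the lowest
cluster index.

### Stage 2 — merging redundant clusters with Markov clustering

K deliberately over-counts, so several fuzzy clusters may cover one true
population. A Gaussian similarity graph is built over the K cluster centers,

    A_ij = exp(−‖μ_i − μ_j‖² / (2σ²)),  A_ii = 1,

and Markov clustering (MCL) is run on it: column-normalise A, then repeat
"expand" (matrix power, default 2) and "inflate" (element-wise power,
default 2, followed by column renormalisation), zeroing entries below 10⁻⁸,
until the matrix stabilises (max-abs change < 10⁻⁶, cap 100 iterations).
Attractors are rows with positive diagonal mass; every node joins the
attractor receiving most of its flow, and attractors sharing support are
unioned. Centers in the same segment become one final population.

The length-scale σ is the load-bearing choice. It is taken from the fitted
clusters themselves: σ = 3 × the typical within-cluster standard deviation
(median over clusters of √(trace(S_j)/M)). Redundant centers of one
population sit within a couple of within-cluster standard deviations of each
other and end up near-fully connected; distinct populations several
standard deviations apart are effectively disconnected. Purely relative
rules (a fraction of the median pairwise center distance) cannot make this
distinction — they are invariant to the data scale, so they give the same
merge decision for two half-clusters of one blob as for two genuinely
separate populations. The factor 3 sits in the middle of a plateau
(roughly 2.5–4) over which the merge results on the synthetic studies are
unchanged; below it, "bridge" centers (a Mahalanobis-FCM artifact sitting
between two populations, ~4 standard deviations from each) fail to merge.

### Evaluation

Clusterings are scored against reference labels with the class-size-weighted
best-match F-measure

    F(L, L') = (1/N) Σ_i |l_i| · max_j F1(l_i, l'_j),

precision = n_ij/|l'_j|, recall = n_ij/|l_i|. It is 1 exactly for any
relabeling of the reference and penalises both split classes and mixed
clusters. Reference cells marked unassigned can be excluded before scoring.

## Cohort anomaly detection

All subjects' cells are pooled (optionally subsampled per subject) and the
two-stage pipeline is run once on the pool. Each subject is then one row of
a feature table with, per final population: the median fluorescence
intensity (MFI) of the subject's own cells in that population for every
marker, plus the percentage of the subject's cells in it — L =
n_populations × (M + 1) features. A subject with no cells in a population
gets 0% and that population's pooled MFI (absence is expressed only through
the percentage feature). Columns are z-scored before any distances are
taken, since MFIs and percentages live on different scales.

On the standardized P × L table a modified density-peak statistic is
computed per subject:

    ρ_i = ω / Σ_{j ∈ ω-NN(i)} ‖s_i − s_j‖²,   ω = round(r·P), r = 0.15
    δ_i = mean distance to the γ nearest subjects with ρ_j > ρ_i,
          γ = max(1, ⌊P/100⌋)

with δ of the global density maximum set to its distance to the farthest
subject. At γ = 1 this is exactly the classical density-peak δ (distance to
the nearest denser point); γ > 1 averages over the γ nearest denser
neighbours, matching the assumption that anomalous subjects come in groups
of at most ⌊P/100⌋ (the rarity threshold). ρ uses population conventions
throughout; duplicated subjects (zero distance) receive a sentinel density
of 10× the largest finite one. The paper-level default r = 0.15 is
deliberately uncritical: the flagged set is unchanged over r ∈ [0.10, 0.20]
on the default study.

Anomalies combine low ρ with high δ, so their ratio δ/ρ is extreme. The
flagging rule is the classic chi-square outlier test applied once against
the full ratio list: subject i is flagged when (x_i − mean)²/var exceeds
the χ²(1) quantile at 1 − α (α = 0.05), with mean and population variance
(ddof = 0) over all P ratios and only the upper tail eligible. Keeping the
reference moments fixed is intentional: one extreme ratio inflates the
variance and masks merely-large values, so flagging does not cascade down
the sorted list. An iterated variant that re-estimates the moments after
each removal was evaluated and rejected — after the true outliers are
removed the variance collapses and the maximum of the remaining
right-skewed list is rejected again, flagging a dozen or more healthy
subjects per cohort.

Known limitation: at α = 0.05 the test is liberal on small cohorts with *no*
true anomalies — the maximum of ~50 skewed ratios typically exceeds the
uncorrected threshold, so one to a few fringe subjects are flagged. The
flagged list should be read as a screening shortlist, with the sorted δ/ρ
plot (and the decision graph) as the confirmatory view; a genuinely
anomalous subject separates from the fringe by an order of magnitude in
ratio, not by a few percent.

## Synthetic study conditions

The generators define the default conditions all seeded tests run under.

* **Seven-population sample** (single-subject gating demonstration): seven
  unit-covariance 2-D Gaussians, equal weights, 300 cells each (N = 2100),
  centers on a 10-unit grid at cells (0,1),(1,0),(1,1),(1,2),(1,3),(2,0),
  (2,2) — pairwise separation ≥ 10 standard deviations, so ground truth is
  unambiguous. The layout was chosen so that the eigen-projection mode
  counts genuinely sum to 7; many equally well-separated layouts sum to 5–6
  because of the bandwidth ceiling discussed above, which is a property of
  the K-estimator worth keeping visible rather than hiding.
* **Cohort** (anomaly-detection demonstration): 150 subjects, 200 cells
  each, 5 markers, 3 template populations (unit covariance, weights
  0.5/0.3/0.2, means ≥ 10 apart). Every subject's population means are
  jittered with sd 0.3 (subject-level biological variation); 2 anomalous
  subjects additionally have the means of markers 3–4 in population 1
  shifted by +4 pooled within-population standard deviations, emulating a
  disease-typical marker shift against healthy donors. Optionally the
  anomalous population fraction can be changed instead of (or besides) the
  MFI shift.

What the generators do *not* emulate: spectral spillover between channels,
debris and doublets, heavy-tailed or skewed population shapes, rare
populations below the percent level, and instrument drift. Passing the
seeded studies therefore demonstrates the mechanics of the method under its
own assumptions (well-separated, roughly Gaussian populations), not
performance on raw clinical files; real data should at minimum be
compensated upstream and possibly arcsinh-transformed (`--arcsinh-cofactor`)
before clustering.

## Problem sizes and runtime

The default studies are desk-scale by design: a single-sample run (2100
cells) takes ~2 s and a full cohort run (30,000 pooled cells, 150 subjects)
~8 s on one CPU core, so the 20-seed acceptance studies finish in a few
minutes. The dominant costs are the KDE significance sweep (O(N·G) per
eigenvector) and the per-iteration Mahalanobis distances (O(N·K·M²)); both
are chunked to keep memory flat, and cohorts of hundreds of subjects with a
per-subject cap are well within reach.
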