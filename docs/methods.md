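# Methods

## Rich-club measurement

The degree of a node is its number of binary edges. For each degree
level k from 1 to the maximum degree, the rich-club coefficient φ(k) is
the density of the subgraph spanned by nodes of degree *strictly greater
than* k: φ(k) = 2·E₍>k₎ / (N₍>k₎·(N₍>k₎−1)). The strict inequality
follows the subscript notation E₍>k₎, N₍>k₎; φ(k) is undefined (stored
as NaN, never 0) when fewer than two nodes qualify, and undefined values
are excluded from all downstream averages and tests.

Normalization divides φ(k) by the mean φ(k) of an ensemble of
degree-preserving randomized graphs. Randomization is by double edge
swaps: pick edges (a,b), (c,d), replace with (a,d), (c,b) when no
self-loop or duplicate arises. The swap preserves every node's degree,
so the set of defined k levels is identical across the ensemble. The
default ensemble is 1000 graphs with 10 successful swaps per edge and an
attempt cap of 100 attempts per edge (a warning is logged if the cap
bites, as it does for graphs near-complete in edges, where few legal
swaps exist); test configurations use 100 nulls, which changes φ_norm
estimates by well under the group-level effect sizes probed. φ_norm is
undefined where φ is undefined or the null mean is zero.

Rich nodes are the ⌊0.15·N⌋ nodes with the highest mean binarized degree
(per subject the mean over the sparsity sweep, then averaged over all
subjects; ties break toward the lower node index). For N = 116 this is
17 nodes. Edges are classed *rich* (both endpoints rich), *feeder* (one),
or *local* (neither). Nodal efficiency is the mean inverse unweighted
shortest-path length to all other nodes; unreachable pairs contribute
zero, so isolated nodes have efficiency 0. Connectedness is not enforced
at low sparsity — this zero-contribution convention absorbs disconnected
components.

A subject "has the rich-club effect" when φ_norm > 1 at every defined k
in a window, default k = 2–8: the low-degree range where group
differences concentrate.

## Connectome construction

Input is a parcels × time matrix (default 116 AAL parcels, 240 samples,
TR 2 s). Preprocessing discards the first 10 volumes, removes each
row's linear trend, and applies a fourth-order zero-phase Butterworth
band-pass (`sosfiltfilt`, 0.01–0.08 Hz). Note the Butterworth passband
gain is 1 only at its unity-gain frequency, so re-filtering already
filtered data is *nearly* but not exactly idempotent (interior energy
ratio ≈ 0.83 for broadband in-band noise); zero-phase filtering keeps
cross-parcel correlations unbiased.

Connectivity is the Pearson correlation of every parcel pair, with the
Fisher transform z = arctanh(r) used for all parametric statistics
(variance stabilization). |r| is clipped to 1−10⁻¹⁵ before arctanh so
degenerate inputs stay finite. Binarization keeps the m = round(s·M)
strongest pairs at each sparsity s (M = N(N−1)/2), ranking by *signed* r
— strong negative correlations never enter the graph, the dominant
convention for binarized FC metrics; `rank_by="abs"` is available. Ties
break by (higher r, then lower lexicographic pair index), making the
cut deterministic across platforms. All thresholds cut one shared
ranking, so graphs are nested across the sweep. The default sweep is
s = 0.05 to 0.5 in steps of 0.01 (46 graphs).

## Group statistics

Per edge (Fisher-z scale): a one-way three-group ANOVA acts as a gate at
α = 0.05; gated edges get pooled-variance two-sample t tests of each
patient group against controls (Welch available), with
Benjamini–Hochberg FDR at q = 0.05 applied per contrast across that
contrast's tested edges. Edges with zero within-group variance are
skipped and logged. The same scheme runs per degree level on
subject-wise φ_norm summary curves (each subject's mean across the
sweep), skipping k levels with fewer than two defined subjects in any
group; the reported "significant window" is the contiguous run of
significant k containing the smallest significant k. Aberrant-node
ranking counts significantly *decreased* edges incident to each node per
contrast and reports the top two nodes with their efficiency ANOVA.
Behavioral and radiomic association tables are Pearson correlations with
two-sided p, reported uncorrected and BH-adjusted.

Segmentation reliability uses the two-way random-effects,
absolute-agreement, single-measure ICC(2,1) computed from the two-way
ANOVA mean squares; values above 0.75 are flagged reliable. The
absolute-agreement form penalizes systematic rater offsets, unlike
consistency ICCs.

## Synthetic cohort

The generator emulates the data *structure* of a three-group stroke
cohort (controls n=21, hemorrhagic n=16, infarct n=21; 116 parcels × 240
samples at TR 2 s), not its physiology. Ground truth is a banded weight
matrix: core–core pairs w_core = 0.85 among the first 17 nodes,
core–periphery w_feeder = 0.35, periphery–periphery w_local = 0.35, each
plus uniform jitter of ±10% of the smallest band gap (to break degree
ties). Patient groups multiply the feeder and local bands by attenuation
factors δ_feeder, δ_local (default 0.7 each, with a per-subject uniform
jitter of half-width 0.1) *before* sampling, so the planted effect is a
true distributional group difference.

Series are drawn as correlated Gaussians (Cholesky factor of the weight
matrix plus identity) and band-passed to the analysis band; applying one
linear filter to every parcel leaves cross-parcel correlations intact
while matching the temporal band of real preprocessed data. Positive
definiteness is guaranteed by diagonal loading — the smallest
λ ∈ {10⁻⁶·2ʲ} that makes *every subject's* covariance in the cohort
admit a Cholesky factorization, applied *identically to all subjects*.
A per-subject loading would scale patient and control correlations
differently and plant a spurious global group effect on nominally
unattenuated edges; the shared loading keeps those edges exactly
exchangeable across groups. The band defaults satisfy
w_feeder² ≤ w_core·w_local·δ_min (a rank-one factor bound), so
small-cohort configurations need no loading at all; at N = 116 the
prescribed weight jitter alone makes the matrix indefinite
(random-matrix spectral radius ≈ 0.3) and a shared loading ≈ 0.26
uniformly rescales all correlations — group-neutral by construction.

Behavior: MMSE/MoCA = group baseline (Table-style means 29.33/29.10 for
controls, 20.69/16.62 hemorrhagic, 18.57/15.48 infarct) −
β·(subject attenuation) + Gaussian noise (β = 8 score points per unit
attenuation, noise SD 1), clipped to [0, 30]. Patients get an
ellipsoidal lesion in a 40³ grid of 3 mm voxels whose radii and signal
intensity grow with the subject's attenuation (infarct lesions drawn
larger than hemorrhagic, echoing the emulated population); controls get
none. Everything derives from one seed via independent per-subject
substreams, so identical specs reproduce the cohort bit for bit.

The planted-core *benchmark graph* (`planted_core_graph`) is a separate,
purely graph-level object: 116 nodes at density 0.10 with the 17-node
core wired pairwise at probability 0.9, a feeder share (18% of the
remaining budget) from the core to the best-connected periphery, and the
rest a periphery chain lattice whose branch count decays geometrically
along the node rank. The chain gives a long low-degree tail whose edges
join other low-degree nodes; a degree-preserving null reallocates those
edges toward hubs, so φ_norm exceeds 1 at low k — the same low-degree
enrichment seen in empirical connectomes. A dense core alone does not
produce this (hubs stay hubs under rewiring, so φ_norm ≈ 1 at low k);
product-weight ("configuration-style") peripheries cannot either, since
degree-preserving nulls reproduce them exactly. With the default
construction the minimum φ_norm over k = 2–8 is ≈ 1.03, rising to ≈ 1.2
by k ≈ 12.

### What the generator does and does not emulate

It reproduces: the cohort layout, a controllable core/periphery
correlation structure, group attenuation confined to feeder/local bands,
behavior and lesion couplings with known sign, and realistic estimation
noise (band-limited series shorten the effective sample, inflating the
variance of r̂ by ≈ 1/bandwidth-fraction). It does not simulate
hemodynamics, head motion, scanner drift, spatial (voxel-level) data,
negative correlations, or non-Gaussian BOLD features. Passing tests
therefore demonstrate that the *pipeline* recovers planted effects of
realistic size under realistic estimation noise — not that any clinical
finding replicates.

## Numerical and design choices

- Round-half-up edge counts at thresholding; endpoint of the sparsity
  grid included within 1e-9.
- Undefined φ/φ_norm as NaN everywhere; no silent zero-filling.
- Rewiring seeds: one seed spawns independent child streams per null
  graph (`numpy` SeedSequence), so ensembles are reproducible and
  order-independent.
- First-order radiomics use the population (divide-by-n) variance and
  moment conventions, excess kurtosis, base-2 histogram entropy with a
  fixed bin width (default 0.1 intensity units); skewness/kurtosis of a
  constant region are defined as 0.
- Surface area counts exposed voxel faces. For smooth shapes this
  converges to ~3/2 the true area (a digitized ball's exposed-face area
  does not approach the sphere area), so sphericity plateaus near 2/3
  for balls instead of approaching 1: sphericity is *comparative across
  lesions*, not an absolute physical shape index. Maximum 3D diameter is
  computed over boundary voxels only (the extremes lie on the boundary;
  a convex hull prunes large boundaries first). Elongation and flatness
  are √(λ₂/λ₁) and √(λ₃/λ₁) of the voxel-scatter eigenvalues, defined
  as 1 when the leading eigenvalue vanishes (single voxel).
- Pipeline determinism: the report JSON is written with sorted keys and
  10-decimal rounding; every number traces to a TSV table stamped with
  the config hash.

## Problem sizes in tests

The default analysis configuration (116 nodes, 46 sparsity levels,
1000 nulls) is the scientific default; the test suite and the shipped
`test_profile` exercise the identical code paths at reduced sizes chosen
to keep runs in minutes: 40-node cohorts, five sparsity levels,
100-graph ensembles, 15–21 node cohorts with 20 replicates for the
error-control and recovery studies. Effect-size calibration at those
sizes (planted δ_local = 0.5 against w_local = 0.35) yields edgewise
sensitivity ≈ 0.87 with rich-edge false positives ≈ 0.02.

## Known limitations

- Statistical tests assume approximate normality of Fisher-z values and
  independent subjects; edge tests within a cohort share subjects, so
  family-level rejection *rates* fluctuate more than binomial.
- The curvewise φ_norm group test is low-powered at small cohort sizes;
  the reduced demo run often reports no significant k window even when
  edgewise effects are clear.
- No covariate adjustment (age, education, lesion side) is applied
  before group tests, and no network-based-statistic or permutation
  correction is implemented — FDR across edges is the only multiplicity
  control.
- Weighted rich-club variants, directed graphs, and structural (DTI)
  connectomes are out of scope.
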