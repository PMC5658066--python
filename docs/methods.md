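# Methods

This note records how `emsynapse` defines its objects, the conventions that
the printed formulas leave open, and the reasoning behind the defaults. It
is the companion to the API documentation: everything below is implemented
and exercised by the test suite.

## Interfaces and subvolumes

A volume segmentation with one-voxel boundaries (label 0) is the input
substrate. For every unordered pair of segment ids, the boundary voxels
whose 26-neighborhood contains both ids are collected; 26-connected
components of that set are the candidate interfaces. Components of 150
voxels or fewer are discarded (`min_border_voxels = 151`). The cutoff is
applied literally as "≤ 150 discarded"; the connectivity used both for the
neighborhood test and for component splitting is 26 — the component rule is
not fully pinned down by the description we follow, and 26 is the only
choice consistent with the neighborhood rule.

Shell subvolumes use the exact anisotropic Euclidean distance between voxel
centers, in nm: `shell(S, d)` is every voxel of segment S whose center lies
within `d ∈ {40, 80, 160}` nm of some border-voxel center. Distance is
computed with a Euclidean distance transform seeded at the border voxels
(`scipy.ndimage.distance_transform_edt` with the physical sampling),
restricted to a local bounding box padded by the maximal shell distance.
Euclidean-in-nm is the only scale-consistent metric given voxels of
11.24 × 11.24 × 28 nm. Shells are nested by construction and never contain
border voxels (those carry label 0).

Interfaces are stored undirected with `id1 < id2`; direction exists only in
feature vectors and scores. The centroid is the arithmetic mean of border
voxel centers in nm and is what the clustering stages operate on.

## Filter bank

All Gaussian scales derive from a base scale `s = (12/11.24, 12/11.24,
12/28)` voxels so the physical standard deviation is 12 nm in every axis.
Kernel half-size per dimension follows `f_d = round((σ_d/s_d)·ceil(2·s_d))`,
i.e. ~3σ in-plane and 1 voxel in z at base scale. The rounding in this rule
is genuinely ambiguous; our reading is fixed, documented here, and
configurable through `FilterBankConfig`.

The plain Gaussian is evaluated on the integer grid `[-f, f]³` and
sum-normalized (DC gain exactly 1). Derivative kernels are the analytic
derivatives of that normalized Gaussian and are **not** re-normalized. A
consequence worth stating explicitly: at base scale the z half-size is 1
while σ_z ≈ 0.43 voxels, so the truncated second-derivative kernel in z does
not sum to zero. Laplacian-of-Gaussian and Hessian maps therefore respond to
a *constant* volume with a constant offset rather than zero. Families whose
kernels have exact vanishing moments — DoG (two unit-DC Gaussians),
gradient (odd kernels), structure tensor, local standard deviation, local
entropy — are exactly zero on constants. The tests assert precisely this
behavior. Re-normalizing the derivative kernels would remove the offset but
would no longer be the stated construction; boosted stumps are insensitive
to per-feature offsets, so we keep the faithful kernels.

Structure tensor: `S_ab = (I_a^{σ_D} · I_b^{σ_D}) * g_{σ_w}` with the five
`(σ_w, σ_D)` multiplier pairs (1,1), (1,2), (2,1), (2,2), (3,3). Hessian:
`H_ab = I_ab^σ` for σ multipliers 1–4. Eigenvalues are sorted by increasing
absolute value, ties broken by signed value ascending, for determinism.

Window filters: local standard deviation is the unbiased sample standard
deviation over 5×5×5. The intensity/variance feature is implemented
verbatim as `Σ_U I² − (Σ_U I)²` for U ∈ {3³, 5³} — the expression lacks the
1/|U| normalization of a true variance and is kept as printed (float64
arithmetic; the magnitude reaches ~10⁹ for 8-bit input). Local entropy uses
the 256-level histogram over 5×5×5 in bits. Sphere averages use the
anisotropy-corrected lattice ball `x² + y² + (2z)² ≤ r²`, r ∈ {3, 6}.

Map order (51): raw, 15 structure-tensor eigenvalue maps, 12 Hessian
eigenvalue maps, 3 smoothings, 5 DoG, 4 LoG, 5 gradient magnitudes, local
std, 2 int/var, entropy, 2 sphere averages. Volume borders are
replicate-padded; tiling (`make_tiles`, reference tile 548×548×268 with
72/72/24 overlap) guarantees per-tile filtering equals untiled filtering on
tile cores whenever the overlap covers the kernel reach, which
`FilterBankConfig.max_reach_voxels()` computes from the configuration
instead of trusting fixed numbers.

## Feature aggregation and direction

Nine statistics per (map, subvolume): quartiles 0.25/0.5/0.75, min, max,
mean, variance, skewness, kurtosis, in that order. Conventions (the names
alone do not pin these down): quantiles interpolate linearly between order
statistics; variance is unbiased (n−1); skewness and kurtosis are biased
standardized central moments with kurtosis non-excess (3 for a Gaussian);
constant samples get skewness = kurtosis = 0; an empty subvolume
contributes zeros for all nine values so the vector length is invariant
(logged when it happens).

Shape features (11): voxel counts of border and the two 160 nm clouds; the
border's sphere-equivalent diameter `2·(3n/4π)^{1/3}` in voxel units; the
three eigenvalues of the covariance of border voxel centers (nm,
descending); the absolute scalar product of the first principal components
of the two 160 nm clouds; convex-hull voxel counts of the three clouds.
The axis product is reported as an absolute value because eigenvector signs
are arbitrary; whether the original quantity was signed is unknowable from
its description, and the absolute value is the sign-deterministic choice.
Hull membership counts voxel centers strictly inside or on the hull
(tolerance 1e-9); the counting is done per (x, y) lattice column as a z
interval, which is exact and fast, and degenerate clouds (< 4 distinct
points, collinear or coplanar) fall back to the number of distinct member
voxels — consistent with the convention that a point set trivially contains
itself. Principal axes of clouds with fewer than two points are zero.

The directed vector is texture block (index `(map·7 + subvolume)·9 + stat`,
subvolume order: border, S1@40, S2@40, S1@80, S2@80, S1@160, S2@160)
followed by the 11 shape values. Direction reversal is a fixed involutive
permutation of all 3224 indices: S1/S2 subvolume blocks swap per distance,
the two 160 nm voxel counts and hull counts swap, and border-derived
entries stay put.

## Classifier

Binary LogitBoost (Friedman–Hastie–Tibshirani) over regression stumps.
Per round: probabilities `p = σ(2F)` clamped to [1e-10, 1−1e-10], weights
`w = w₀·p(1−p)` floored at 1e-12, working responses `z = (y−p)/(p(1−p))`
clamped at ±4, a weighted least-squares stump fitted over all features
(threshold candidates are midpoints between distinct consecutive sorted
values; ties go to the left branch), the Newton half-step folded into the
stored responses (also clamped at ±4), and `F ← F + 0.1·f`. The
misclassification cost of 100 for the synaptic class enters as a
multiplicative prior weight `w₀` on synaptic observations, renormalized to
sum 1 — under boosting's weighted-loss view this is what a class cost does;
a literal cost matrix is not expressible in LogitBoost's Newton step.
Everything is deterministic; no subsampling exists, so the stored seed only
documents provenance. AdaBoost.M1 with classification stumps is available
as `algorithm="adaboostm1"` for ablation but is not the default.

Feature importance accumulates each stump's weighted-SSE split gain on its
feature; unused features have importance 0.

Direction is resolved by the larger of the two directed scores (`max` rule,
ties toward forward); undirected validation instead uses the logical-OR
rule (detected iff either directed score exceeds θ). Both rules are
implemented and named (`classify_interface` vs `validate_undirected`)
because the two descriptions of validation differ; the max rule is what the
pipeline uses for detection and direction, the OR rule for undirected
precision/recall bookkeeping. Default score thresholds θ_s = −1.67 (exc) /
−2.06 (inh) and θ_nn = −0.08 (exc) / −1.58 (inh) are carried as overridable
constants; they are meaningful only for a classifier trained on comparable
labels.

## Evaluation

A ground-truth synapse is detected if at least one interface overlapping it
is detected; it is missed if none is; a detected interface overlapping no
synapse is one false positive. Multiple detected interfaces on one synapse
count once as TP; FP de-duplication beyond the per-interface rule is not
applied. Interfaces with centroids within 160 nm of the evaluation-volume
faces can be excluded (configurable margin) so that no evaluated interface
has clipped subvolumes. PR curves sweep θ over the max-direction score;
with no detections precision is reported as 1 with a flag.

## Connectomes and areas

Within each (pre, post) process pair, detected interfaces are merged by
single-linkage clustering of centroids with a distance cutoff — exactly the
connected components of the ≤cutoff graph. One implementation serves both
defaults: 1500 nm when building connectomes (concatenating multi-interface
synapses) and 320.12 nm when counting synapses volume-wide. Binarization
thresholds the per-pair count at γ_nn, optionally per presynaptic type
(1 excitatory, 2 inhibitory).

Interface area: the reference this pipeline descends from delegates area
computation to an external codebase without formulas, so the package defines
it as the face-count surface — for each border voxel, the voxel faces shared
with either adjacent segment, each weighted by its physical face area, and
the two one-sided surfaces averaged. On a flat axis-aligned interface this
is exactly face area × face count; the analytic-plane test requires 5%
agreement. ASI (axon–spine interface) area of a synapse is the sum of its
member interface areas; the contactome sums areas over *all* interfaces per
process pair, synaptic or not.

The analytic error model is implemented exactly as stated in the README;
`scipy.stats.binom/poisson` survival functions provide exact tails. The
excitatory `p(n)` table is user-supplied (`ConnectivityModel.excitatory`),
because the per-study empirical distribution is not part of this package's
inputs; only its mean (4.3) and the inhibitory point mass at 6 are wired in
as defaults, together with connectivity rates 0.2 (exc) and 0.6 (inh).
`nn_precision` optionally routes through an explicit neuron count N to make
the N-cancellation property testable; the result is identical to 1e-12
relative.

## Synthetic scenes

The generator produces the *statistics the features key on*, not realistic
anatomy: seeded Voronoi cells under the anisotropic metric stand in for
neurite processes; a one-voxel boundary (the lower-index side of each label
change) separates them so every boundary voxel sees both labels in its
26-neighborhood; membranes are dark (60), cytosol mid-gray (150 ± 8 per
process), and at each planted synapse the border band is darkened by 40
(PSD), the presynaptic 160 nm shell receives a 2-voxel-grain binary dark
speckle of amplitude 70 (vesicle cloud), and the postsynaptic 160 nm shell
is filled bright and smooth at 200 (spine lumen). Gaussian noise (σ = 6
gray levels) is added and the result clipped to [0, 255]. Synapse count is
Poisson with density 1 per µm³ — the cortical neuropil value — over the
scene volume; infeasible draws (more synapses than eligible interfaces away
from the scene faces) are re-drawn a bounded number of times before
failing. All randomness flows through one seeded generator; scenes are
byte-identical per seed.

What the generator does *not* emulate: mitochondria and myelin (the classic
false-positive sources), segmentation errors, image alignment artifacts,
intensity gradients, and partner ambiguity at crowded contacts. Passing the
end-to-end test therefore shows that the machinery — extraction, features,
directed training, max-direction inference, matching — is wired correctly
and that the planted cues are learnable; it does not certify performance on
real tissue, where error rates are dominated by exactly the confounders the
generator omits.

Problem sizes used by the test suite and the acceptance script: scenes of
128 × 128 × 64 voxels (≈ 3.7 µm³) — large enough for a dozen processes and
a few planted synapses each while keeping the 51-map filter bank and
per-interface aggregation around half a minute per scene; 8 training + 2
test scenes; classifier at its production parameters (1500 learners, rate
0.1, cost 100). The brute-force oracle comparisons run on 32³ label volumes
and 16³ intensity volumes, where exhaustive enumeration is exact and cheap.

## Known limitations

- The filter-size rule reading (and hence the z-truncation behavior) is one
  of several defensible interpretations; it is configurable but the default
  is fixed for reproducibility.
- Empty subvolumes encode as zero statistics, which is a discontinuity; it
  occurs only for degenerate contacts near volume faces.
- The per-pair interface grouping is quadratic in the number of distinct
  labels meeting at a junction voxel (harmless at realistic junction
  multiplicities).
- Training presorts the full feature matrix (n × 3224 doubles); for the
  intended training-set sizes (10³–10⁵ directed examples) this is the right
  trade, but it is not an out-of-core implementation.
- The area definition is a reasonable surface estimator but is validated
  only against analytic planes; curved-interface bias is untested.
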