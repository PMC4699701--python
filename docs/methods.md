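# Methods

This note documents the models, estimators and numerical choices behind
`lgncolumns`, and what the synthetic benchmark does and does not show.

## Setting

A focal retrograde tracer injection in primary visual cortex (V1) labels a
*projection column*: the set of thalamic relay neurons in the dorsal
lateral geniculate nucleus (dLGN) that converge on the injected cortical
point. With many animals registered into one standardized nucleus space,
the columns form a family of 3D point clouds spanning the nucleus from its
pial (dorsal) surface to its ventral border. The package quantifies
(i) how cells are distributed along and around each column,
(ii) how the column array rotates and expands with depth,
(iii) how well neighbourhood order is preserved within the nucleus
(topology) and relative to V1 (topography), and
(iv) how many latent factors explain the pooled depth profiles.

Axis convention (the standardized spaces do not name axes; this is a
package convention): right-handed, x = medio-lateral, y = dorso-ventral
(positive dorsal), z = antero-posterior, in µm. V1 injection sites are 2D
(anterior, lateral of lambda) in mm. All downstream order metrics are
similarity-invariant, so the mixed units carry no weight.

## Column trajectory and unit column

Each column's trajectory is a per-axis quadratic piecewise polynomial with
five break parameters (the two endpoints plus three uniformly spaced
interior knots, giving four C1 quadratic pieces), least-squares fitted
against an ordering parameter. The ordering parameter is the rank of each
cell's projection onto the cloud's first principal axis, refined once by
re-projecting cells onto the fitted curve and re-ranking; ranks rather
than raw projections keep the abscissae uniformly spread so the spline
system stays well conditioned regardless of cell clustering.

The trajectory is extended along its terminal tangents to the nucleus
surface mesh (Möller–Trumbore ray casting against all faces; nucleus
meshes are ~10³ triangles so brute force is exact and fast). The end whose
crossing lies on a pial-labelled face becomes depth 0, the other depth 1.
Two robustness rules cover noisy end pieces: an end that already overshot
the surface is walked back along the curve to the curve's own crossing,
and an end whose tangent runs nearly parallel to a nearby surface (no
crossing within one path length, yet the end is within 10% of a path
length of the surface) takes its nearest surface point. Ends farther away
than one path length raise an error, as does a pial assignment where both
or neither end crosses a pial face.

Each cell's unit depth t is the arc length of its nearest trajectory point
from the pial end divided by the total length, clipped to [0, 1]; its
spread r is the perpendicular distance to the trajectory. Cells whose
perpendicular foot falls beyond a column end are flagged *clipped*: their
t is clamped but they are excluded from depth-binned profiles, so bin
counts plus the clipped count always equal the cell total.

Depth profiles use 20 half-open bins of width 0.05 (t = 1 goes to the last
bin). Counts and spreads are summarised as mean ± SEM **across columns**
(the animal is the replication unit). Spread values are multiplied by
(V_ref / V_group)^(1/3), the cube-root mesh-volume ratio to the reference
(wild-type) nucleus, to remove gross size differences between groups.
Spread is defined as perpendicular distance to the trajectory; distance
to a per-bin centre of mass is a natural variant, but the trajectory
definition is the one this package computes (it stays meaningful in
sparsely populated bins). Radial spread pooled over
cells is summarised by a maximum-likelihood Rayleigh scale,
σ̂ = √(Σ r² / 2n).

Known boundary effect: near t = 0 and t = 1 the estimated boundary
position jitters with the fit noise, and any jitter moves cells *out* of
an end bin (down into the clipped set or up into the neighbouring bin), so
end-bin counts are biased slightly low in the full reconstruction even
though the binning itself is exact. The count-profiler's rate-recovery
benchmark therefore feeds it unit columns directly; end-to-end count
recovery is asserted on the cell totals and the interior of the profile.

## Map stack and similarity alignment

At each depth level t ∈ {0, 0.05, …, 1} (21 levels; one more level than
bins because levels are bin edges, not bin interiors), the columns'
iso-percentile points are fitted with a total-least-squares plane (SVD;
the smallest-variance direction is the normal) and orthogonally projected
into it. Plane normals carry an arbitrary SVD sign and the in-plane bases
an arbitrary rotation, either of which would corrupt depth-to-depth
rotation estimates, so the stack is gauge-fixed: normals are co-oriented
with the mean pial→ventral column direction and each level's first basis
vector is the previous level's, projected into the current plane
(v = n × u completes a right-handed frame; rotations are then CCW about
the normal). Pairwise rotation estimates are invariant to the initial
bases by construction, which a dedicated test asserts.

Neighbouring maps are registered with a similarity transform
b ≈ E·R(θ)·a + τ, estimated by bounded L-BFGS-B minimisation of the mean
squared distance with E ∈ [0.1, 10] and θ ∈ (−π, π], initialised at the
closed-form complex-Procrustes solution E·e^{iθ} = Σ conj(â)b̂ / Σ|â|².
On interior optima the two agree to 1e-6 (asserted over 1,000 random
instances); the bounds only matter for pathological scale ratios.
Columns missing from either map are dropped pairwise. Cumulative rotation
is the running sum of step rotations (anchored 0 at the pial plane) and
cumulative expansion the running product (anchored 1).

## Topographic product and permutation normalization

Order between two matched point configurations is measured by the
topographic product: for each point j and neighbour rank k, with n_k^a(j)
the k-th nearest neighbour of j in space a (ties broken by lowest index),

    Q1(j,k) = d_b(j, n_k^a(j)) / d_b(j, n_k^b(j))
    Q2(j,k) = d_a(j, n_k^a(j)) / d_a(j, n_k^b(j))
    P = 1/(N(N−1)) Σ_j Σ_k log[(Π_{l≤k} Q1 Q2)^{1/2k}]

P is zero exactly when both spaces share all neighbour ranks, is invariant
to similarity transforms of either space, and flips sign when the two
spaces are exchanged — so its magnitude carries the order information.
Coincident points make the metric undefined (log of a zero distance); they
are rejected, with an opt-in deterministic jitter of 1e-6 × configuration
diameter for callers that want a value anyway.

Because raw |P| has no absolute scale, it is normalized by the mean |P|
over uniform random relabellings of one space: 0 is perfect order, ≈1 is
chance-level disorder. Values above 1 are possible and reported unclipped;
the nominal [0, 1] range is an expectation, not a bound. The Monte-Carlo
p-value is (1 + #{|P_perm| ≤ |P_obs|}) / (1 + n_perm); when N! ≤ n_perm
the full permutation group is enumerated instead of sampled, making both
the normalization and the p-value exact. The default n_perm is 999 (the
pipeline demo uses 199 to keep runs short); the normalization denominator
is the mean (not median) permuted |P|. Under random matching the p-values
are uniform up to the 1/(n_perm+1) discretisation, which the
null-calibration test verifies by Kolmogorov–Smirnov.

Three comparisons are reported per group: *topology* (each depth map vs
its predecessor, 20 values), *end-to-end* (pial vs ventral map), and
*topography* (V1 injection sites vs each depth map, 21 values). Results
with fewer than 4 shared points are flagged low-n.

## Latent-variable scan

The four metrics × groups depth profiles (counts, spread, topology,
topography) are reduced to shape by zero-mean/unit-variance
standardization (population 1/n convention), resampled onto the 21 map
levels by linear interpolation of bin centres, and stacked into a profile
matrix (rows = metric × group, columns = depth levels).

The latent scan is an autoassociative partial least squares decomposition
(X = Y = the profile matrix): with no natural predictor/response split
among the profiles, the autoassociative arrangement reduces to a
principal-component-like scan while producing the usual
explained-variance-vs-latents curve; the transposed orientation is
available by config. Cumulative %
explained variance per latent count comes from one nested fit. The
cross-validated reconstruction error uses leave-one-out by default (9-fold
available by config; both appear in the demo) with an element-wise
held-out reconstruction: each variable of a held-out row is predicted from
the row's *other* variables through the train-fold loadings
(Eastment–Krzanowski style PRESS). A plain projection of the held-out row
onto the latent subspace would be monotone non-increasing in the latent
count (nested subspaces) and could never locate a rank; the element-wise
scheme rises again once components fit noise, so its minimum estimates the
effective rank. Exact ties at numerically zero error (noiseless low-rank
input) resolve to the smallest tied latent count.

## Synthetic generator

The generator emulates the data model, not the anatomy: an ellipsoidal
nucleus (default half-axes 500 × 400 × 600 µm — the ~1 mm scale of an
adult mouse dLGN) with a dorsal pial cap (55° polar half-angle), and
16 columns per group (the adult wild-type animal count) entering through
the cap on a jittered lateral grid (±120 µm). Each column descends to the
ventral surface with a 40 µm medio-lateral bow while the column *array*
rotates by a prescribed field θ*(t) (default linear, 0.5 rad total) and
expands by E*(t) (default linear, ×1.3 total). The fields are functions of
each column's own arc-length fraction between its surface crossings; since
the clip depends on the curve and vice versa, a four-round fixed-point
iteration makes them self-consistent, so recorded ground truth holds
exactly along every generated column. Cells are drawn per depth bin with
Poisson counts (default rate 8 per 5% bin, ≈160 cells/column, the order of
magnitude of a focal tracer injection) and Rayleigh radial offsets
(default σ = 25 µm) at uniform angle in the local normal plane. Injection
sites are a fixed affine image (rotation + scale + offset into the V1
coordinate range) of the pial entry offsets; a scrambling fraction
ρ re-pairs a random ⌈ρn⌉-subset of injection↔column matches, providing a
dial from perfect topography (ρ=0) to chance (ρ=1). Low-rank profile
matrices for the latent benchmark are random loadings on k random
invertible mixtures of half-cosine harmonics plus relative Gaussian noise.

What the generator does **not** emulate: real dLGN geometry (the ellipsoid
only exercises containment/intersection behaviour), section registration
artefacts, depth-dependent σ, non-Poisson clustering of labelled cells,
tracer-spill label, or short columns that terminate inside the nucleus.
Passing recovery benchmarks therefore certify the estimators under the
stated noise model, not the anatomy of any particular dataset.

## Problem sizes and reproducibility

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn` in a fixed order (per-group simulation,
per-group order metrics, latent scan), so identical config + seed gives
bit-identical summaries. Benchmarks use problem sizes that keep the full
suite a few minutes on one CPU: brute-force oracle sweeps at N ≤ 7, full
permutation enumeration at N ≤ 6, 1,000 Procrustes instances, 10 replicate
datasets for the rotation-field recovery (the per-dataset estimate has ~8%
noise at the default scatter; the replicate mean is the benchmark), 10
scrambling levels × 5 replicate re-pairings, 50 profile-matrix seeds for
the modal rank, and 500 null replicates for p-value calibration.

## Known limitations

- End-bin count bias from boundary jitter (documented above); interior
  bins are unbiased.
- The per-dataset cumulative-rotation estimate is noisy at the default
  radial scatter; it is unbiased (zero-noise recovery is ≲1%), but single
  datasets of 16 columns resolve a 0.5 rad total rotation only to ~±8%.
- The topographic product requires ≥3 matched points and no coincident
  points; maps from very small groups are flagged rather than suppressed.
- The latent scan's explained variance is reported for the autoassociative
  arrangement; with rows ≪ columns the leave-one-out PRESS can be
  conservative about ranks close to the row count.
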