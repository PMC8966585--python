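# Methods

## Random-walker segmentation with distance-augmented weights

A 2D slice is a 4-connected lattice graph (8-connectivity optional) whose
vertices are pixels with min-max-normalized intensities g ∈ [0, 1]. Seeded
random-walker segmentation assigns each unlabeled pixel the probability
that a random walk starting there reaches a foreground seed before a
background seed; this is the solution of the combinatorial Dirichlet
problem `L_UU x_U = −L_UM x_M` on the graph Laplacian L (weighted degrees
on the diagonal, −w_ij off-diagonal, identical to AᵀCA for the edge–vertex
incidence matrix A and diagonal edge-weight matrix C) with boundary values
1 on F and 0 on B. Because there are exactly two labels, the background
probability is the complement of the foreground probability and only one
solve is needed. Labels follow the maximum-probability rule, i.e. a 0.5
threshold; the tie p = 0.5 goes to foreground.

The edge weight combines the usual Gaussian intensity affinity with a
seed-distance similarity:

    w_ij = exp(−[β₁ (g_i − g_j)² + β₂ · min(G_i, G_j)])
    G(v)  = exp(−∂ (d(F,v) + d(B,v)) / max_{f∈F} d(f, B))

* **β₁ = 90** (dimensionless): intensity-contrast sensitivity, the
  conventional magnitude for unit-range intensities.
* **β₂ = −51.5** (dimensionless): weight of the distance-similarity term.
  Negative β₂ *raises* the weight of edges whose endpoints have high G,
  i.e. edges lying near the corridor between the two seed contours, which
  is where the automatic seeds leave the boundary under-determined.
* **∂ = 0.048** (dimensionless): decay rate of the similarity with the
  normalized seed distance. `max_{f∈F} d(f, B)` (the directed Hausdorff
  distance from F to B) makes the exponent scale-free.

G is a per-pixel quantity but an edge needs a single value; we attach
`min(G_i, G_j)` to the edge, which preserves weight symmetry (a
`mean` combination is available behind the `g_combine` flag).

Numerics: with G ∈ (0, 1] and β₂ = −51.5 the raw weights reach e^51.5,
so log-weights are computed first and shifted so the maximum weight is 1 —
a global rescaling of L that leaves the Dirichlet solution unchanged.
After rescaling, weights are floored at 1e−12 of the maximum so extreme
intensity steps cannot disconnect the lattice numerically. The floor caps
the Laplacian condition number near 1e12, which in double precision can
leave errors up to ~1e−4 on large slices; solved probabilities are
validated against [−1e−3, 1 + 1e−3] and clipped to [0, 1]. The reduced
system is solved by a sparse direct method with a relative-residual check
at 1e−8. Unlabeled pixels in graph components containing no seed would
make the system singular; they are labelled by their nearest seed (exact
Euclidean distance) with a warning.

Distances d(·, v) are exact Euclidean distance transforms in pixel units,
not city-block approximations.

## Automatic seeding

Otsu's 256-bin between-class-variance threshold splits the denoised slice;
the lungs are taken as the *below*-threshold (dark) class. The preliminary
mask then drops components touching the image border (exterior air),
drops components below `min_area` (default 100 px), fills interior holes
(so nodules inside the lung stay inside the mask), and keeps at most the
two largest 4-connected components — two lobes, though a single surviving
lobe is accepted. Seeds are *contours*, not filled regions: F is the
8-connected contour of the mask eroded by `erode_radius`, B the contour of
the mask dilated by `dilate_radius` (defaults 3 and 3). Erosion/dilation
iterate the 3×3 structuring element, i.e. a Chebyshev ball, so a filled
square grows/shrinks by exactly the radius on every side; with both radii
≥ 1 the two contours cannot intersect, which is asserted. Denoising before
thresholding is a 3×3 median filter (kernel configurable; the value is a
standard denoising default).

## VLDTP texture descriptor

For each interior voxel, the 3×3×3 window defines μ (mean of all 27
values) and σ = sqrt(Σ(x−μ)²/26) — the sum runs over all 27 window values
with an N−1 divisor. Each of the 26 neighbours is coded +1/0/−1 with
dead-zone k·σ around μ (default k = 1; Φ(k), the standard normal CDF,
gives the expected fraction of neighbours not coded +1 under a locally
normal model and is exposed for reporting). The 26 offsets partition into
13 antipodal axes, ordered lexicographically on (dz, dy, dx) with the
representative whose first nonzero component is positive; each axis
accumulates the codes of both of its neighbours. Counts are normalized by
the interior-voxel count (N₁−2)(N₂−2)(N₃−2), so the 39-vector always sums
to 26 and is exactly invariant under positive affine intensity maps
(μ and σ transform covariantly). A σ = 0 window codes every neighbour 0.

The 12 gray features use population moments on the raw voxel values of
the full 3D ROI (per-middle-slice extraction would be a trivial variant;
3D was chosen because the descriptor is volumetric); kurtosis is reported
as excess kurtosis, and skewness/kurtosis of a constant input are defined
as 0. Entropy (base-2) and energy Σp² come from the 256-bin histogram on
[0, 1]. The serial handcrafted vector is [VLDTP(39), gray(12)].

## Classification

The baseline classifier is a one-hidden-layer feed-forward network
(32 logistic units, cross-entropy loss, seeded) on z-scored features;
standardization statistics are fit on the training split only. Splits are
stratified 8:2 by default and seeded. The fusion classifier concatenates a
deep volume embedding *in series* before the handcrafted values and trains
the same dense head; the backbone is frozen. The backbone is a contract
(deterministic `embed`, fixed `embedding_dim`) rather than a fixed
architecture; the built-in default is a seeded random-filter 3D
convolution bank (16 filters, ReLU, four global pooling statistics each) —
untrained random convolutional features, which are deterministic and
dependency-free. A pretrained 2D image backbone can be adapted through the
same contract (channel replication for grayscale input being the
adapter's concern); none ships with the package. A constant-output
backbone is provided to verify the sanity reduction that fusion with an
uninformative embedding matches the handcrafted-only classifier.

## Metrics

IOU = TP/(TP+FP+FN) and FPR = FP/(FP+TN) score segmentations;
accuracy, sensitivity, precision and F1 follow the standard confusion
formulas. Specificity defaults to TN/(TN+FP); a `fp_specificity` flag
returns FP/(FP+TN) under the same name for compatibility with sources
that print that ratio. Undefined metrics (zero denominators) raise rather
than return 0, since silent zeros corrupt comparisons. `standard_error`
of a set of per-run metric values is the sample standard deviation of
their deviations from the mean (n−1 divisor).

## Phantom generator

A slice is background (0.05) + body ellipse (0.70) + two lung-lobe
ellipses (0.20), intensities chosen to mimic the dark-lung/bright-tissue
CT contrast and proportioned so the Otsu split lands between lung and
body; geometry is jittered ±2% per seed around fixed named constants.
Nodules are bright discs (0.85) placed strictly inside the lobes. Noise
is additive Gaussian (default σ = 0.02) clipped to [0, 1] — the simplest
model that exercises median filtering. Geometry, nodule placement and
noise use independent spawned random streams, so the ground-truth mask is
unchanged when only the nodule count or noise changes.

Nodule ROIs (default 9³, matching a small real ROI) share a central
Gaussian blob (peak contrast 0.7 on a 0.08 pedestal). The *smooth* class
(labelled "nodule") adds a weak spatially correlated field (blurred white
noise, amplitude 0.03); the *speckled* class (labelled "suspected") is
the stand-in for irregular distractors and multiplies the blob by
voxel-wise independent noise (amplitude 0.35). The classes are separable
by raw voxel variance and by VLDTP zero-code mass by construction — that
is what passing classifier tests demonstrate. The distractor class is a
texture model, not an anatomical one, and the phantom makes no claim of
anatomical realism; results on it bound what the code does, not clinical
performance on real CT, where nodule/non-nodule contrast is far subtler.

## Problem sizes and defaults

Default experiment sizes — 5 to 20 slices at 128×128, 25 to 50 ROIs per
class at 9³ — were chosen as the smallest scales at which every behaviour
of interest (two-lobe recovery, texture separability, stable test
metrics) is expressed; all are configurable. The balanced two-class
design with an 8:2 stratified split mirrors the standard candidate-nodule
classification setup (the study scale of 500 per class is exercised in
the split and dataset-count tests).

## Known limitations

* 2D segmentation only; the random walk is not volumetric, and multi-label
  (>2 classes) walks are out of scope.
* No juxtapleural nodule recovery (border-touching lung corrections).
* DICOM support is single-frame with slope/intercept only — no HU
  windowing, multi-frame series, or physical-spacing resampling.
* The bundled backbone is untrained; fusion gains over handcrafted
  features on real data require a real pretrained embedding plugged into
  the contract.
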