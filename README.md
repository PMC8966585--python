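# noduleseg

Automatic lung parenchyma segmentation and pulmonary nodule classification
for chest CT slices, built around three ingredients:

1. **Automatic random-walker segmentation.** Seed points are obtained
   without user interaction: Otsu thresholding gives a preliminary lung
   mask (lung air is dark in CT); the contours of its morphological erosion
   and dilation become the foreground seed set *F* and background seed set
   *B*. The slice is then segmented with the random walker of Grady, using
   an edge weight augmented by the shortest distance to the seed sets:

   ```
   w_ij = exp(−[β₁ (g_i − g_j)² + β₂ · min(G_i, G_j)])
   G(v) = exp(−∂ · (d(F, v) + d(B, v)) / max_{f∈F} d(f, B))
   ```

   with intensities *g* min-max normalized to [0, 1], *d*(·, *v*) the
   Euclidean distance from pixel *v* to a seed set, and defaults
   β₁ = 90, β₂ = −51.5, ∂ = 0.048. Setting β₂ = 0 recovers the classical
   random walker. Foreground-arrival probabilities solve the combinatorial
   Dirichlet problem on the graph Laplacian; pixels are labelled by
   maximum probability.

2. **Handcrafted nodule descriptors.** A 3D region of interest around a
   candidate nodule is described by the Volume Local Direction Ternary
   Pattern (VLDTP): each of the 26 neighbours of every interior voxel is
   coded −1/0/+1 against the local window mean ± *k*·σ and the codes are
   histogrammed over the 13 antipodal direction axes, giving 39 values;
   plus 12 first-order gray-histogram statistics (mean, median, standard
   deviation, skewness, kurtosis, min, max, entropy, energy, range, mean
   absolute deviation, RMS) — a 51-dimensional serial descriptor.

3. **Feature-fusion classification.** A one-hidden-layer feed-forward
   network classifies nodules vs. suspected nodules from the handcrafted
   features, or from the serial fusion (concatenation) of a deep volume
   embedding with the handcrafted features. The embedding producer is a
   contract — anything with a deterministic `embed(volume)` — with a
   seeded random-filter convolutional backbone built in.

Every stage is testable without any external dataset through a synthetic
chest-CT phantom generator (bright body ellipse, two dark lung lobes,
bright nodule discs, two 3D nodule texture classes with ground truth).
Real data enter through PNG or single-frame DICOM readers.

## Worked example

```sh
noduleseg run-all --out demo_run --seed 7
```

runs the full synthetic pipeline (5 phantom slices at 128×128 with noise
σ = 0.02; 25 nodule ROIs per class at 9³) and prints, from
`demo_run/report.json`:

```
mean_iou: 0.99977  mean_fpr: 0.0        # segmentation vs. ground truth
mlp:    accuracy 1.0  sensitivity 1.0  specificity 1.0  precision 1.0  f1 1.0
fusion: accuracy 1.0  sensitivity 1.0  specificity 1.0  precision 1.0  f1 1.0
```

The segmentation block reports the mean intersection-over-union and false
positive rate of the automatically segmented lung masks against the
phantom ground truth; the classification blocks report held-out test
metrics (8:2 stratified split) for the handcrafted-feature network and the
fusion classifier. The phantom classes are separable by construction, so
both classifiers should sit at or near 1.0; segmentation IOU near 1.0
shows the automatic seeding and the distance-augmented walk recover the
lobes almost exactly at this noise level.

Individual stages are also exposed (`noduleseg simulate / segment /
extract-features / classify / evaluate`), and the same functionality is
available as a library:

```python
from noduleseg import phantom, segment_lung, handcrafted

sample = phantom.generate_slice(phantom.PhantomSpec(rng_seed=7))
mask, prob, seeds = segment_lung(sample.image)
vec = handcrafted(phantom.generate_nodule_volume(phantom.NoduleVolumeSpec()))
```

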