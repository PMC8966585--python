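"""Synthetic chest-CT phantom generator.

Every downstream stage (seeding, random-walk segmentation, texture features,
classification) is exercised on images produced here, so no external dataset
is needed.  A phantom slice is a bright elliptical "body" on a dark background
containing two darker elliptical "lung lobes" — the dark-lung / bright-tissue
contrast that Otsu thresholding exploits in real CT — optionally with small
bright discs standing in for nodules.  Nodule ROIs are 3D volumes in one of
two texture classes: ``smooth`` (a low-frequency Gaussian blob with spatially
correlated perturbations, emulating a solid nodule) and ``speckled`` (the same
blob carrying uncorrelated high-frequency multiplicative noise, a stand-in
for irregular suspected-nodule distractors).  The two classes are separable
both by raw voxel variance and by local ternary texture statistics.

All generation is driven by ``numpy.random.Generator`` streams spawned from a
single integer seed, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError

# Fixed phantom geometry (fractions of image height/width).  Chosen so that
# the body stays clear of the image border, the lobes stay inside the body,
# and the Otsu split on a noiseless slice lands between lung and body
# intensity (background + lungs together outweigh the body class).
BODY_SEMI_AXES = (0.42, 0.46)      # (row, col) semi-axes of the body ellipse
LUNG_SEMI_AXES = (0.26, 0.13)      # semi-axes of each lung lobe
LUNG_CENTER_ROW = 0.50             # lobe centre row (fraction of height)
LUNG_CENTER_COLS = (0.32, 0.68)    # lobe centre columns, left and right
GEOMETRY_JITTER = 0.02             # relative jitter on centres and axes
NODULE_INTENSITY = 0.85            # disc intensity of in-lung nodules

LABEL_NODULE = "nodule"
LABEL_SUSPECTED = "suspected"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic CT slice.

    Intensities are fractions of the unit range and must satisfy
    ``background < lung < body`` (air-filled lungs are darker than the
    surrounding tissue).  ``noise_sigma`` is the standard deviation of the
    additive Gaussian noise, in intensity units; the image is clipped back
    to [0, 1] afterwards.
    """

    image_height: int = 128
    image_width: int = 128
    lung_intensity: float = 0.20
    body_intensity: float = 0.70
    background_intensity: float = 0.05
    noise_sigma: float = 0.02
    n_nodules: int = 2
    nodule_radius_range: tuple[int, int] = (2, 4)
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.background_intensity < self.lung_intensity < self.body_intensity):
            raise DegenerateInputError(
                "phantom intensities must satisfy background < lung < body, got "
                f"{self.background_intensity} / {self.lung_intensity} / {self.body_intensity}"
            )
        if self.noise_sigma < 0:
            raise DegenerateInputError("noise_sigma must be >= 0")
        if self.n_nodules < 0:
            raise DegenerateInputError("n_nodules must be >= 0")
        if self.image_height < 16 or self.image_width < 16:
            raise DegenerateInputError("phantom slices must be at least 16x16")
        lo, hi = self.nodule_radius_range
        if not (1 <= lo <= hi):
            raise DegenerateInputError("nodule_radius_range must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class PhantomSample:
    """A generated slice with its ground truth."""

    image: np.ndarray            # (H, W) float in [0, 1]
    lung_mask: np.ndarray        # (H, W) bool, the two lobes
    nodule_centers: tuple[tuple[int, int], ...]
    label: str                   # LABEL_NODULE if nodules present else LABEL_SUSPECTED


@dataclass(frozen=True)
class NoduleVolumeSpec:
    """Parameters of a 3D nodule ROI volume.

    ``contrast`` is the peak intensity of the central blob above the dim
    pedestal.  All dimensions must be >= 3 so the volume has interior voxels
    (the texture descriptor codes full 26-neighbourhoods only).
    """

    depth: int = 9
    height: int = 9
    width: int = 9
    texture_class: Literal["smooth", "speckled"] = "smooth"
    contrast: float = 0.7
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.depth, self.height, self.width) < 3:
            raise DegenerateInputError(
                "nodule volumes need all dimensions >= 3 "
                f"(got {self.depth}x{self.height}x{self.width})"
            )
        if self.texture_class not in ("smooth", "speckled"):
            raise DegenerateInputError(f"unknown texture_class {self.texture_class!r}")
        if not (0 < self.contrast <= 1):
            raise DegenerateInputError("contrast must lie in (0, 1]")


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi_axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (((rr - center[0]) / semi_axes[0]) ** 2
            + ((cc - center[1]) / semi_axes[1]) ** 2) <= 1.0


def generate_slice(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom slice with ground-truth lung mask and nodule centres.

    The geometry, nodule placement, and noise use three independent random
    streams spawned from ``spec.rng_seed``, so the lung mask is identical
    across specs that differ only in ``n_nodules`` or ``noise_sigma``.
    """
    spec.validate()
    geom_rng, nodule_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.rng_seed).spawn(3)
    )
    h, w = spec.image_height, spec.image_width

    def jitter() -> float:
        return 1.0 + geom_rng.uniform(-GEOMETRY_JITTER, GEOMETRY_JITTER)

    body = _ellipse_mask(
        (h, w),
        (h / 2 * jitter(), w / 2 * jitter()),
        (BODY_SEMI_AXES[0] * h * jitter(), BODY_SEMI_AXES[1] * w * jitter()),
    )
    lung_mask = np.zeros((h, w), dtype=bool)
    for col_frac in LUNG_CENTER_COLS:
        lobe = _ellipse_mask(
            (h, w),
            (LUNG_CENTER_ROW * h * jitter(), col_frac * w * jitter()),
            (LUNG_SEMI_AXES[0] * h * jitter(), LUNG_SEMI_AXES[1] * w * jitter()),
        )
        lung_mask |= lobe & body

    image = np.full((h, w), spec.background_intensity, dtype=float)
    image[body] = spec.body_intensity
    image[lung_mask] = spec.lung_intensity

    centers: list[tuple[int, int]] = []
    lo, hi = spec.nodule_radius_range
    for _ in range(spec.n_nodules):
        radius = int(nodule_rng.integers(lo, hi + 1))
        # candidate centres keep the whole disc strictly inside the lung;
        # iterated cross erosion is a city-block ball, so cover the Euclidean
        # disc with radius*sqrt(2) plus one voxel of margin
        candidates = ndimage.binary_erosion(
            lung_mask, iterations=int(np.ceil(radius * np.sqrt(2))) + 1
        )
        rows, cols = np.nonzero(candidates)
        if rows.size == 0:
            raise DegenerateInputError(
                "lungs too small to place a nodule of radius "
                f"{radius}; shrink nodule_radius_range or enlarge the image"
            )
        pick = int(nodule_rng.integers(rows.size))
        r0, c0 = int(rows[pick]), int(cols[pick])
        disc = _ellipse_mask((h, w), (r0, c0), (radius, radius))
        image[disc] = NODULE_INTENSITY
        centers.append((r0, c0))

    if spec.noise_sigma > 0:
        image = image + noise_rng.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    label = LABEL_NODULE if spec.n_nodules > 0 else LABEL_SUSPECTED
    return PhantomSample(image=image, lung_mask=lung_mask,
                         nodule_centers=tuple(centers), label=label)


# Amplitudes of the two perturbation fields in generate_nodule_volume.
SMOOTH_NOISE_AMP = 0.03     # additive, spatially correlated (blurred white noise)
SMOOTH_NOISE_SIGMA = 1.5    # Gaussian blur length of the correlated field, voxels
SPECKLE_AMP = 0.35          # multiplicative, voxel-wise independent


def generate_nodule_volume(spec: NoduleVolumeSpec) -> np.ndarray:
    """Generate one 3D nodule ROI of the requested texture class.

    Both classes share a central Gaussian blob of peak ``contrast`` on a dim
    pedestal.  The ``smooth`` class adds a weak spatially correlated
    perturbation; the ``speckled`` class multiplies the blob by independent
    per-voxel noise, giving a strictly larger voxel-wise variance and a very
    different local ternary code distribution while keeping the mean
    intensity of the two classes comparable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = (spec.depth, spec.height, spec.width)

    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - (n - 1) / 2) / (n / 4)) ** 2 for g, n in zip(grids, shape))
    blob = spec.contrast * np.exp(-0.5 * r2)
    base = 0.08 + blob

    if spec.texture_class == "smooth":
        field = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=SMOOTH_NOISE_SIGMA, mode="reflect"
        )
        volume = base + SMOOTH_NOISE_AMP * field
    else:
        volume = base * (1.0 + SPECKLE_AMP * rng.standard_normal(shape))
    return np.clip(volume, 0.0, 1.0)


def generate_dataset(
    n_per_class: int,
    template: NoduleVolumeSpec | None = None,
    rng_seed: int = 0,
) -> list[tuple[np.ndarray, str]]:
    """Generate a balanced, shuffled list of ``(volume, label)`` pairs.

    ``smooth`` volumes carry the nodule label, ``speckled`` volumes the
    suspected-nodule label.  Ordering and per-volume seeds are derived from
    ``rng_seed`` so the whole dataset is reproducible.
    """
    if n_per_class < 1:
        raise DegenerateInputError("n_per_class must be >= 1")
    template = template or NoduleVolumeSpec()
    order_rng = np.random.default_rng(np.random.SeedSequence(rng_seed).spawn(1)[0])
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * n_per_class) % (2**31)

    samples: list[tuple[np.ndarray, str]] = []
    for i in range(n_per_class):
        for cls, label in (("smooth", LABEL_NODULE), ("speckled", LABEL_SUSPECTED)):
            k = 2 * i + (0 if cls == "smooth" else 1)
            vspec = dataclasses.replace(
                template, texture_class=cls, rng_seed=int(seeds[k])
            )
            samples.append((generate_nodule_volume(vspec), label))
    order = order_rng.permutation(len(samples))
    return [samples[i] for i in order]
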