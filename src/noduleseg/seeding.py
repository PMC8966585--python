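"""Automatic seed-point selection for the random walker.

Manual seed placement is replaced by: (1) a preliminary lung segmentation by
Otsu thresholding (lung air is dark in CT, so the lungs are the below-
threshold class, after discarding exterior air touching the image border,
dropping small components, filling interior holes, and keeping at most the
two largest components — the two lobes); (2) morphological erosion and
dilation of that mask, whose inner and outer boundary contours become the
foreground seed set F (inside the lung) and background seed set B (outside
it).  F and B are disjoint by construction and anchor the Dirichlet boundary
conditions of the random walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import clear_border

from .errors import DegenerateInputError, SeedingError

DEFAULT_MIN_AREA = 100
DEFAULT_ERODE_RADIUS = 3
DEFAULT_DILATE_RADIUS = 3

# 8-connected structuring element; iterated r times it spans a Chebyshev
# ball of radius r, so eroding/dilating a filled square shrinks/grows it by
# r pixels on every side.
_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedSet:
    """Disjoint foreground (F) and background (B) seed coordinates."""

    foreground: frozenset[tuple[int, int]]
    background: frozenset[tuple[int, int]]

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if not self.foreground or not self.background:
            raise SeedingError("both seed sets must be nonempty")
        if self.foreground & self.background:
            raise SeedingError("foreground and background seeds must be disjoint")
        if shape is not None:
            for r, c in self.foreground | self.background:
                if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                    raise SeedingError(f"seed ({r}, {c}) outside image of shape {shape}")

    def indicator(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (F, B) indicator images of the given shape."""
        fg = np.zeros(shape, dtype=bool)
        bg = np.zeros(shape, dtype=bool)
        if self.foreground:
            fr, fc = zip(*sorted(self.foreground))
            fg[list(fr), list(fc)] = True
        if self.background:
            br, bc = zip(*sorted(self.background))
            bg[list(br), list(bc)] = True
        return fg, bg


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram (returns the selected bin's midpoint)."""
    image = np.asarray(image, dtype=float)
    if np.unique(image).size < 2:
        raise DegenerateInputError("Otsu threshold undefined for a constant image")
    return float(threshold_otsu(image, nbins=256))


def _coords(mask: np.ndarray) -> frozenset[tuple[int, int]]:
    rows, cols = np.nonzero(mask)
    return frozenset(zip(rows.tolist(), cols.tolist()))


def contour(mask: np.ndarray) -> np.ndarray:
    """8-connected contour: mask pixels with at least one background 8-neighbour.

    Pixels on the image border count as adjacent to background.
    """
    inner = ndimage.binary_erosion(mask, structure=_SQUARE3, border_value=0)
    return mask & ~inner


def initial_lung_mask(image: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Preliminary lung segmentation by Otsu thresholding plus cleanup.

    Keeps below-threshold (dark) pixels, removes components touching the
    image border (exterior air), drops components smaller than ``min_area``,
    fills interior holes, and keeps at most the two largest 4-connected
    components (the lobes; a single surviving lobe is allowed).
    """
    image = np.asarray(image, dtype=float)
    try:
        thresh = otsu_threshold(image)
    except DegenerateInputError as exc:
        raise SeedingError(f"initial lung mask failed: {exc}") from exc
    dark = image <= thresh
    dark = clear_border(dark)
    labels, n = ndimage.label(dark)  # 4-connected
    if n == 0:
        raise SeedingError(
            "no dark component survives border removal; "
            "check image polarity or lower min_area"
        )
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(areas)[::-1][:2] + 1
    keep = [int(k) for k in keep if areas[k - 1] >= min_area]
    if not keep:
        raise SeedingError(
            f"all candidate lung components smaller than min_area={min_area}; "
            "lower min_area or check the input"
        )
    mask = np.isin(labels, keep)
    return ndimage.binary_fill_holes(mask)


def seeds_from_mask(
    mask: np.ndarray,
    erode_radius: int = DEFAULT_ERODE_RADIUS,
    dilate_radius: int = DEFAULT_DILATE_RADIUS,
) -> SeedSet:
    """Seed sets from the morphological boundaries of an initial mask.

    F is the contour of the mask eroded by ``erode_radius`` (strictly inside
    the lung); B is the contour of the mask dilated by ``dilate_radius``
    (strictly outside).  Radii are in pixels of Chebyshev distance.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SeedingError("empty mask: nothing to seed")
    if erode_radius < 1 or dilate_radius < 1:
        raise SeedingError("erode_radius and dilate_radius must be >= 1")
    eroded = ndimage.binary_erosion(mask, structure=_SQUARE3,
                                    iterations=erode_radius, border_value=0)
    if not eroded.any():
        raise SeedingError(
            f"erosion with radius {erode_radius} annihilates the mask; "
            "use a smaller erode_radius"
        )
    dilated = ndimage.binary_dilation(mask, structure=_SQUARE3,
                                      iterations=dilate_radius, border_value=0)
    seeds = SeedSet(foreground=_coords(contour(eroded)),
                    background=_coords(contour(dilated)))
    seeds.validate(mask.shape)
    return seeds
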