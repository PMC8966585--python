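"""Handcrafted nodule descriptors: VLDTP texture + first-order gray features.

VLDTP (Volume Local Direction Ternary Pattern)
----------------------------------------------
For every interior voxel of a 3D ROI, the 3x3x3 window around it defines a
local mode: the reference value is the window mean ``mu`` over all N = 27
voxels and the adaptive threshold is ``k * sigma`` with

    sigma = sqrt( sum_i (x_i - mu)^2 / (N - 1) ).

Each of the 26 neighbours g_p is coded ternary:

    +1 if g_p > mu + k*sigma,   -1 if g_p < mu - k*sigma,   0 otherwise.

The 26 neighbour offsets are grouped into 13 direction axes (antipodal
pairs); per axis the counts of -1 / 0 / +1 over both neighbours and all
interior voxels form a 13 x 3 = 39 histogram, normalized by the number of
interior voxels (N1-2)(N2-2)(N3-2).  Each interior voxel contributes exactly
26 codes, so the normalized vector always sums to 26.  The default threshold
coefficient is k = 1; under a locally normal intensity model the expected
fraction of neighbours falling at or below the upper cutoff (i.e. not coded
+1) is the standard normal CDF Phi(k).

Gray-histogram features
-----------------------
Twelve first-order statistics of the ROI intensity distribution: mean,
median, standard deviation, skewness, kurtosis (excess), minimum, maximum,
entropy, energy, range, mean absolute deviation, root mean square.  Entropy
(bits) and energy are computed from the 256-bin probability histogram
p(r_k) = n_k / n over [0, 1]; the moments use the raw voxel values with
population normalization.

The serial handcrafted descriptor is the 39 VLDTP values followed by the 12
gray features: 51 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy.stats import norm

from .errors import DegenerateInputError

WINDOW_SIZE = 27          # voxels in the 3x3x3 local mode
N_NEIGHBORS = 26
N_AXES = 13
N_VLDTP = N_AXES * 3      # 39
N_GRAY = 12
N_HANDCRAFTED = N_VLDTP + N_GRAY  # 51
DEFAULT_K = 1.0
HIST_BINS = 256

#: the 26 neighbour offsets (dz, dy, dx), lexicographic order
NEIGHBOR_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def direction_axes() -> tuple[tuple[int, int, int], ...]:
    """The 13 antipodal direction axes of the 26-neighbourhood.

    Each axis is represented by the offset whose first nonzero component is
    positive; axes are sorted lexicographically on (dz, dy, dx).  Every
    neighbour offset belongs to exactly one axis (itself or its negation).
    """
    reps = sorted(
        o for o in NEIGHBOR_OFFSETS
        if next(c for c in o if c != 0) > 0
    )
    return tuple(reps)


_AXES = direction_axes()
_AXIS_INDEX = {o: i for i, o in enumerate(_AXES)}
_AXIS_INDEX.update({tuple(-c for c in o): i for i, o in enumerate(_AXES)})


def local_ternary_codes(window: np.ndarray, k: float = DEFAULT_K) -> np.ndarray:
    """Ternary codes of the 26 neighbours of one 3x3x3 window.

    Returns an array of 26 values in {-1, 0, +1}, ordered like
    ``NEIGHBOR_OFFSETS``.  A zero-variance window yields all zeros.
    """
    window = np.asarray(window, dtype=float)
    if window.shape != (3, 3, 3):
        raise DegenerateInputError(f"expected a 3x3x3 window, got {window.shape}")
    mu = window.mean()
    sigma = np.sqrt(np.sum((window - mu) ** 2) / (WINDOW_SIZE - 1))
    codes = np.empty(N_NEIGHBORS, dtype=np.int8)
    for idx, (dz, dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        gp = window[dz + 1, dy + 1, dx + 1]
        if gp > mu + k * sigma:
            codes[idx] = 1
        elif gp < mu - k * sigma:
            codes[idx] = -1
        else:
            codes[idx] = 0
    return codes


def vldtp(volume: np.ndarray, k: float = DEFAULT_K) -> np.ndarray:
    """The 39-dimensional VLDTP descriptor of a 3D volume.

    Output ordering is axis-major over :func:`direction_axes`, with the
    three code slots (-1, 0, +1) contiguous per axis.  The values are counts
    divided by the interior-voxel count, and always sum to 26.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3 or min(volume.shape) < 3:
        raise DegenerateInputError(
            f"vldtp needs a 3D volume with all dims >= 3, got shape {volume.shape}"
        )
    core = (slice(1, -1),) * 3

    # window mean over the 27-voxel neighbourhood of each interior voxel
    stacked = np.stack(
        [volume[1 + dz: volume.shape[0] - 1 + dz,
                1 + dy: volume.shape[1] - 1 + dy,
                1 + dx: volume.shape[2] - 1 + dx]
         for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)],
        axis=0,
    )
    mu = stacked.mean(axis=0)
    sigma = np.sqrt(((stacked - mu) ** 2).sum(axis=0) / (WINDOW_SIZE - 1))
    hi = mu + k * sigma
    lo = mu - k * sigma

    hist = np.zeros((N_AXES, 3), dtype=float)
    for offset in NEIGHBOR_OFFSETS:
        dz, dy, dx = offset
        gp = volume[1 + dz: volume.shape[0] - 1 + dz,
                    1 + dy: volume.shape[1] - 1 + dy,
                    1 + dx: volume.shape[2] - 1 + dx]
        code = (gp > hi).astype(np.int8) - (gp < lo).astype(np.int8)
        ax = _AXIS_INDEX[offset]
        hist[ax, 0] += np.count_nonzero(code == -1)
        hist[ax, 1] += np.count_nonzero(code == 0)
        hist[ax, 2] += np.count_nonzero(code == 1)

    n_interior = np.prod([s - 2 for s in volume.shape])
    return (hist / n_interior).ravel()


def threshold_coefficient_check(k: float) -> float:
    """Standard normal CDF Phi(k): expected fraction of neighbours not coded +1.

    Reported for documentation of the threshold coefficient; Phi(0) = 0.5
    and Phi(k) -> 1 as k grows.
    """
    return float(norm.cdf(k))


def gray_histogram(values: np.ndarray, bins: int = HIST_BINS) -> np.ndarray:
    """Probability histogram p(r_k) = n_k / n over ``bins`` uniform bins on [0, 1]."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("empty input to gray_histogram")
    counts, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return counts / values.size


@dataclass(frozen=True)
class GrayFeature:
    """The 12 first-order gray-histogram features, in reporting order."""

    mean: float
    median: float
    standard_deviation: float
    skewness: float
    kurtosis: float
    minimum: float
    maximum: float
    entropy: float
    energy: float
    range: float
    mean_absolute_deviation: float
    root_mean_square: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dataclass_fields(self)])

    @staticmethod
    def names() -> list[str]:
        return [f.name for f in dataclass_fields(GrayFeature)]


def gray_features(values: np.ndarray) -> GrayFeature:
    """First-order statistics of an image or volume intensity distribution.

    Moments use population normalization; kurtosis is excess kurtosis
    (normal -> 0); a constant input has skewness and kurtosis 0 by
    convention, entropy 0 and energy 1.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateInputError("empty input to gray_features")
    mean = float(v.mean())
    std = float(v.std())  # population
    centered = v - mean
    if std > 0:
        skew = float((centered**3).mean() / std**3)
        kurt = float((centered**4).mean() / std**4 - 3.0)
    else:
        skew = kurt = 0.0
    p = gray_histogram(v)
    nz = p[p > 0]
    return GrayFeature(
        mean=mean,
        median=float(np.median(v)),
        standard_deviation=std,
        skewness=skew,
        kurtosis=kurt,
        minimum=float(v.min()),
        maximum=float(v.max()),
        entropy=float(-(nz * np.log2(nz)).sum()),
        energy=float((p**2).sum()),
        range=float(v.max() - v.min()),
        mean_absolute_deviation=float(np.abs(centered).mean()),
        root_mean_square=float(np.sqrt((v**2).mean())),
    )


def vldtp_feature_names() -> list[str]:
    """Column names of the 39 VLDTP slots: axis index + offset + code sign."""
    names = []
    for i, (dz, dy, dx) in enumerate(_AXES):
        tag = f"a{i:02d}_{dz:+d}{dy:+d}{dx:+d}".replace("+", "p").replace("-", "m")
        for code in ("m1", "z0", "p1"):
            names.append(f"vldtp_{tag}_{code}")
    return names


def handcrafted_feature_names() -> list[str]:
    return vldtp_feature_names() + [f"gray_{n}" for n in GrayFeature.names()]


def handcrafted(volume: np.ndarray, k: float = DEFAULT_K) -> np.ndarray:
    """The serial 51-dimensional descriptor: VLDTP (39) then gray features (12)."""
    return np.concatenate([vldtp(volume, k=k), gray_features(volume).as_array()])
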