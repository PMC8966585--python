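"""Random-walker lung segmentation with a distance-augmented weight function.

A slice is modelled as a lattice graph whose vertices are pixels.  Each edge
(i, j) carries the weight

    w_ij = exp(-[beta1 * (g_i - g_j)^2 + beta2 * min(G_i, G_j)])

where g is the [0, 1] intensity and G is the shortest-spatial-distance
similarity

    G(v) = exp(-partial * (d(F, v) + d(B, v)) / max_{f in F} d(f, B)),

with d(., v) the exact Euclidean distance from pixel v to the foreground (F)
or background (B) seed set.  The classical Grady walker is the beta2 = 0
special case; the negative default beta2 = -51.5 boosts edges near the seed
sets, sharpening the segmentation boundary obtained from automatic seeds.

The probability that a walker starting at each pixel first reaches a
foreground seed solves the combinatorial Dirichlet problem on the graph
Laplacian L (degrees on the diagonal, -w_ij off-diagonal) with boundary
values 1 on F and 0 on B: the unlabeled block satisfies
``L_UU x_U = -L_UM x_M``.  Pixels are then labelled by the maximum
probability criterion (foreground where p >= 0.5).

Because beta2 = -51.5 with G in (0, 1] would exponentiate to e^51.5, edge
weights are computed in log space and globally rescaled so the largest
weight is 1.  Scaling every weight by a constant rescales both sides of the
Dirichlet system and leaves the solution unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph, linalg as splinalg

from .errors import DegenerateInputError, NumericalError
from .io_preprocess import median_filter
from .seeding import (
    DEFAULT_DILATE_RADIUS,
    DEFAULT_ERODE_RADIUS,
    DEFAULT_MIN_AREA,
    SeedSet,
    initial_lung_mask,
    seeds_from_mask,
)

#: default weight-function parameters
DEFAULT_BETA1 = 90.0
DEFAULT_BETA2 = -51.5
DEFAULT_PARTIAL = 0.048

#: relative floor applied to edge weights after rescaling, so that extreme
#: intensity steps cannot underflow an edge to exactly zero and disconnect
#: the lattice numerically
WEIGHT_FLOOR = 1e-12

RESIDUAL_RTOL = 1e-8

#: admissible numerical overshoot of solved probabilities outside [0, 1]
#: before clipping; the weight floor bounds the Laplacian condition number
#: near 1/WEIGHT_FLOOR, which in double precision can leave errors of this
#: order on large slices
OVERSHOOT_TOL = 1e-3


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the edge-weight function."""

    beta1: float = DEFAULT_BETA1
    beta2: float = DEFAULT_BETA2
    partial: float = DEFAULT_PARTIAL
    connectivity: Literal[4, 8] = 4
    g_combine: Literal["min", "mean"] = "min"

    def validate(self) -> None:
        if self.beta1 <= 0:
            raise DegenerateInputError("beta1 must be > 0")
        if self.connectivity not in (4, 8):
            raise DegenerateInputError("connectivity must be 4 or 8")
        if self.g_combine not in ("min", "mean"):
            raise DegenerateInputError("g_combine must be 'min' or 'mean'")


@dataclass(frozen=True)
class DistanceFields:
    """Euclidean distances to each seed set plus the directed Hausdorff scale."""

    d_to_F: np.ndarray
    d_to_B: np.ndarray
    hausdorff_FB: float  # max over f in F of d(f, B)


@dataclass(frozen=True)
class SimilarityField:
    """Shortest-spatial-distance similarity G, per pixel, in (0, 1]."""

    G: np.ndarray


@dataclass(frozen=True)
class ProbabilityField:
    """Per-pixel probability of first arrival at a foreground seed."""

    p_fg: np.ndarray


@dataclass(frozen=True)
class LatticeGraph:
    """Undirected lattice graph over the pixels of a ``shape`` image."""

    shape: tuple[int, int]
    edges: np.ndarray    # (m, 2) int, row-major vertex indices, i < j
    weights: np.ndarray  # (m,) float, symmetric by construction

    @property
    def n_vertices(self) -> int:
        return int(np.prod(self.shape))


def distance_fields(shape: tuple[int, int], seeds: SeedSet) -> DistanceFields:
    """Exact Euclidean distance transforms to F and B.

    ``hausdorff_FB`` is the largest distance from a foreground seed to the
    background set; it is the normalizing scale of the similarity field and
    is positive whenever F and B are disjoint and nonempty.
    """
    seeds.validate(shape)
    fg, bg = seeds.indicator(shape)
    d_to_F = ndimage.distance_transform_edt(~fg)
    d_to_B = ndimage.distance_transform_edt(~bg)
    hausdorff_FB = float(d_to_B[fg].max())
    return DistanceFields(d_to_F=d_to_F, d_to_B=d_to_B, hausdorff_FB=hausdorff_FB)


def similarity_field(df: DistanceFields, partial: float = DEFAULT_PARTIAL) -> SimilarityField:
    """G(v) = exp(-partial * (d(F,v) + d(B,v)) / hausdorff_FB), in (0, 1]."""
    if df.hausdorff_FB <= 0:
        raise DegenerateInputError(
            "degenerate seeds: the foreground-to-background Hausdorff distance is zero"
        )
    G = np.exp(-partial * (df.d_to_F + df.d_to_B) / df.hausdorff_FB)
    return SimilarityField(G=G)


def _lattice_edges(shape: tuple[int, int], connectivity: int) -> np.ndarray:
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pairs = [
        np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1),  # horizontal
        np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1),  # vertical
    ]
    if connectivity == 8:
        pairs.append(np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1))
        pairs.append(np.stack([idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()], axis=1))
    return np.concatenate(pairs, axis=0)


def edge_weights(
    image: np.ndarray,
    G: SimilarityField | None,
    params: WeightParams = WeightParams(),
) -> LatticeGraph:
    """Build the weighted lattice graph of the improved weight function.

    ``G`` may be None when ``beta2 == 0`` (the distance term vanishes).
    Weights are computed in log space, shifted so the maximum weight is 1,
    and floored at ``WEIGHT_FLOOR`` relative to that maximum.
    """
    params.validate()
    image = np.asarray(image, dtype=float)
    if params.beta2 != 0 and G is None:
        raise DegenerateInputError("a similarity field is required when beta2 != 0")
    if G is not None and G.G.shape != image.shape:
        raise DegenerateInputError(
            f"similarity field shape {G.G.shape} != image shape {image.shape}"
        )

    edges = _lattice_edges(image.shape, params.connectivity)
    g = image.ravel()
    log_w = -params.beta1 * (g[edges[:, 0]] - g[edges[:, 1]]) ** 2
    if params.beta2 != 0:
        gv = G.G.ravel()
        gi, gj = gv[edges[:, 0]], gv[edges[:, 1]]
        combined = np.minimum(gi, gj) if params.g_combine == "min" else 0.5 * (gi + gj)
        log_w = log_w - params.beta2 * combined
    if not np.all(np.isfinite(log_w)):
        raise NumericalError("non-finite edge weight encountered")
    log_w -= log_w.max()
    weights = np.maximum(np.exp(log_w), WEIGHT_FLOOR)
    return LatticeGraph(shape=tuple(image.shape), edges=edges, weights=weights)


def build_laplacian(graph: LatticeGraph) -> sparse.csr_array:
    """Sparse combinatorial Laplacian: degrees on the diagonal, -w_ij off it."""
    n = graph.n_vertices
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    w = graph.weights
    W = sparse.coo_array(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    degrees = np.asarray(W.sum(axis=1)).ravel()
    return (sparse.diags_array(degrees) - W).tocsr()


def _seed_indices(seeds: SeedSet, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    fg = np.array(sorted(seeds.foreground))
    bg = np.array(sorted(seeds.background))
    return fg[:, 0] * shape[1] + fg[:, 1], bg[:, 0] * shape[1] + bg[:, 1]


def solve_dirichlet(
    L: sparse.csr_array,
    seeds: SeedSet,
    shape: tuple[int, int],
) -> ProbabilityField:
    """Solve the Dirichlet problem with boundary values 1 on F and 0 on B.

    Unlabeled pixels in graph components containing no seed make the reduced
    system singular; those pixels are labelled by their nearest seed instead
    (with a warning) and excluded from the solve.
    """
    seeds.validate(shape)
    n = int(np.prod(shape))
    fg_idx, bg_idx = _seed_indices(seeds, shape)
    x = np.full(n, np.nan)
    x[fg_idx] = 1.0
    x[bg_idx] = 0.0
    labeled = ~np.isnan(x)
    unlabeled = np.nonzero(~labeled)[0]
    if unlabeled.size == 0:
        return ProbabilityField(p_fg=x.reshape(shape))

    # detect unlabeled components that no seed can reach
    n_comp, comp = csgraph.connected_components(abs(L), directed=False)
    if n_comp > 1:
        seeded_comps = np.unique(comp[labeled])
        orphan = ~np.isin(comp[unlabeled], seeded_comps)
        if orphan.any():
            warnings.warn(
                f"{int(orphan.sum())} pixels lie in components with no seed; "
                "labelling them by nearest seed", stacklevel=2
            )
            df = distance_fields(shape, seeds)
            nearest_fg = (df.d_to_F <= df.d_to_B).ravel()
            orphan_idx = unlabeled[orphan]
            x[orphan_idx] = nearest_fg[orphan_idx].astype(float)
            unlabeled = unlabeled[~orphan]

    if unlabeled.size:
        labeled_idx = np.nonzero(~np.isnan(x))[0]
        L_csr = L.tocsr()
        L_UU = L_csr[unlabeled][:, unlabeled].tocsc()
        L_UM = L_csr[unlabeled][:, labeled_idx]
        b = -L_UM @ x[labeled_idx]
        x_u = splinalg.spsolve(L_UU, b)
        residual = np.linalg.norm(L_UU @ x_u - b)
        if residual > RESIDUAL_RTOL * max(1.0, np.linalg.norm(b)):
            raise NumericalError(
                f"Dirichlet solve residual {residual:.3e} exceeds tolerance"
            )
        if x_u.min() < -OVERSHOOT_TOL or x_u.max() > 1 + OVERSHOOT_TOL:
            raise NumericalError(
                f"solved probabilities outside [0, 1]: [{x_u.min()}, {x_u.max()}]"
            )
        x[unlabeled] = x_u
    return ProbabilityField(p_fg=np.clip(x, 0.0, 1.0).reshape(shape))


def label_from_probability(p: ProbabilityField, threshold: float = 0.5) -> np.ndarray:
    """Maximum-probability labelling: foreground where p_fg >= threshold (ties -> foreground)."""
    return p.p_fg >= threshold


@dataclass(frozen=True)
class SeedingConfig:
    """Parameters of the automatic seeding stage used by :func:`segment_lung`."""

    median_kernel: int = 3
    min_area: int = DEFAULT_MIN_AREA
    erode_radius: int = DEFAULT_ERODE_RADIUS
    dilate_radius: int = DEFAULT_DILATE_RADIUS


def segment_lung(
    image: np.ndarray,
    params: WeightParams = WeightParams(),
    seeding_config: SeedingConfig = SeedingConfig(),
) -> tuple[np.ndarray, ProbabilityField, SeedSet]:
    """Fully automatic lung parenchyma segmentation of one slice.

    Pipeline: median denoising -> Otsu initial mask -> morphological seed
    contours -> distance/similarity fields -> improved edge weights ->
    Laplacian -> Dirichlet solve -> maximum-probability labelling.
    Deterministic; returns ``(mask, probabilities, seeds)``.
    """
    image = np.asarray(image, dtype=float)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            exc.add_note(f"segment_lung stage: {name}")
            raise

    denoised = _stage("median_filter", median_filter, image, seeding_config.median_kernel)
    mask0 = _stage("initial_lung_mask", initial_lung_mask, denoised, seeding_config.min_area)
    seeds = _stage("seeds_from_mask", seeds_from_mask, mask0,
                   seeding_config.erode_radius, seeding_config.dilate_radius)
    if params.beta2 != 0:
        df = _stage("distance_fields", distance_fields, denoised.shape, seeds)
        G = _stage("similarity_field", similarity_field, df, params.partial)
    else:
        G = None
    graph = _stage("edge_weights", edge_weights, denoised, G, params)
    L = _stage("build_laplacian", build_laplacian, graph)
    prob = _stage("solve_dirichlet", solve_dirichlet, L, seeds, denoised.shape)
    mask = label_from_probability(prob)
    return mask, prob, seeds
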