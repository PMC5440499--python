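"""LV blood-pool delineation (segmentation part I).

The blood pool is located on a low-signal subtraction image (shortest TE
minus the LVBP-optimal TE, clipped at zero), where the slowly decaying blood
becomes dark and homogeneous while the myocardium stays bright.  Pixels
inside the mid-wall contour are grouped by k-means on intensity and the
lowest-intensity cluster seeds the pool mask; a vector-field-convolution
(VFC) active contour then shapes the central pool on the subtraction image,
and a second contour evolved on the composite image re-joins papillary
muscles and trabeculae into the final LVBP region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import lu_factor, lu_solve
from scipy.signal import fftconvolve

from . import _geometry as geo
from .composite import CompositeImage, ROISet
from .mge_io import MGESeries

logger = logging.getLogger(__name__)


@dataclass
class VFCParams:
    """Vector-field-convolution snake parameters.

    ``kernel_radius`` (px) bounds the attraction range of the field kernel
    m(r) = (r + epsilon)^(-gamma); ``alpha``/``beta`` are the snake tension
    and rigidity, ``step`` the evolution step size, ``tol`` the mean vertex
    displacement (px) below which evolution stops.
    """

    kernel_radius: int = 8
    gamma: float = 2.4
    epsilon: float = 1e-8
    alpha: float = 0.1
    beta: float = 0.5
    step: float = 0.5
    max_iter: int = 300
    tol: float = 0.05

    def __post_init__(self) -> None:
        for name in ("kernel_radius", "gamma", "epsilon", "alpha", "beta", "step", "max_iter", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tol >= 1:
            raise ValueError("tol must be < 1 px")


@dataclass
class LVBPRegion:
    mask: np.ndarray
    contour: np.ndarray
    center: tuple[float, float]


# ---------------------------------------------------------------------------
# Subtraction image and clustering
# ---------------------------------------------------------------------------


def make_subtraction_image(series: MGESeries, selection) -> np.ndarray:
    """Shortest-TE echo minus the LVBP-optimal echo, clipped at zero."""
    if selection.te_lvbp == 0:
        raise ValueError(
            "LVBP-optimal TE equals the shortest TE; the subtraction image is degenerate"
        )
    return np.clip(series.echo(0) - series.echo(selection.te_lvbp), 0.0, None)


def kmeans_cluster(values: np.ndarray, k: int, seed: int, n_restarts: int = 10) -> np.ndarray:
    """k-means labels on a 1-D intensity vector, relabeled by ascending mean.

    Cluster 0 always has the lowest mean intensity; deterministic for a
    fixed seed (k-means++ initialization, ``n_restarts`` restarts).
    """
    from sklearn.cluster import KMeans

    values = np.asarray(values, dtype=float).ravel()
    if len(values) < k or k < 2:
        raise ValueError(f"need at least k={k} >= 2 values, got {len(values)}")
    if len(np.unique(values)) < k:
        raise ValueError(f"fewer than k={k} distinct values; clustering is degenerate")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31))
    raw = km.fit_predict(values[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


def blood_pool_mask(
    subimage: np.ndarray, midwall_contour: np.ndarray, k: int = 3, seed: int = 0
) -> np.ndarray:
    """Central blood-pool mask: lowest-intensity cluster inside the mid-wall
    contour, reduced to the hole-filled connected component holding the
    region centroid.
    """
    enclosed = geo.polygon_mask(subimage.shape, midwall_contour)
    n_inside = int(enclosed.sum())
    if n_inside <= k:
        raise ValueError("mid-wall contour encloses too few pixels for clustering")
    labels = kmeans_cluster(subimage[enclosed], k, seed)
    mask = np.zeros(subimage.shape, dtype=bool)
    mask[enclosed] = labels == 0
    if not mask.any():
        raise ValueError("no blood-pool cluster found; review the mid-wall contour")
    comp, n_comp = ndimage.label(mask)
    centroid = ndimage.center_of_mass(enclosed)
    cr, cc = int(round(centroid[0])), int(round(centroid[1]))
    if comp[cr, cc] > 0:
        keep = comp[cr, cc]
    else:  # centroid not on the retained cluster: fall back to largest component
        keep = int(np.argmax(ndimage.sum(mask, comp, index=range(1, n_comp + 1)))) + 1
    mask = comp == keep
    if not mask.any():
        raise ValueError("blood-pool mask is empty; review seeds/contour")
    return mask


# ---------------------------------------------------------------------------
# Vector field convolution
# ---------------------------------------------------------------------------


def vfc_kernel(params: VFCParams) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) components of the radially attracting VFC kernel."""
    R = int(params.kernel_radius)
    y, x = np.mgrid[-R : R + 1, -R : R + 1].astype(float)
    r = np.hypot(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = (r + params.epsilon) ** (-params.gamma)
        ky = np.where(r > 0, -m * y / r, 0.0)
        kx = np.where(r > 0, -m * x / r, 0.0)
    outside = r > R
    ky[outside] = 0.0
    kx[outside] = 0.0
    return ky, kx


def vfc_field(edge_map: np.ndarray, params: VFCParams) -> np.ndarray:
    """VFC external force field, shape (2, H, W) with (row, col) components.

    field(p) = sum_q edge(q) * K(p - q), i.e. the convolution of the edge
    map with the attracting kernel; equal to the direct double-sum to
    numerical precision.
    """
    edge_map = np.asarray(edge_map, dtype=float)
    if np.any(edge_map < 0):
        raise ValueError("edge map must be non-negative")
    if not np.any(edge_map):
        logger.warning("all-zero edge map: VFC field is identically zero")
        return np.zeros((2,) + edge_map.shape)
    ky, kx = vfc_kernel(params)
    fy = fftconvolve(edge_map, ky, mode="same")
    fx = fftconvolve(edge_map, kx, mode="same")
    return np.stack([fy, fx])


def edge_map(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gradient magnitude of the Gaussian-smoothed image, normalized to [0, 1]."""
    smoothed = ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma)
    gy, gx = np.gradient(smoothed)
    mag = np.hypot(gy, gx)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


# ---------------------------------------------------------------------------
# Snake evolution
# ---------------------------------------------------------------------------


def _internal_matrix(n: int, alpha: float, beta: float, step: float) -> np.ndarray:
    """(I + step*A) for the periodic pentadiagonal internal-energy operator."""
    A = np.zeros((n, n))
    row = np.zeros(n)
    row[0] = 2 * alpha + 6 * beta
    row[1] = -(alpha + 4 * beta)
    row[2] = beta
    row[-1] = -(alpha + 4 * beta)
    row[-2] = beta
    for i in range(n):
        A[i] = np.roll(row, i)
    return np.eye(n) + step * A


def _sample_field(field: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    coords = vertices.T  # (2, n) -> row, col
    fy = ndimage.map_coordinates(field[0], coords, order=1, mode="nearest")
    fx = ndimage.map_coordinates(field[1], coords, order=1, mode="nearest")
    return np.column_stack([fy, fx])


def evolve_snake(init: np.ndarray, field: np.ndarray, params: VFCParams) -> np.ndarray:
    """Evolve a closed snake under internal smoothing and the external field.

    Semi-implicit update (internal forces solved implicitly through the
    periodic pentadiagonal system, external field sampled by bilinear
    interpolation at sub-pixel vertices); vertices are re-sampled to uniform
    arc length at roughly one-pixel spacing every iteration, which makes the
    result independent of the initial vertex count; stops when the mean
    vertex displacement falls below ``tol`` or after ``max_iter`` iterations.
    """
    v = np.asarray(init, dtype=float)
    if v.ndim != 2 or v.shape[0] < 8:
        raise ValueError("initial contour must be closed with at least 8 vertices")

    lu_cache: dict[int, object] = {}

    def _resample_to_spacing(poly: np.ndarray) -> np.ndarray:
        closed = np.vstack([poly, poly[:1]])
        perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
        n = int(np.clip(round(perimeter), 16, 512))
        return geo.resample_closed_polyline(poly, n)

    v = _resample_to_spacing(v)
    for _ in range(params.max_iter):
        n = v.shape[0]
        if n not in lu_cache:
            lu_cache[n] = lu_factor(_internal_matrix(n, params.alpha, params.beta, params.step))
        f = _sample_field(field, v)
        v_new = lu_solve(lu_cache[n], v + params.step * f)
        disp = float(np.mean(np.linalg.norm(v_new - v, axis=1)))
        if abs(geo.polygon_area(v_new)) < 4.0:
            raise RuntimeError("active contour collapsed (area < 4 px)")
        v = _resample_to_spacing(v_new)
        if disp < params.tol:
            break
    return v


# ---------------------------------------------------------------------------
# Part-I orchestration
# ---------------------------------------------------------------------------


def _unit_peak(field: np.ndarray) -> np.ndarray:
    """Scale a VFC field to unit peak magnitude so snake steps are in pixels."""
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def detect_lvbp(
    series: MGESeries,
    composite: CompositeImage,
    rois: ROISet,
    params: VFCParams | None = None,
    k: int = 3,
    seed: int = 0,
    cluster_smooth_sigma: float = 1.0,
) -> LVBPRegion:
    """Full part-I chain: subtraction, clustering, two-stage VFC snakes.

    The first snake starts on the clustered blood-pool boundary and evolves
    against the subtraction-image edge map (central pool shape); the second
    starts on the first result dilated by 2 px and evolves against the
    composite-image edge map, re-joining papillary/trabecular pixels.  The
    intensity clustering runs on a lightly smoothed copy of the subtraction
    image (``cluster_smooth_sigma``) to suppress salt-and-pepper
    misclassification; both snake edge maps use the unsmoothed images.  The
    external fields are rescaled to unit peak magnitude so the evolution
    step size is expressed in pixels.
    """
    params = params or VFCParams()
    sub = make_subtraction_image(series, composite.selection)
    sub_for_clustering = (
        ndimage.gaussian_filter(sub, cluster_smooth_sigma) if cluster_smooth_sigma > 0 else sub
    )
    core = blood_pool_mask(sub_for_clustering, rois.midwall_contour, k=k, seed=seed)

    init1 = geo.mask_boundary_polyline(core)
    n_vertices = max(16, int(round(init1.shape[0])))
    init1 = geo.resample_closed_polyline(init1, n_vertices)
    field1 = _unit_peak(vfc_field(edge_map(sub), params))
    snake1 = evolve_snake(init1, field1, params)

    mask1 = geo.polygon_mask(series.shape, snake1)
    if not mask1.any():
        raise RuntimeError("stage-4 contour encloses no pixels")
    dilated = ndimage.binary_dilation(mask1, ndimage.generate_binary_structure(2, 1), iterations=2)
    init2 = geo.resample_closed_polyline(geo.mask_boundary_polyline(dilated), n_vertices)
    # the step-4 region serves as a mask for the step-5 segmentation: edges
    # outside it (notably the epicardial border) must not capture the snake
    field2 = _unit_peak(vfc_field(edge_map(composite.image) * dilated, params))
    snake2 = evolve_snake(init2, field2, params)

    mask = geo.polygon_mask(series.shape, snake2)
    # keep a single connected pool
    comp, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum(mask, comp, index=range(1, n_comp + 1))
        mask = comp == (int(np.argmax(sizes)) + 1)
    if not mask.any():
        raise RuntimeError("final LVBP contour encloses no pixels")
    mask = _snap_pool_boundary(mask, composite.image)
    center = ndimage.center_of_mass(mask)
    return LVBPRegion(mask=mask, contour=snake2, center=(float(center[0]), float(center[1])))


def _snap_pool_boundary(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    """One-pixel intensity snap of the pool boundary.

    Polygon rasterization of the snake can leave individual bright (blood)
    pixels just outside the pool and dark (wall) pixels just inside.  Each
    boundary pixel is re-assigned to the side whose mean intensity it is
    closer to: adjacent outside pixels brighter than the pool/wall midpoint
    join the pool, inside boundary pixels darker than it leave.
    """
    struct = ndimage.generate_binary_structure(2, 2)
    interior = ndimage.binary_erosion(mask, struct)
    wall_ring = ndimage.binary_dilation(mask, struct, iterations=3) & ~ndimage.binary_dilation(
        mask, struct
    )
    if not interior.any() or not wall_ring.any():
        return mask
    midpoint = 0.5 * (float(image[interior].mean()) + float(image[wall_ring].mean()))
    brighter_pool = image[interior].mean() > image[wall_ring].mean()
    outer_band = ndimage.binary_dilation(mask, struct) & ~mask
    inner_band = mask & ~interior
    snapped = mask.copy()
    if brighter_pool:
        snapped[outer_band & (image > midpoint)] = True
        snapped[inner_band & (image < midpoint)] = False
    else:
        snapped[outer_band & (image < midpoint)] = True
        snapped[inner_band & (image > midpoint)] = False
    snapped = ndimage.binary_fill_holes(snapped)
    comp, n_comp = ndimage.label(snapped)
    if n_comp > 1:
        sizes = ndimage.sum(snapped, comp, index=range(1, n_comp + 1))
        snapped = comp == (int(np.argmax(sizes)) + 1)
    return snapped if snapped.any() else mask
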