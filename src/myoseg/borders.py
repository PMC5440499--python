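"""Myocardial border determination (segmentation part II).

Around the detected LV blood pool a grid of one-pixel-thick expansion layers
by angular radial segments is built on the composite image (72 segments on
mid/basal slices, 40 apical; expansion limited to 14 mm on mid/basal and
8 mm on apical slices, beyond any plausible wall thickness).  Per radial
segment the epicardial border grows outward while the coefficient of
variance (CoV = SD/mean) of the cumulative accepted intensities stays below
20%.  The low-contrast anterior/septal/posterior borders are refined by
two-cluster k-means (keeping the radially inner cluster), sparse false outer
layers are removed by per-sector occupancy cut-offs (70%, 40% lateral), the
layer-count profile is smoothed to a maximum neighbor difference of two,
and the final endo/epicardial contours are selected among +/-2-layer global
shifts by minimizing the scaled-IQR intensity-outlier ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from . import _geometry as geo
from .composite import SECTOR_GROUPS, SECTOR_NAMES, CompositeImage
from .lvbp import LVBPRegion, kmeans_cluster

logger = logging.getLogger(__name__)


@dataclass
class BorderConfig:
    cov_threshold: float = 0.20
    cutoff_main: float = 0.70
    cutoff_lateral: float = 0.40
    neighbor_max_diff: int = 2
    iqr_factor: float = 0.9825
    extra_layers: int = 2
    expansion_limit_mm: dict = field(default_factory=lambda: {"basal": 14.0, "mid": 14.0, "apical": 8.0})
    n_radial: dict = field(default_factory=lambda: {"basal": 72, "mid": 72, "apical": 40})

    def __post_init__(self) -> None:
        if not (0 < self.cov_threshold < 1):
            raise ValueError("cov_threshold must be in (0, 1)")
        for c in (self.cutoff_main, self.cutoff_lateral):
            if not (0 < c < 1):
                raise ValueError("occupancy cutoffs must be in (0, 1)")
        if any(v <= 0 for v in self.expansion_limit_mm.values()):
            raise ValueError("expansion limits must be positive")


@dataclass
class RadialLayerGrid:
    """Per-radial-segment, per-one-pixel-layer pixel cells around the LVBP."""

    n_segments: int
    n_layers: int
    cells: list  # cells[s][l] = (rows, cols), l in 1..n_layers (index 0 unused)
    intensity: np.ndarray
    lvbp_mask: np.ndarray
    center: tuple[float, float]
    sector_group: np.ndarray  # per-segment group name array
    slice_level: str
    anchor_deg: float

    def cell_count(self, s: int, l: int) -> int:
        return len(self.cells[s][l][0])

    def cell_values(self, s: int, l: int) -> np.ndarray:
        rr, cc = self.cells[s][l]
        return self.intensity[rr, cc]


@dataclass
class LayerCounts:
    accepted: np.ndarray
    start_pair: tuple[int, int] | None = None

    def copy(self) -> "LayerCounts":
        return LayerCounts(self.accepted.copy(), self.start_pair)


@dataclass
class MyocardialContours:
    endo_mask: np.ndarray
    epi_mask: np.ndarray
    myo_mask: np.ndarray
    endo_polyline: np.ndarray
    epi_polyline: np.ndarray
    excluded_outliers: np.ndarray
    shifts: tuple[int, int] = (0, 0)
    outlier_ratio: float = 0.0


# ---------------------------------------------------------------------------
# Step 6: layer grid
# ---------------------------------------------------------------------------


def build_layer_grid(
    lvbp: LVBPRegion,
    composite: CompositeImage,
    slice_level: str,
    cfg: BorderConfig | None = None,
    pixel_spacing: float = 1.56,
    anchor_deg: float = 135.0,
) -> RadialLayerGrid:
    """One-pixel-thick Euclidean expansion layers x angular radial segments.

    Layer l holds the pixels at (Euclidean) distance (l-1, l] from the LVBP
    mask; radial segments are equal angular bins about the LVBP centroid
    anchored at the anterior insertion ray so they nest exactly inside the
    anatomical sectors.
    """
    cfg = cfg or BorderConfig()
    mask = lvbp.mask
    h, w = mask.shape
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("LVBP mask touches the image border; cannot build expansion layers")
    n_layers = int(np.ceil(cfg.expansion_limit_mm[slice_level] / pixel_spacing))
    n_segments = int(cfg.n_radial[slice_level])
    dist = ndimage.distance_transform_edt(~mask)
    theta = geo.angle_map(mask.shape, lvbp.center)
    span = 360.0 / n_segments
    seg_map = (geo.wrap_deg(theta - anchor_deg) // span).astype(int)
    cells = [[(np.array([], int), np.array([], int)) for _ in range(n_layers + 1)] for _ in range(n_segments)]
    outside = ~mask & (dist <= n_layers)
    rr, cc = np.nonzero(outside)
    layer_idx = np.ceil(dist[rr, cc]).astype(int)
    seg_idx = seg_map[rr, cc]
    for s in range(n_segments):
        sel_s = seg_idx == s
        for l in range(1, n_layers + 1):
            sel = sel_s & (layer_idx == l)
            cells[s][l] = (rr[sel], cc[sel])
    sector_names = SECTOR_NAMES[slice_level]
    per_sector = n_segments // len(sector_names)
    groups = np.array(
        [SECTOR_GROUPS[sector_names[min(s // per_sector, len(sector_names) - 1)]] for s in range(n_segments)]
    )
    return RadialLayerGrid(
        n_segments=n_segments,
        n_layers=n_layers,
        cells=cells,
        intensity=np.asarray(composite.image, dtype=float),
        lvbp_mask=mask,
        center=lvbp.center,
        sector_group=groups,
        slice_level=slice_level,
        anchor_deg=anchor_deg,
    )


# ---------------------------------------------------------------------------
# Step 7: CoV-driven expansion
# ---------------------------------------------------------------------------


def _cov(values: np.ndarray) -> float | None:
    """SD/mean; None when undefined (empty or non-positive mean)."""
    if values.size == 0:
        return None
    m = float(values.mean())
    if m <= 0:
        return None
    return float(values.std() / m)


def cov_expand(grid: RadialLayerGrid, cfg: BorderConfig | None = None) -> LayerCounts:
    """Expand each radial segment until the cumulative CoV exceeds the threshold.

    The pair of adjacent segments with the smallest innermost-layer CoV is
    the starting point; expansion then propagates circumferentially as two
    fronts.  A segment accepts layer l if the CoV of its cumulative pixels
    including layer l stays at or below the threshold; undefined CoV (empty
    cell or non-positive mean) is a stop condition.
    """
    cfg = cfg or BorderConfig()
    n = grid.n_segments
    inner_cov = np.full(n, np.inf)
    for s in range(n):
        c = _cov(grid.cell_values(s, 1))
        inner_cov[s] = np.inf if c is None else c
    pair_scores = np.array([inner_cov[s] + inner_cov[(s + 1) % n] for s in range(n)])
    s0 = int(np.argmin(pair_scores))
    order = [s0, (s0 + 1) % n]
    left, right = s0 - 1, s0 + 2
    while len(order) < n:  # two fronts advancing around the ring
        if len(order) < n:
            order.append(left % n)
            left -= 1
        if len(order) < n:
            order.append(right % n)
            right += 1
    accepted = np.zeros(n, dtype=int)
    for s in order:
        cum = []
        for l in range(1, grid.n_layers + 1):
            vals = grid.cell_values(s, l)
            if vals.size == 0:
                # a narrow angular bin may simply not intersect this
                # one-pixel ring: nothing to test, expansion continues
                accepted[s] = l
                continue
            candidate = np.concatenate(cum + [vals])
            c = _cov(candidate)
            if c is None:
                logger.debug("segment %d stops at layer %d: CoV undefined", s, l)
                break
            if c > cfg.cov_threshold:
                break
            cum.append(vals)
            accepted[s] = l
    return LayerCounts(accepted=accepted, start_pair=(s0, (s0 + 1) % n))


# ---------------------------------------------------------------------------
# Step 8: k-means refinement (anterior / septal / posterior)
# ---------------------------------------------------------------------------

_REFINE_GROUPS = ("anterior", "septal", "posterior")


def kmeans_refine(
    grid: RadialLayerGrid,
    counts: LayerCounts,
    seed: int = 0,
    cfg: BorderConfig | None = None,
) -> LayerCounts:
    """Two-cluster intensity refinement of the low-contrast sector borders.

    Pixels of the CoV-accepted region in the anterior/septal/posterior
    sectors are split into two intensity clusters and the radially inner
    cluster is kept; per-segment accepted counts become the outermost layer
    whose pixels are still (majority) retained.  The step is a no-op when
    the split is degenerate: fewer than two distinct intensities, cluster
    separation below the CoV threshold relative to the pooled mean, or no
    radial structure (mean layer depths closer than one layer) - the latter
    two guards keep noise-only splits of a homogeneous wall from eroding it.
    Lateral sectors are never modified.
    """
    cfg = cfg or BorderConfig()
    out = counts.copy()
    scope = [s for s in range(grid.n_segments) if grid.sector_group[s] in _REFINE_GROUPS]
    vals, layers, owners = [], [], []
    for s in scope:
        for l in range(1, counts.accepted[s] + 1):
            v = grid.cell_values(s, l)
            vals.append(v)
            layers.append(np.full(v.size, l))
            owners.append(np.full(v.size, s))
    if not vals:
        return out
    vals = np.concatenate(vals)
    layers = np.concatenate(layers)
    owners = np.concatenate(owners)
    if vals.size < 4 or len(np.unique(vals)) < 2:
        logger.info("k-means refinement skipped: degenerate intensity distribution")
        return out
    try:
        labels = kmeans_cluster(vals, 2, seed)
    except ValueError:
        logger.info("k-means refinement skipped: clustering degenerate")
        return out
    mean_int = np.array([vals[labels == c].mean() for c in (0, 1)])
    mean_layer = np.array([layers[labels == c].mean() for c in (0, 1)])
    pooled = float(vals.mean())
    if pooled <= 0 or abs(mean_int[1] - mean_int[0]) / pooled < cfg.cov_threshold:
        logger.info("k-means refinement skipped: clusters not separated beyond the CoV threshold")
        return out
    frac = np.bincount(labels, minlength=2) / labels.size
    if frac.min() < 0.05:
        # a split that isolates a handful of stray pixels is not a tissue
        # boundary; both clusters must represent substantial areas
        logger.info("k-means refinement skipped: minority cluster below 5%% of pixels")
        return out
    if abs(mean_layer[1] - mean_layer[0]) < 1.0:
        logger.info("k-means refinement skipped: clusters show no radial structure")
        return out
    # the inner cluster is the tissue adjacent to the blood pool: the cluster
    # holding the majority of first-layer pixels (robust when a few stray
    # blood pixels sit at layer 1); falls back to the smaller mean layer
    first_layer = labels[layers == 1]
    if first_layer.size:
        inner = int(np.bincount(first_layer, minlength=2).argmax())
    else:
        inner = int(np.argmin(mean_layer))
    retained = labels == inner
    for s in scope:
        new_acc = 0
        for l in range(1, counts.accepted[s] + 1):
            sel = (owners == s) & (layers == l)
            if sel.sum() == 0:  # empty ring cell: vacuously retained
                new_acc = l
                continue
            if retained[sel].mean() < 0.5:
                break
            new_acc = l
        out.accepted[s] = new_acc
    return out


# ---------------------------------------------------------------------------
# Step 9: occupancy correction and neighbor smoothing
# ---------------------------------------------------------------------------


def correct_false_layers(
    grid: RadialLayerGrid, counts: LayerCounts, cfg: BorderConfig | None = None
) -> LayerCounts:
    """Remove sparse outer layers per sector position (70% cutoff; 40% lateral).

    Within each anatomical sector group the outermost accepted layer is
    eliminated while its accepted pixel count falls below the cutoff times
    the largest full-layer pixel count of that group (a sparsely accepted
    outer layer is a false area outside the myocardium).  Individual radial
    segments hold only 1-2 pixels per one-pixel layer, so occupancy is only
    meaningful at the sector-group level.
    """
    cfg = cfg or BorderConfig()
    out = counts.copy()
    for group in np.unique(grid.sector_group):
        segs = [s for s in range(grid.n_segments) if grid.sector_group[s] == group]
        cutoff = cfg.cutoff_lateral if group == "lateral" else cfg.cutoff_main
        top0 = max((int(counts.accepted[s]) for s in segs), default=0)
        if top0 == 0:
            continue
        # reference: the fullest layer among those actually in play
        max_full = max(sum(grid.cell_count(s, l) for s in segs) for l in range(1, top0 + 1))
        if max_full == 0:
            continue
        while True:
            top = max((out.accepted[s] for s in segs), default=0)
            if top <= 0:
                break
            accepted_at_top = sum(
                grid.cell_count(s, top) for s in segs if out.accepted[s] >= top
            )
            if accepted_at_top >= cutoff * max_full:
                break
            for s in segs:
                if out.accepted[s] >= top:
                    out.accepted[s] = top - 1
    return out


def limit_neighbor_difference(counts: LayerCounts, cfg: BorderConfig | None = None) -> LayerCounts:
    """Clip circular layer counts so adjacent segments differ by at most 2.

    Relaxation a[s] <- min(a[s], a[s-1]+2, a[s+1]+2) iterated to its fixed
    point; only ever reduces counts, and the fixed point is independent of
    sweep order (it equals min_t a0[t] + 2*d_ring(s, t)).
    """
    cfg = cfg or BorderConfig()
    a = counts.accepted.astype(int).copy()
    d = int(cfg.neighbor_max_diff)
    changed = True
    while changed:
        changed = False
        bound = np.minimum(np.roll(a, 1), np.roll(a, -1)) + d
        new = np.minimum(a, bound)
        if np.any(new < a):
            a = new
            changed = True
    return LayerCounts(accepted=a)


# ---------------------------------------------------------------------------
# Step 10: border optimization
# ---------------------------------------------------------------------------


def _endo_rings(lvbp_mask: np.ndarray, n: int) -> list[np.ndarray]:
    """Ring i (1-based) = the i-th one-pixel erosion shell inside the LVBP."""
    din = ndimage.distance_transform_edt(lvbp_mask)
    return [(din > i - 1) & (din <= i) & lvbp_mask for i in range(1, n + 1)]


def optimize_borders(
    grid: RadialLayerGrid,
    counts: LayerCounts,
    lvbp: LVBPRegion,
    composite: CompositeImage,
    cfg: BorderConfig | None = None,
    seed: int = 0,
) -> MyocardialContours:
    """Select among global +/-2-layer endo/epi shifts by outlier ratio.

    For each shift pair (d_endo, d_epi) in {-2..2}^2 the candidate
    myocardium is assembled (d_endo > 0 adds erosion shells of the LVBP,
    i.e. moves the endocardial border inward toward the pool; d_endo < 0
    drops the innermost expansion layers; d_epi shifts every segment's
    accepted count).  Border homogeneity is tested relative to the whole
    myocardium: the intensity quartiles of the *initial* (0, 0) annulus fix
    the outlier bounds [f*Q1, Q3/f] (f = 0.9825) for every candidate, so a
    candidate stuffed with non-myocardial tissue cannot drag the quartiles
    with it.  Pixels in the candidate's border layers (its innermost and
    outermost rings - the only pixels the shift decision controls) falling
    beyond the bounds are the outliers; the candidate minimizing the ratio
    of outlier pixels to total myocardial pixels wins (ties: nearest (0,0),
    then smaller area).  The winner's outliers, indicating area outside or
    on the edge of the myocardium, are excluded from the final mask; the
    complementary correction is applied at the epicardial edge, where pixels
    of the first ring beyond the accepted border whose intensity lies
    within the myocardial IQR bounds are myocardium straddled by the
    discrete one-pixel layers and are re-included.
    """
    cfg = cfg or BorderConfig()
    img = grid.intensity
    shape = img.shape
    e = int(cfg.extra_layers)
    rings = _endo_rings(lvbp.mask, e)
    if counts.accepted.max() == 0:
        raise ValueError("no accepted layers: initial annulus is empty")

    def candidate_masks(d_endo: int, d_epi: int):
        l_lo = 1 + max(0, -d_endo)
        epi_part = np.zeros(shape, dtype=bool)
        outer_ring = np.zeros(shape, dtype=bool)
        inner_ring = np.zeros(shape, dtype=bool)
        for s in range(grid.n_segments):
            top = min(counts.accepted[s] + d_epi, grid.n_layers)
            if top < l_lo:
                continue
            for l in range(l_lo, top + 1):
                rr, cc = grid.cells[s][l]
                epi_part[rr, cc] = True
                if l == top:
                    outer_ring[rr, cc] = True
                if l == l_lo and d_endo <= 0:
                    inner_ring[rr, cc] = True
        endo_part = np.zeros(shape, dtype=bool)
        if d_endo > 0:
            for i in range(min(d_endo, e)):
                endo_part |= rings[i]
            inner_ring = rings[min(d_endo, e) - 1].copy()
        myo = epi_part | endo_part
        return myo, inner_ring, outer_ring

    initial_myo, _, _ = candidate_masks(0, 0)
    if initial_myo.sum() < 8:
        raise ValueError("initial annulus is degenerate")
    q1, q3 = np.percentile(img[initial_myo], [25, 75])
    lo, hi = cfg.iqr_factor * q1, q3 / cfg.iqr_factor

    best = None
    for d_endo, d_epi in product(range(-e, e + 1), repeat=2):
        myo, inner_ring, outer_ring = candidate_masks(d_endo, d_epi)
        n_total = int(myo.sum())
        if n_total < 8:
            logger.debug("candidate (%d, %d) skipped: degenerate annulus", d_endo, d_epi)
            continue
        border = (inner_ring | outer_ring) & myo
        outlier_mask = border & ((img < lo) | (img > hi))
        ratio = float(outlier_mask.sum()) / n_total
        key = (ratio, abs(d_endo) + abs(d_epi), n_total)
        if best is None or key < best[0]:
            best = (key, (d_endo, d_epi), myo, outlier_mask)
    if best is None:
        raise ValueError("no viable endo/epi shift candidate")
    key, (d_endo, d_epi), myo, outlier_mask = best

    excluded = outlier_mask
    myo_final = myo & ~excluded
    # epicardial edge inclusion: myocardium-like pixels of the next ring
    for s in range(grid.n_segments):
        l_next = min(counts.accepted[s] + d_epi, grid.n_layers) + 1
        if l_next < 1 or l_next > grid.n_layers:
            continue
        rr, cc = grid.cells[s][l_next]
        if rr.size == 0:
            continue
        ok = (img[rr, cc] >= lo) & (img[rr, cc] <= hi)
        myo_final[rr[ok], cc[ok]] = True
        myo[rr[ok], cc[ok]] = True

    endo_interior = lvbp.mask.copy()
    if d_endo > 0:
        for i in range(min(d_endo, e)):
            endo_interior &= ~rings[i]
    elif d_endo < 0:
        dist = ndimage.distance_transform_edt(~lvbp.mask)
        endo_interior |= (dist > 0) & (dist <= -d_endo)
    epi_interior = ndimage.binary_fill_holes(endo_interior | myo)
    return MyocardialContours(
        endo_mask=endo_interior,
        epi_mask=epi_interior,
        myo_mask=myo_final,
        endo_polyline=geo.mask_boundary_polyline(endo_interior),
        epi_polyline=geo.mask_boundary_polyline(epi_interior),
        excluded_outliers=excluded,
        shifts=(d_endo, d_epi),
        outlier_ratio=key[0],
    )


def delineate_borders(
    lvbp: LVBPRegion,
    composite: CompositeImage,
    slice_level: str,
    pixel_spacing: float,
    anchor_deg: float,
    cfg: BorderConfig | None = None,
    seed: int = 0,
) -> tuple[MyocardialContours, RadialLayerGrid, LayerCounts]:
    """Full part-II chain (steps 6-10)."""
    cfg = cfg or BorderConfig()
    grid = build_layer_grid(lvbp, composite, slice_level, cfg, pixel_spacing, anchor_deg)
    counts = cov_expand(grid, cfg)
    counts = kmeans_refine(grid, counts, seed=seed, cfg=cfg)
    counts = correct_false_layers(grid, counts, cfg)
    counts = limit_neighbor_difference(counts, cfg)
    contours = optimize_borders(grid, counts, lvbp, composite, cfg, seed=seed)
    return contours, grid, counts
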