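"""Contrast-optimized composite image generation.

Per-echo contrast-to-noise ratios between the LV myocardium and each of its
surroundings (LV blood pool, RV blood pool, lung) are computed as

    CNR = NF * |SI_s - SI_m| / sigma_b

where SI_s is the mean intensity of the surrounding-region ROI, SI_m the
mean intensity sampled along the mid-wall contour, sigma_b the standard
deviation of an air-background ROI and NF a configurable noise factor
(NF cancels in the argmax over echoes, so it does not affect which echoes
are selected).  The composite is the weighted sum of the CNR-optimal echoes:
equal thirds for three distinct echoes, 2:1 when one echo is optimal for two
regions, weight one for a single echo.

Two ROI-placement methods are provided.  Method 1 derives everything from a
mid-wall contour, one air point and the anterior RV-LV insertion point, by
sector-junction extrapolation.  Method 2 uses manually contoured RVBP and
lung regions; the insertion points are taken from the RVBP contour endpoints
and the lung ROI is auto-picked among candidate positions as the one with
minimum intensity variance on the shortest-TE image (avoiding vessels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line

from . import _geometry as geo
from .mge_io import ManualSeeds, MGESeries

REGIONS = ("LVBP", "RVBP", "lung")

SECTOR_NAMES = {
    # counter-clockwise from the anterior insertion ray
    "apical": ("septal", "inferior", "lateral", "anterior"),
    "mid": ("anteroseptal", "inferoseptal", "inferior", "inferolateral", "anterolateral", "anterior"),
    "basal": ("anteroseptal", "inferoseptal", "inferior", "inferolateral", "anterolateral", "anterior"),
}

#: Anatomical grouping used by the border-refinement steps.  "posterior" maps
#: to the inferior/inferolateral sectors; the lateral group faces the lung.
SECTOR_GROUPS = {
    "anterior": "anterior",
    "anteroseptal": "septal",
    "inferoseptal": "septal",
    "septal": "septal",
    "inferior": "posterior",
    "inferolateral": "posterior",
    "lateral": "lateral",
    "anterolateral": "lateral",
}


@dataclass
class CompositeConfig:
    nf: float = 1.0
    roi_radius_px: float = 3.0
    air_box_px: int = 5
    tie_break: str = "shortest"
    lung_candidates: int = 8
    #: method-1 extrapolation: ROI center distance from the LV centroid as a
    #: multiple of the local mid-wall radius along the junction ray
    extrapolation_factor: float = 1.9


@dataclass
class ROISet:
    """Surrounding-tissue ROIs plus the angular sector frame of the slice."""

    midwall_contour: np.ndarray
    midwall_band: np.ndarray
    roi_lvbp: np.ndarray
    roi_rvbp: np.ndarray
    roi_lung: np.ndarray
    roi_air: np.ndarray
    insertion_anterior: tuple[float, float]
    insertion_inferior: tuple[float, float]
    insertion_anterior_deg: float
    center: tuple[float, float]
    sector_labels: np.ndarray
    sector_names: tuple[str, ...]
    slice_level: str

    def __post_init__(self) -> None:
        rois = [self.roi_lvbp, self.roi_rvbp, self.roi_lung, self.roi_air]
        total = sum(r.astype(int) for r in rois)
        if np.any(total > 1):
            raise ValueError("ROIs must be pairwise disjoint")


@dataclass
class CNRRecord:
    te: float
    te_index: int
    region: str
    si_s: float
    si_m: float
    sigma_b: float
    nf: float

    @property
    def cnr(self) -> float:
        return self.nf * abs(self.si_s - self.si_m) / self.sigma_b


@dataclass
class TESelection:
    te_lvbp: int
    te_rvbp: int
    te_lung: int
    weights: dict  # te_index -> weight

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()))
        if not (1 <= len(w) <= 3) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must cover 1-3 unique echoes and sum to 1")


@dataclass
class CompositeImage:
    image: np.ndarray
    selection: TESelection
    cnr_table: list = field(default_factory=list)
    cnr_gain_pct: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Shared ROI helpers
# ---------------------------------------------------------------------------


def _midwall_band(shape: tuple[int, int], polyline: np.ndarray) -> np.ndarray:
    """One-pixel-wide sampling band along the mid-wall polyline."""
    band = np.zeros(shape, dtype=bool)
    verts = np.round(np.vstack([polyline, polyline[:1]])).astype(int)
    for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        band[rr[keep], cc[keep]] = True
    return band


def _sector_label_map(
    shape: tuple[int, int], center: tuple[float, float], theta_a: float, slice_level: str
) -> tuple[np.ndarray, tuple[str, ...]]:
    names = SECTOR_NAMES[slice_level]
    span = 360.0 / len(names)
    theta = geo.angle_map(shape, center)
    labels = (geo.wrap_deg(theta - theta_a) // span).astype(int)
    return labels, names


def _radius_at(polyline: np.ndarray, center: tuple[float, float], theta: float) -> float:
    """Mid-wall radius at angle ``theta`` by nearest-angle interpolation."""
    angles = geo.angle_deg(polyline, center)
    radii = np.hypot(polyline[:, 0] - center[0], polyline[:, 1] - center[1])
    order = np.argsort(angles)
    a, r = angles[order], radii[order]
    a_ext = np.concatenate([a - 360.0, a, a + 360.0])
    r_ext = np.concatenate([r, r, r])
    return float(np.interp(geo.wrap_deg(theta), a_ext, r_ext))


def _roi_disc(shape, center, radius, name: str) -> np.ndarray:
    r0, c0 = center
    if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
        raise ValueError(f"{name} ROI center {center} falls outside image bounds")
    mask = geo.disc_mask(shape, center, radius)
    if not mask.any():
        raise ValueError(f"{name} ROI is empty")
    return mask


def _air_box(shape, air_point, size) -> np.ndarray:
    box = geo.box_mask(shape, air_point, size)
    if not box.any():
        raise ValueError("air ROI is empty / outside image bounds")
    return box


# ---------------------------------------------------------------------------
# Method 1
# ---------------------------------------------------------------------------


def place_rois_method1(
    series: MGESeries, seeds: ManualSeeds, config: CompositeConfig | None = None
) -> ROISet:
    """Sector-junction ROI placement from a single insertion point.

    The wall band is divided into 4 (apical) or 6 (mid/basal) angular
    sectors anchored at the anterior insertion ray, counting counter-
    clockwise with the septum following the insertion (standard short-axis
    orientation, RV leftward).  RVBP and lung ROIs are extrapolated along the
    anteroseptal/inferoseptal and inferolateral/anterolateral junction rays.
    """
    if seeds.method != 1:
        raise ValueError("seeds.method must be 1")
    config = config or CompositeConfig()
    shape = series.shape
    center = geo.polygon_centroid(seeds.midwall_polyline)
    theta_a = float(geo.angle_deg(np.array(seeds.insertion_point), center)[0])
    labels, names = _sector_label_map(shape, center, theta_a, seeds.slice_level)
    roi_lvbp = _roi_disc(shape, (round(center[0]), round(center[1])), config.roi_radius_px, "LVBP")
    if seeds.slice_level == "apical":
        roi_rvbp = _roi_disc(shape, seeds.apical_rvbp_point, config.roi_radius_px, "RVBP")
        roi_lung = _roi_disc(shape, seeds.apical_lung_point, config.roi_radius_px, "lung")
        theta_inferior = theta_a + 90.0  # end of the (single) septal sector
    else:
        # junction rays: anteroseptal|inferoseptal and inferolateral|anterolateral
        rvbp_center = np.asarray(center) + config.extrapolation_factor * _radius_at(
            seeds.midwall_polyline, center, theta_a + 60.0
        ) * geo.unit_vector(theta_a + 60.0)
        lung_center = np.asarray(center) + config.extrapolation_factor * _radius_at(
            seeds.midwall_polyline, center, theta_a + 240.0
        ) * geo.unit_vector(theta_a + 240.0)
        try:
            roi_rvbp = _roi_disc(shape, tuple(rvbp_center), config.roi_radius_px, "RVBP")
        except ValueError as exc:
            raise ValueError(f"anteroseptal/inferoseptal junction extrapolation failed: {exc}")
        try:
            roi_lung = _roi_disc(shape, tuple(lung_center), config.roi_radius_px, "lung")
        except ValueError as exc:
            raise ValueError(f"inferolateral/anterolateral junction extrapolation failed: {exc}")
        theta_inferior = theta_a + 120.0  # end of the septum
    roi_air = _air_box(shape, seeds.air_point, config.air_box_px)
    insertion_inferior = tuple(
        np.asarray(center)
        + _radius_at(seeds.midwall_polyline, center, theta_inferior) * geo.unit_vector(theta_inferior)
    )
    return ROISet(
        midwall_contour=np.asarray(seeds.midwall_polyline, dtype=float),
        midwall_band=_midwall_band(shape, seeds.midwall_polyline),
        roi_lvbp=roi_lvbp,
        roi_rvbp=roi_rvbp,
        roi_lung=roi_lung,
        roi_air=roi_air,
        insertion_anterior=tuple(np.asarray(seeds.insertion_point, dtype=float)),
        insertion_inferior=insertion_inferior,
        insertion_anterior_deg=theta_a,
        center=center,
        sector_labels=labels,
        sector_names=names,
        slice_level=seeds.slice_level,
    )


# ---------------------------------------------------------------------------
# Method 2
# ---------------------------------------------------------------------------


def _lung_candidates(
    lung_polyline: np.ndarray, shape, n_candidates: int, roi_radius: float
) -> list[tuple[int, int]]:
    mask = geo.polygon_mask(shape, lung_polyline)
    if not mask.any():
        raise ValueError("lung contour encloses no pixels")
    edt = ndimage.distance_transform_edt(mask)
    centroid = np.array(ndimage.center_of_mass(mask))
    rr, cc = np.nonzero(edt >= roi_radius + 1.0)
    if len(rr) == 0:
        raise ValueError("lung contour too small to place an ROI")
    angles = geo.angle_deg(np.column_stack([rr, cc]), tuple(centroid))
    bins = (angles // (360.0 / n_candidates)).astype(int)
    candidates = []
    for b in range(n_candidates):
        sel = bins == b
        if not sel.any():
            continue
        idx = np.argmax(edt[rr[sel], cc[sel]])
        candidates.append((int(rr[sel][idx]), int(cc[sel][idx])))
    if not candidates:
        raise ValueError("no valid lung ROI candidate positions")
    return candidates


def _rvbp_center(series: MGESeries, rvbp_polyline: np.ndarray) -> tuple[float, float]:
    """Center of the RV blood pool enclosed by the RVBP contour.

    The open contour is closed by its end chord, which also sweeps in the
    gap toward the septum; the pool itself is the bright compartment on the
    shortest-TE image, so the centroid is taken over the brighter of two
    intensity clusters inside the closed region.
    """
    region = geo.polygon_mask(series.shape, rvbp_polyline)
    if not region.any():
        raise ValueError("RVBP contour encloses no pixels")
    shortest = series.echo(0)
    vals = shortest[region]
    if len(np.unique(vals)) >= 2:
        lo, hi = float(vals.min()), float(vals.max())
        thresh = 0.5 * (lo + hi)
        bright = region & (shortest > thresh)
        if bright.any():
            region = bright
    rr, cc = np.nonzero(region)
    return float(rr.mean()), float(cc.mean())


def place_rois_method2(
    series: MGESeries, seeds: ManualSeeds, config: CompositeConfig | None = None
) -> ROISet:
    """ROI placement from contoured RVBP and lung regions.

    The anterior and inferior insertion points are the first and last
    endpoints of the (open) RVBP contour; the LVBP ROI sits at the mid-wall
    contour centroid, the RVBP ROI at the centroid of the enclosed RVBP
    region, and the lung ROI at the candidate position with minimum
    shortest-TE intensity variance (an area without blood vessels).
    """
    if seeds.method != 2:
        raise ValueError("seeds.method must be 2")
    config = config or CompositeConfig()
    shape = series.shape
    center = geo.polygon_centroid(seeds.midwall_polyline)
    anterior = tuple(np.asarray(seeds.rvbp_polyline[0], dtype=float))
    inferior = tuple(np.asarray(seeds.rvbp_polyline[-1], dtype=float))
    theta_a = float(geo.angle_deg(np.array(anterior), center)[0])
    labels, names = _sector_label_map(shape, center, theta_a, seeds.slice_level)
    roi_lvbp = _roi_disc(shape, (round(center[0]), round(center[1])), config.roi_radius_px, "LVBP")
    rv_centroid = _rvbp_center(series, seeds.rvbp_polyline)
    roi_rvbp = _roi_disc(
        shape, (round(rv_centroid[0]), round(rv_centroid[1])), config.roi_radius_px, "RVBP"
    )
    candidates = _lung_candidates(
        seeds.lung_polyline, shape, config.lung_candidates, config.roi_radius_px
    )
    shortest = series.echo(0)
    variances = []
    for cand in candidates:
        disc = geo.disc_mask(shape, cand, config.roi_radius_px)
        variances.append(float(np.var(shortest[disc])))
    best = candidates[int(np.argmin(variances))]
    roi_lung = _roi_disc(shape, best, config.roi_radius_px, "lung")
    roi_air = _air_box(shape, seeds.air_point, config.air_box_px)
    return ROISet(
        midwall_contour=np.asarray(seeds.midwall_polyline, dtype=float),
        midwall_band=_midwall_band(shape, seeds.midwall_polyline),
        roi_lvbp=roi_lvbp,
        roi_rvbp=roi_rvbp,
        roi_lung=roi_lung,
        roi_air=roi_air,
        insertion_anterior=anterior,
        insertion_inferior=inferior,
        insertion_anterior_deg=theta_a,
        center=center,
        sector_labels=labels,
        sector_names=names,
        slice_level=seeds.slice_level,
    )


def place_rois(series: MGESeries, seeds: ManualSeeds, config: CompositeConfig | None = None) -> ROISet:
    if seeds.method == 1:
        return place_rois_method1(series, seeds, config)
    return place_rois_method2(series, seeds, config)


# ---------------------------------------------------------------------------
# CNR, TE selection and compositing
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-12


def _sigma_b(image: np.ndarray, roi_air: np.ndarray) -> float:
    vals = image[roi_air]
    if vals.size == 0:
        raise ValueError("air ROI is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sd <= 0.0:
        warnings.warn("air ROI has zero variance; substituting a tiny sigma_b floor")
        return _SIGMA_FLOOR
    return sd


def _sigma_b_pooled(series: MGESeries, roi_air: np.ndarray) -> float:
    """Air-background SD pooled over all echoes.

    Receiver noise does not depend on the echo time, so pooling the air ROI
    across the series gives a far more stable estimate than the handful of
    pixels of a single echo.
    """
    vals = np.concatenate([series.echo(i)[roi_air] for i in range(series.n_echoes)])
    if vals.size == 0:
        raise ValueError("air ROI is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sd <= 0.0:
        warnings.warn("air ROI has zero variance; substituting a tiny sigma_b floor")
        return _SIGMA_FLOOR
    return sd


def compute_cnr(series: MGESeries, rois: ROISet, nf: float = 1.0) -> list[CNRRecord]:
    """One CNR record per (echo, surrounding region)."""
    region_masks = {"LVBP": rois.roi_lvbp, "RVBP": rois.roi_rvbp, "lung": rois.roi_lung}
    for name, mask in list(region_masks.items()) + [("air", rois.roi_air), ("mid-wall", rois.midwall_band)]:
        if not mask.any():
            raise ValueError(f"ROI '{name}' is empty")
    records = []
    sb = _sigma_b_pooled(series, rois.roi_air)
    for i, te in enumerate(series.te_list):
        img = series.echo(i)
        si_m = float(img[rois.midwall_band].mean())
        for region, mask in region_masks.items():
            records.append(
                CNRRecord(
                    te=float(te), te_index=i, region=region,
                    si_s=float(img[mask].mean()), si_m=si_m, sigma_b=sb, nf=nf,
                )
            )
    return records


def select_optimal_tes(cnr_table: Sequence[CNRRecord]) -> TESelection:
    """Per region, the echo with maximal CNR; ties go to the shortest TE."""
    best = {}
    for region in REGIONS:
        recs = [r for r in cnr_table if r.region == region]
        if not recs:
            raise ValueError(f"CNR table has no records for region {region}")
        recs.sort(key=lambda r: (-r.cnr, r.te))
        best[region] = recs[0].te_index
    chosen = [best["LVBP"], best["RVBP"], best["lung"]]
    unique = sorted(set(chosen))
    if len(unique) == 3:
        weights = {i: 1.0 / 3.0 for i in unique}
    elif len(unique) == 2:
        counts = {i: chosen.count(i) for i in unique}
        weights = {i: (2.0 / 3.0 if counts[i] == 2 else 1.0 / 3.0) for i in unique}
    else:
        weights = {unique[0]: 1.0}
    return TESelection(te_lvbp=best["LVBP"], te_rvbp=best["RVBP"], te_lung=best["lung"], weights=weights)


def build_composite(
    series: MGESeries,
    selection: TESelection,
    rois: ROISet | None = None,
    cnr_table: Sequence[CNRRecord] | None = None,
    nf: float = 1.0,
) -> CompositeImage:
    """Weighted sum of the selected echoes.

    When ``rois`` and ``cnr_table`` are given, the per-region percent CNR
    gain of the composite over the best single echo is computed with the
    same ROIs.  The composite's background SD follows from the pooled
    per-echo estimate by noise propagation of the known weights,
    sigma_bc = sigma_b * sqrt(sum w_i^2) (echo noise is independent).
    """
    image = np.zeros(series.shape)
    for idx, w in selection.weights.items():
        image = image + w * series.echo(idx)
    gains = {}
    if rois is not None and cnr_table is not None:
        si_m = float(image[rois.midwall_band].mean())
        w = np.array(list(selection.weights.values()))
        sb = _sigma_b_pooled(series, rois.roi_air) * float(np.sqrt((w**2).sum()))
        for region, mask in (("LVBP", rois.roi_lvbp), ("RVBP", rois.roi_rvbp), ("lung", rois.roi_lung)):
            cnr_comp = nf * abs(float(image[mask].mean()) - si_m) / sb
            best_single = max(r.cnr for r in cnr_table if r.region == region)
            gains[region] = 100.0 * (cnr_comp - best_single) / best_single
    return CompositeImage(
        image=image,
        selection=selection,
        cnr_table=list(cnr_table) if cnr_table is not None else [],
        cnr_gain_pct=gains,
    )
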