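"""Pixel-wise T2* quantification and AHA 16-segment reporting.

Signal decay over echo time is fitted per pixel with the monoexponential
model with constant offset, y = K exp(-TE/T2*) + C, which counteracts the
noise-floor-driven underestimation of short T2* values in magnitude images.
Myocardial pixels are grouped into American Heart Association segments
(6 basal, 6 mid-ventricular, 4 apical) anchored at the anterior RV-LV
insertion point; segments are summarized by the median pixel T2* (robust to
pixel-wise noise and artifacts), a segment is flagged as iron-loaded when
its median is at or below 20 ms, the global value is the unweighted mean of
the 16 segment medians, and the mid-ventricular septal value averages the
mid anteroseptal and inferoseptal segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import _geometry as geo
from .borders import MyocardialContours
from .mge_io import MGESeries

IRON_THRESHOLD_MS = 20.0

#: AHA segment ids and names, counter-clockwise from the anterior insertion
#: ray (the anterior/anteroseptal boundary) with the septum following it.
AHA_SEGMENTS = {
    "basal": ((2, "basal anteroseptal"), (3, "basal inferoseptal"), (4, "basal inferior"),
              (5, "basal inferolateral"), (6, "basal anterolateral"), (1, "basal anterior")),
    "mid": ((8, "mid anteroseptal"), (9, "mid inferoseptal"), (10, "mid inferior"),
            (11, "mid inferolateral"), (12, "mid anterolateral"), (7, "mid anterior")),
    "apical": ((14, "apical septal"), (15, "apical inferior"), (16, "apical lateral"),
               (13, "apical anterior")),
}

ALL_SEGMENT_IDS = tuple(range(1, 17))


@dataclass
class T2StarConfig:
    t2_bounds: tuple[float, float] = (0.1, 500.0)
    max_iter: int = 500
    tol: float = 1e-8


@dataclass
class DecayFit:
    k_amp: float
    t2star: float
    c_offset: float
    rss: float
    converged: bool
    te_used: np.ndarray
    y_used: np.ndarray


@dataclass
class T2StarMap:
    values: np.ndarray  # ms, NaN off-domain / failed fits
    fit_flags: np.ndarray  # True where the pixel fit converged
    n_failed: int = 0


@dataclass
class SegmentalT2:
    slice_level: str
    segment_medians: dict  # AHA id -> median ms (None when empty)
    segment_names: dict
    n_pixels: dict
    iron_flags: dict  # AHA id -> median <= 20 ms (None when empty)


# ---------------------------------------------------------------------------
# Pixel fit
# ---------------------------------------------------------------------------


def _loglinear_init(y: np.ndarray, te: np.ndarray) -> tuple[float, float, float]:
    c0 = float(y.min())
    z = y - c0 + 1e-6
    pos = z > 0
    slope, intercept = np.polyfit(te[pos], np.log(z[pos]), 1)
    t2_0 = -1.0 / slope if slope < 0 else 100.0
    t2_0 = float(np.clip(t2_0, 1.0, 400.0))
    k0 = float(np.exp(intercept))
    return max(k0, 1e-6), t2_0, c0


def fit_pixel_t2star(
    y: np.ndarray, te: np.ndarray, config: T2StarConfig | None = None
) -> DecayFit:
    """Bounded nonlinear least squares fit of y = K exp(-TE/T2*) + C.

    Initialization comes from a log-linear fit of the offset-corrected
    signal; T2* is constrained to (0.1, 500] ms.  A constant signal is a
    degenerate input and returns ``converged=False``.
    """
    config = config or T2StarConfig()
    y = np.asarray(y, dtype=float).ravel()
    te = np.asarray(te, dtype=float).ravel()
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(te))):
        raise ValueError("non-finite signal or echo-time values")
    if len(y) != len(te) or len(y) < 4:
        raise ValueError("need matching y/TE vectors with at least 4 echoes (3 parameters)")
    if np.ptp(y) == 0:
        return DecayFit(0.0, np.nan, float(y[0]), 0.0, False, te, y)
    k0, t2_0, c0 = _loglinear_init(y, te)

    def residuals(p):
        k, t2, c = p
        return k * np.exp(-te / t2) + c - y

    lo, hi = config.t2_bounds
    try:
        res = least_squares(
            residuals,
            x0=[k0, t2_0, c0],
            bounds=([0.0, lo, -np.inf], [np.inf, hi, np.inf]),
            xtol=config.tol,
            ftol=config.tol,
            max_nfev=config.max_iter * 3,
        )
    except Exception:
        return DecayFit(k0, np.nan, c0, np.inf, False, te, y)
    k, t2, c = res.x
    rss = float(np.sum(res.fun**2))
    converged = bool(res.success) and lo < t2 <= hi and k >= 0
    if k < 1e-9:  # pure-offset signal: T2* unidentifiable
        converged = False
    return DecayFit(float(k), float(t2), float(c), rss, converged, te, y)


def build_t2star_map(
    series: MGESeries, contours: MyocardialContours, config: T2StarConfig | None = None
) -> T2StarMap:
    """Fit every retained myocardial pixel; failed fits are excluded (NaN)."""
    myo = contours.myo_mask
    if not myo.any():
        raise ValueError("empty myocardium: nothing to fit")
    if myo.shape != series.shape:
        raise ValueError("contours do not match the series geometry")
    values = np.full(series.shape, np.nan)
    flags = np.zeros(series.shape, dtype=bool)
    te = series.te_list
    rr, cc = np.nonzero(myo)
    n_failed = 0
    for r, c in zip(rr, cc):
        fit = fit_pixel_t2star(series.images[:, r, c], te, config)
        if fit.converged:
            values[r, c] = fit.t2star
            flags[r, c] = True
        else:
            n_failed += 1
    return T2StarMap(values=values, fit_flags=flags, n_failed=n_failed)


# ---------------------------------------------------------------------------
# AHA partition and aggregation
# ---------------------------------------------------------------------------


def partition_aha(
    contours: MyocardialContours,
    insertion_anterior: tuple[float, float],
    insertion_inferior: tuple[float, float],
    slice_level: str,
) -> np.ndarray:
    """Label myocardial pixels with AHA segment ids (0 = off-myocardium).

    Segments are equal angular spans about the LV centroid starting at the
    anterior insertion ray; the rotation sense is chosen so the septum lies
    between the anterior and inferior insertion points.
    """
    if np.allclose(insertion_anterior, insertion_inferior):
        raise ValueError("insertion points must be distinct")
    segments = AHA_SEGMENTS[slice_level]
    span = 360.0 / len(segments)
    center = np.asarray(ndimage_center(contours.endo_mask))
    theta_a = float(geo.angle_deg(np.asarray(insertion_anterior), tuple(center))[0])
    theta_i = float(geo.angle_deg(np.asarray(insertion_inferior), tuple(center))[0])
    ccw = geo.wrap_deg(theta_i - theta_a) <= 180.0
    labels = np.zeros(contours.myo_mask.shape, dtype=int)
    rr, cc = np.nonzero(contours.myo_mask)
    theta = geo.angle_deg(np.column_stack([rr, cc]), tuple(center))
    offset = geo.wrap_deg(theta - theta_a) if ccw else geo.wrap_deg(theta_a - theta)
    idx = np.minimum((offset // span).astype(int), len(segments) - 1)
    seg_ids = np.array([seg_id for seg_id, _ in segments])
    labels[rr, cc] = seg_ids[idx]
    present = np.unique(labels[labels > 0])
    if len(present) < len(segments):
        raise ValueError(
            f"insertion rays do not partition the myocardium into {len(segments)} "
            f"non-empty segments (got {len(present)})"
        )
    return labels


def ndimage_center(mask: np.ndarray) -> tuple[float, float]:
    from scipy import ndimage

    c = ndimage.center_of_mass(mask)
    return float(c[0]), float(c[1])


def segment_names(slice_level: str) -> dict:
    return {seg_id: name for seg_id, name in AHA_SEGMENTS[slice_level]}


def segmental_medians(t2map: T2StarMap, labels: np.ndarray, slice_level: str) -> SegmentalT2:
    """Median pixel T2* per AHA segment with the <= 20 ms iron flag."""
    names = segment_names(slice_level)
    medians, n_pixels, flags = {}, {}, {}
    for seg_id, name in AHA_SEGMENTS[slice_level]:
        vals = t2map.values[(labels == seg_id) & t2map.fit_flags]
        n_pixels[seg_id] = int(vals.size)
        if vals.size == 0:
            medians[seg_id] = None
            flags[seg_id] = None
        else:
            med = float(np.median(vals))
            medians[seg_id] = med
            flags[seg_id] = med <= IRON_THRESHOLD_MS
    return SegmentalT2(
        slice_level=slice_level,
        segment_medians=medians,
        segment_names=names,
        n_pixels=n_pixels,
        iron_flags=flags,
    )


def summarize(segs: Sequence[SegmentalT2]) -> tuple[float, float]:
    """(global, mid-septal) T2* from the per-slice segment medians.

    Global is the unweighted mean over all 16 segment medians; mid-septal
    averages the mid anteroseptal (8) and mid inferoseptal (9) segments.
    """
    medians: dict[int, float] = {}
    for seg in segs:
        for seg_id, med in seg.segment_medians.items():
            if med is not None:
                medians[seg_id] = med
    missing = [seg_id for seg_id in ALL_SEGMENT_IDS if seg_id not in medians]
    if missing:
        raise ValueError(f"global T2* undefined: missing AHA segments {missing}")
    global_t2 = float(np.mean([medians[i] for i in ALL_SEGMENT_IDS]))
    mid_septal = float(np.mean([medians[8], medians[9]]))
    return global_t2, mid_septal
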