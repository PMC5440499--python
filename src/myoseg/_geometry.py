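"""Shared geometry helpers.

Coordinate convention used throughout the package: 0-based ``(row, col)``
pixel-center coordinates.  Angles are measured in the mathematical
convention of the short-axis plane, i.e. ``theta = atan2(-(row - r0),
col - c0)`` in degrees, wrapped to ``[0, 360)``: 0 deg points to the right
of the image (+col), 90 deg points up (-row), and angles increase
counter-clockwise on screen.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon2mask


def wrap_deg(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle (deg) into [0, 360)."""
    return np.mod(theta, 360.0)


def angle_deg(points: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Angle of (row, col) points about ``center``, degrees in [0, 360)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dy = -(pts[:, 0] - center[0])
    dx = pts[:, 1] - center[1]
    return wrap_deg(np.degrees(np.arctan2(dy, dx)))


def angle_map(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Per-pixel angle (deg, [0, 360)) about ``center`` for a full image."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = -(rr - center[0])
    dx = cc - center[1]
    return wrap_deg(np.degrees(np.arctan2(dy, dx)))


def unit_vector(theta_deg: float) -> np.ndarray:
    """(row, col) unit vector pointing along ``theta_deg``."""
    t = np.radians(theta_deg)
    return np.array([-np.sin(t), np.cos(t)])


def in_angular_span(theta: np.ndarray, start_deg: float, stop_deg: float) -> np.ndarray:
    """Membership of angles in the CCW span [start, stop), wrap-aware."""
    width = wrap_deg(stop_deg - start_deg)
    if width == 0:
        width = 360.0
    return wrap_deg(theta - start_deg) < width


def polygon_mask(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    """Boolean mask of pixel centers strictly inside a closed polygon."""
    return polygon2mask(shape, np.asarray(vertices, dtype=float))


def polygon_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Area centroid of a closed polygon given as (row, col) vertices."""
    v = np.asarray(vertices, dtype=float)
    r, c = v[:, 0], v[:, 1]
    r2, c2 = np.roll(r, -1), np.roll(c, -1)
    cross = c * r2 - c2 * r
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:  # degenerate: fall back to vertex mean
        return float(r.mean()), float(c.mean())
    cr = ((r + r2) * cross).sum() / (6.0 * area)
    cc = ((c + c2) * cross).sum() / (6.0 * area)
    return float(cr), float(cc)


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area (positive = counter-clockwise in (row, col))."""
    v = np.asarray(vertices, dtype=float)
    r, c = v[:, 0], v[:, 1]
    return float((c * np.roll(r, -1) - np.roll(c, -1) * r).sum() / 2.0)


def resample_closed_polyline(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` vertices at uniform arc length."""
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(v[:1], n, axis=0)
    targets = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(targets, s, closed[:, 0])
    cols = np.interp(targets, s, closed[:, 1])
    return np.column_stack([rows, cols])


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc by pixel-center Euclidean distance (r <= radius)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def box_mask(shape: tuple[int, int], center: tuple[float, float], size: int) -> np.ndarray:
    """Boolean ``size`` x ``size`` box centered on the rounded center pixel."""
    h = size // 2
    r0, c0 = int(round(center[0])), int(round(center[1]))
    mask = np.zeros(shape, dtype=bool)
    mask[max(0, r0 - h) : r0 + h + 1, max(0, c0 - h) : c0 + h + 1] = True
    return mask


def mask_boundary_polyline(mask: np.ndarray) -> np.ndarray:
    """Longest iso-contour of a boolean mask as a closed (row, col) polyline."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour (empty mask?)")
    longest = max(contours, key=len)
    # find_contours returns a closed loop with duplicated endpoint
    if np.allclose(longest[0], longest[-1]):
        longest = longest[:-1]
    return longest
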