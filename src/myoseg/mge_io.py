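"""Readers/writers for the standard formats the pipeline touches.

Canonical internal format is NIfTI-1 (echoes stacked on the 4th axis) with a
JSON sidecar carrying the echo-time list, pixel spacing and slice level.
DICOM directories are import-only.  All persisted pixel artifacts state the
coordinate convention: 0-based, (row, col), pixel-center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

COORD_CONVENTION = "pixel-center, 0-based, (row, col)"

SLICE_LEVELS = ("apical", "mid", "basal")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MGESeries:
    """A multi-gradient-echo magnitude stack for one short-axis slice.

    ``images`` is a float array of shape (n_echoes, H, W) ordered by ascending
    echo time; ``te_list`` is in milliseconds; ``pixel_spacing`` is the
    isotropic in-plane spacing in mm/pixel.
    """

    images: np.ndarray
    te_list: np.ndarray
    pixel_spacing: float
    slice_level: str
    scanner_id: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.te_list = np.asarray(self.te_list, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_echoes, H, W) stack")
        if len(self.te_list) != self.images.shape[0]:
            raise ValueError("te_list length must match number of echoes")
        if len(self.te_list) < 3:
            raise ValueError("an MGE series needs at least 3 echoes")
        if np.any(np.diff(self.te_list) <= 0):
            raise ValueError("te_list must be strictly increasing")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")
        if self.slice_level not in SLICE_LEVELS:
            raise ValueError(f"slice_level must be one of {SLICE_LEVELS}")

    @property
    def n_echoes(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def echo(self, index: int) -> np.ndarray:
        return self.images[index]


@dataclass
class ManualSeeds:
    """Minimal manual input for one slice.

    ``midwall_polyline`` is a closed (row, col) polyline traced inside the LV
    wall.  Method 1 additionally needs the anterior RV-LV ``insertion_point``
    (plus approximate RVBP/lung points on apical slices); method 2 needs open
    ``rvbp_polyline`` and closed ``lung_polyline`` contours, from which the
    insertion points are derived automatically.
    """

    midwall_polyline: np.ndarray
    air_point: tuple[float, float]
    method: int
    insertion_point: tuple[float, float] | None = None
    rvbp_polyline: np.ndarray | None = None
    lung_polyline: np.ndarray | None = None
    apical_rvbp_point: tuple[float, float] | None = None
    apical_lung_point: tuple[float, float] | None = None
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        self.midwall_polyline = np.asarray(self.midwall_polyline, dtype=float)
        if self.midwall_polyline.ndim != 2 or self.midwall_polyline.shape[0] < 3:
            raise ValueError("midwall_polyline must be an (N>=3, 2) closed polyline")
        if self.method not in (1, 2):
            raise ValueError("method must be 1 or 2")
        from shapely.geometry import Polygon

        if not Polygon(self.midwall_polyline).is_valid:
            raise ValueError("midwall_polyline must be closed and non-self-intersecting")
        if self.method == 1:
            if self.insertion_point is None:
                raise ValueError("method 1 requires insertion_point")
            if self.slice_level == "apical" and (
                self.apical_rvbp_point is None or self.apical_lung_point is None
            ):
                raise ValueError(
                    "method 1 on an apical slice requires apical_rvbp_point and apical_lung_point"
                )
        else:
            if self.rvbp_polyline is None or self.lung_polyline is None:
                raise ValueError("method 2 requires rvbp_polyline and lung_polyline")
            self.rvbp_polyline = np.asarray(self.rvbp_polyline, dtype=float)
            self.lung_polyline = np.asarray(self.lung_polyline, dtype=float)
            if len(self.rvbp_polyline) < 2 or len(self.lung_polyline) < 3:
                raise ValueError("method 2 polylines are too short")


# ---------------------------------------------------------------------------
# MGE series I/O
# ---------------------------------------------------------------------------


def _read_nifti_series(path: Path) -> MGESeries:
    import nibabel as nib

    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    sidecar = Path(str(sidecar) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("te_list_ms", "pixel_spacing_mm", "slice_level"):
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} is missing required key '{key}'")
    vol = np.asarray(nib.load(str(path)).get_fdata())
    if vol.ndim == 4:  # (H, W, 1, echoes) or (H, W, echoes, 1)
        vol = np.squeeze(vol, axis=tuple(i for i in (2, 3) if vol.shape[i] == 1 and vol.ndim > 3))
    if vol.ndim != 3:
        raise ValueError(f"expected (H, W, n_echoes) NIfTI volume, got shape {vol.shape}")
    images = np.moveaxis(vol, -1, 0)
    te = np.asarray(meta["te_list_ms"], dtype=float)
    order = np.argsort(te)
    return MGESeries(
        images=images[order],
        te_list=te[order],
        pixel_spacing=float(meta["pixel_spacing_mm"]),
        slice_level=str(meta["slice_level"]),
        scanner_id=str(meta.get("scanner_id", "")),
    )


def _read_dicom_series(path: Path) -> MGESeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    echoes: list[tuple[float, np.ndarray]] = []
    spacing = None
    series_uid = None
    level = "mid"
    scanner = ""
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_uid is None:
            series_uid = uid
        elif uid is not None and uid != series_uid:
            raise ValueError(f"mixed DICOM series in {path} ({uid} vs {series_uid})")
        te = getattr(ds, "EchoTime", None)
        if te is None:
            raise ValueError(f"DICOM file {f.name} has no EchoTime metadata")
        spc = getattr(ds, "PixelSpacing", None)
        if spc is not None:
            spacing = float(spc[0])
        level = str(getattr(ds, "SeriesDescription", level)) or level
        scanner = str(getattr(ds, "ManufacturerModelName", scanner))
        echoes.append((float(te), ds.pixel_array.astype(float)))
    if len(echoes) < 3:
        raise ValueError(f"found {len(echoes)} echoes in {path}; need at least 3")
    echoes.sort(key=lambda pair: pair[0])
    te_list = np.array([t for t, _ in echoes])
    images = np.stack([im for _, im in echoes])
    if level not in SLICE_LEVELS:
        level = "mid"
    if spacing is None:
        raise ValueError(f"no PixelSpacing metadata found in {path}")
    return MGESeries(images, te_list, spacing, level, scanner)


def read_mge_series(path: str | Path) -> MGESeries:
    """Read an MGE series from a DICOM directory or NIfTI file + JSON sidecar.

    Echoes are sorted by ascending TE regardless of on-disk order.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti_series(path)


def write_mge_series(series: MGESeries, path: str | Path) -> Path:
    """Write a series as a 4D NIfTI (echoes on the last axis) + JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    vol = np.moveaxis(series.images, 0, -1)
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "te_list_ms": series.te_list.tolist(),
                "pixel_spacing_mm": series.pixel_spacing,
                "slice_level": series.slice_level,
                "scanner_id": series.scanner_id,
                "coordinate_convention": COORD_CONVENTION,
            },
            indent=2,
        )
    )
    return path


# ---------------------------------------------------------------------------
# Seeds I/O
# ---------------------------------------------------------------------------


def _tolist(x):
    if x is None:
        return None
    return np.asarray(x, dtype=float).tolist()


def write_seeds(seeds: ManualSeeds, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "coordinate_convention": COORD_CONVENTION,
        "method": seeds.method,
        "slice_level": seeds.slice_level,
        "midwall_polyline": _tolist(seeds.midwall_polyline),
        "air_point": _tolist(seeds.air_point),
        "insertion_point": _tolist(seeds.insertion_point),
        "rvbp_polyline": _tolist(seeds.rvbp_polyline),
        "lung_polyline": _tolist(seeds.lung_polyline),
        "apical_rvbp_point": _tolist(seeds.apical_rvbp_point),
        "apical_lung_point": _tolist(seeds.apical_lung_point),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_seeds(path: str | Path) -> ManualSeeds:
    data = json.loads(Path(path).read_text())
    for key in ("midwall_polyline", "air_point", "method"):
        if key not in data:
            raise KeyError(f"seeds file {path} is missing required key '{key}'")

    def _tup(x):
        return None if x is None else tuple(float(v) for v in x)

    def _arr(x):
        return None if x is None else np.asarray(x, dtype=float)

    return ManualSeeds(
        midwall_polyline=_arr(data["midwall_polyline"]),
        air_point=_tup(data["air_point"]),
        method=int(data["method"]),
        insertion_point=_tup(data.get("insertion_point")),
        rvbp_polyline=_arr(data.get("rvbp_polyline")),
        lung_polyline=_arr(data.get("lung_polyline")),
        apical_rvbp_point=_tup(data.get("apical_rvbp_point")),
        apical_lung_point=_tup(data.get("apical_lung_point")),
        slice_level=str(data.get("slice_level", "mid")),
    )


# ---------------------------------------------------------------------------
# Masks and contours
# ---------------------------------------------------------------------------


def write_masks(
    masks: Mapping[str, np.ndarray],
    directory: str | Path,
    reference_shape: tuple[int, int] | None = None,
    pixel_spacing: float = 1.0,
) -> dict[str, Path]:
    """Persist boolean masks as 0/1 NIfTI files, one per mask name."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    for name, mask in masks.items():
        mask = np.asarray(mask)
        if reference_shape is not None and mask.shape != tuple(reference_shape):
            raise ValueError(
                f"mask '{name}' has shape {mask.shape}, expected {tuple(reference_shape)}"
            )
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(p))
        out[name] = p
    return out


def read_masks(directory: str | Path) -> dict[str, np.ndarray]:
    import nibabel as nib

    directory = Path(directory)
    out = {}
    for p in sorted(directory.glob("*.nii.gz")):
        name = p.name[: -len(".nii.gz")]
        out[name] = np.asarray(nib.load(str(p)).get_fdata()) > 0.5
    return out


def write_contours(contours: Mapping[str, np.ndarray], path: str | Path) -> Path:
    """Persist contours as JSON polygon lists with an explicit convention header."""
    path = Path(path)
    payload = {"coordinate_convention": COORD_CONVENTION}
    payload["contours"] = {k: np.asarray(v, dtype=float).tolist() for k, v in contours.items()}
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_contours(path: str | Path) -> dict[str, np.ndarray]:
    data = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in data["contours"].items()}


# ---------------------------------------------------------------------------
# Segmental report
# ---------------------------------------------------------------------------


def write_segmental_report(segs: Sequence, path: str | Path) -> Path:
    """Write segment-level T2* results plus global / mid-septal summary rows.

    ``segs`` is a sequence of :class:`myoseg.t2star.SegmentalT2`, one per
    slice.  The CSV has a deterministic column and row order so identical
    inputs produce byte-identical files.
    """
    import pandas as pd

    from .t2star import summarize

    rows = []
    for seg in segs:
        for seg_id in sorted(seg.segment_medians):
            median = seg.segment_medians[seg_id]
            n_pix = seg.n_pixels.get(seg_id, 0)
            flag = seg.iron_flags.get(seg_id)
            rows.append(
                {
                    "slice_level": seg.slice_level,
                    "aha_segment_id": seg_id,
                    "segment_name": seg.segment_names[seg_id],
                    "median_t2star_ms": "" if median is None else f"{median:.4f}",
                    "n_pixels": n_pix,
                    "iron_flag": "" if flag is None else str(bool(flag)),
                }
            )
    try:
        global_t2, mid_septal = summarize(segs)
        summary = [("global", global_t2), ("mid_septal", mid_septal)]
    except ValueError:
        summary = [("global", None), ("mid_septal", None)]
    for name, value in summary:
        rows.append(
            {
                "slice_level": "summary",
                "aha_segment_id": "",
                "segment_name": name,
                "median_t2star_ms": "" if value is None else f"{value:.4f}",
                "n_pixels": "",
                "iron_flag": "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "slice_level",
            "aha_segment_id",
            "segment_name",
            "median_t2star_ms",
            "n_pixels",
            "iron_flag",
        ],
    )
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path
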