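"""Synthetic short-axis multi-gradient-echo phantom with known ground truth.

The phantom emulates a bright-blood short-axis acquisition: an annular LV
myocardium with a spatial T2* map (including one focal low-T2* sector in the
lateral wall to exercise the iron pathway), bright LV/RV blood pools with
long T2*, a low-signal lung field, air background, and Rician magnitude
noise.  The noiseless signal of a pixel of tissue r at echo time t is the
monoexponential-with-offset forward model ``K_r * exp(-t / T2*_r(p)) + C``.

Default echo times follow the 2.69-18.86 ms ladder at 2.31-ms increments
(eight echoes); an alternative 2.59-18.20 ms / 2.23-ms ladder is provided as
``TE_LADDER_ALT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _geometry as geo
from .mge_io import ManualSeeds, MGESeries, SLICE_LEVELS

TE_LADDER_DEFAULT = tuple(2.69 + 2.31 * i for i in range(8))
TE_LADDER_ALT = tuple(2.59 + 2.23 * i for i in range(8))

#: Default per-slice LV geometry in mm (endocardial radius, epicardial radius),
#: consistent with normal short-axis wall thickness tapering toward the apex.
DEFAULT_RADII_MM = {"apical": (13.0, 19.5), "mid": (17.0, 26.0), "basal": (19.0, 28.0)}

#: Default angular extent (deg, CCW span) of the focal low-T2* sector.  On
#: mid/basal slices it sits inside the anterolateral segment; on apical slices
#: inside the (90 deg wide) lateral segment, so a segmental median <= 20 ms is
#: produced at every slice level.
DEFAULT_IRON_SECTOR = {"apical": (330.0, 40.0), "mid": (18.0, 52.0), "basal": (18.0, 52.0)}


@dataclass
class PapillaryDisc:
    center: tuple[float, float]
    radius_px: float


@dataclass
class PhantomSpec:
    """Full description of one synthetic short-axis slice.

    T2* values are in ms, radii in mm, ``noise_sigma`` in raw intensity
    units (scale of the Gaussian components of the Rician noise).
    """

    image_size: tuple[int, int] = (128, 128)
    pixel_spacing: float = 1.56
    slice_level: str = "mid"
    lv_center: tuple[float, float] = (64.0, 72.0)
    endo_radius: float = 17.0
    epi_radius: float = 26.0
    myo_t2star: float = 35.0
    iron_t2star: float = 16.0
    iron_sector_deg: tuple[float, float] | None = (18.0, 52.0)
    blood_t2star: float = 120.0
    #: RV pool: bright inflow at short TE with rapid turbulence/deoxygenation
    #: driven dephasing, hence a short effective T2*
    rv_blood_t2star: float = 25.0
    lung_t2star: float = 2.0
    k_scale: dict = field(
        default_factory=lambda: {"myo": 1000.0, "lvbp": 1400.0, "rvbp": 2000.0, "lung": 80.0}
    )
    offset_c: float = 0.0
    te_list: tuple = TE_LADDER_DEFAULT
    noise_sigma: float = 48.0
    rng_seed: int = 7
    papillary: tuple[PapillaryDisc, ...] = ()
    rv_radius: float | None = None  # px; default by slice level
    seed_jitter: float = 0.5  # px, Gaussian jitter of synthesized manual seeds

    def __post_init__(self) -> None:
        if self.slice_level not in SLICE_LEVELS:
            raise ValueError(f"slice_level must be one of {SLICE_LEVELS}")
        if not (self.epi_radius > self.endo_radius > 0):
            raise ValueError(
                f"invalid geometry: epi_radius ({self.epi_radius} mm) must exceed "
                f"endo_radius ({self.endo_radius} mm) and both must be positive"
            )
        te = np.asarray(self.te_list, dtype=float)
        if len(te) < 3 or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be strictly increasing with length >= 3")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name, t2 in (
            ("myo_t2star", self.myo_t2star),
            ("iron_t2star", self.iron_t2star),
            ("blood_t2star", self.blood_t2star),
            ("rv_blood_t2star", self.rv_blood_t2star),
            ("lung_t2star", self.lung_t2star),
        ):
            if t2 <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def endo_radius_px(self) -> float:
        return self.endo_radius / self.pixel_spacing

    @property
    def epi_radius_px(self) -> float:
        return self.epi_radius / self.pixel_spacing


@dataclass
class GroundTruth:
    """Reference masks, true T2* map and synthesized seeds for one slice.

    ``lvbp_mask`` includes papillary-muscle discs (the blood-pool ROI the
    segmentation is asked to recover encloses papillary muscles and
    trabeculae); ``myo_mask`` is the compact annulus.  ``t2star_true`` is NaN
    off the myocardium.
    """

    myo_mask: np.ndarray
    lvbp_mask: np.ndarray
    rvbp_mask: np.ndarray
    lung_mask: np.ndarray
    air_mask: np.ndarray
    t2star_true: np.ndarray
    seeds_method1: ManualSeeds
    seeds_method2: ManualSeeds
    lv_center: tuple[float, float] = (0.0, 0.0)
    insertion_anterior_deg: float = 135.0


def default_spec(
    slice_level: str = "mid",
    noise_sigma: float = 48.0,
    rng_seed: int = 7,
    with_papillary: bool = True,
    **overrides,
) -> PhantomSpec:
    """Standard study-condition phantom for a given slice level."""
    endo_mm, epi_mm = DEFAULT_RADII_MM[slice_level]
    spec = PhantomSpec(
        slice_level=slice_level,
        endo_radius=endo_mm,
        epi_radius=epi_mm,
        iron_sector_deg=DEFAULT_IRON_SECTOR[slice_level],
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )
    if with_papillary:
        r_endo_px = spec.endo_radius_px
        discs = []
        for theta in (120.0, 240.0):
            c = np.asarray(spec.lv_center) + 0.45 * r_endo_px * geo.unit_vector(theta)
            discs.append(PapillaryDisc(center=(float(c[0]), float(c[1])), radius_px=1.8))
        spec = replace(spec, papillary=tuple(discs))
    return replace(spec, **overrides)


def add_rician_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Apply Rician noise: sqrt((image + g1)^2 + g2^2), g1, g2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, image.shape)
    g2 = rng.normal(0.0, sigma, image.shape)
    return np.sqrt((image + g1) ** 2 + g2**2)


# ---------------------------------------------------------------------------
# Geometry of the default anatomy
# ---------------------------------------------------------------------------

_ANTERIOR_INSERTION_DEG = 135.0  # septum spans 135-255 deg (RV on the left)
_RV_DIRECTION_DEG = 195.0  # anteroseptal/inferoseptal junction ray
_RV_GAP_PX = 4.0


def _rv_geometry(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    rv_radius = spec.rv_radius
    if rv_radius is None:
        rv_radius = 8.0 if spec.slice_level == "apical" else 13.0
    d = spec.epi_radius_px + rv_radius + _RV_GAP_PX
    center = np.asarray(spec.lv_center) + d * geo.unit_vector(_RV_DIRECTION_DEG)
    return center, rv_radius


def _lung_geometry(spec: PhantomSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """(center, (semi_row, semi_col)) of the elliptic lung field."""
    if spec.slice_level == "apical":
        return (60.0, 104.0), (24.0, 12.0)
    return (58.0, 108.0), (38.0, 16.0)


def _tissue_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    shape = spec.image_size
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = np.hypot(rr - spec.lv_center[0], cc - spec.lv_center[1])
    lv_pool = r <= spec.endo_radius_px
    myo = (r > spec.endo_radius_px) & (r <= spec.epi_radius_px)
    rv_center, rv_radius = _rv_geometry(spec)
    rvbp = geo.disc_mask(shape, tuple(rv_center), rv_radius) & ~(lv_pool | myo)
    (lr, lc), (sr, sc) = _lung_geometry(spec)
    lung = ((rr - lr) / sr) ** 2 + ((cc - lc) / sc) ** 2 <= 1.0
    lung &= ~(lv_pool | myo | rvbp)
    papillary = np.zeros(shape, dtype=bool)
    for disc in spec.papillary:
        papillary |= geo.disc_mask(shape, disc.center, disc.radius_px) & lv_pool
    air = ~(lv_pool | myo | rvbp | lung)
    return {
        "lv_pool": lv_pool,
        "papillary": papillary,
        "myo": myo,
        "rvbp": rvbp,
        "lung": lung,
        "air": air,
    }


def _t2star_image(spec: PhantomSpec, tissues: dict[str, np.ndarray]) -> np.ndarray:
    """Per-pixel T2* (ms); air pixels get NaN (no tissue signal)."""
    shape = spec.image_size
    t2 = np.full(shape, np.nan)
    theta = geo.angle_map(shape, spec.lv_center)
    myo_t2 = np.full(shape, spec.myo_t2star)
    if spec.iron_sector_deg is not None:
        start, stop = spec.iron_sector_deg
        myo_t2[geo.in_angular_span(theta, start, stop)] = spec.iron_t2star
    t2[tissues["myo"]] = myo_t2[tissues["myo"]]
    t2[tissues["papillary"]] = myo_t2[tissues["papillary"]]
    t2[tissues["lv_pool"] & ~tissues["papillary"]] = spec.blood_t2star
    t2[tissues["rvbp"]] = spec.rv_blood_t2star
    t2[tissues["lung"]] = spec.lung_t2star
    return t2


def _amplitude_image(spec: PhantomSpec, tissues: dict[str, np.ndarray]) -> np.ndarray:
    k = np.zeros(spec.image_size)
    k[tissues["lv_pool"]] = spec.k_scale["lvbp"]
    k[tissues["myo"]] = spec.k_scale["myo"]
    k[tissues["papillary"]] = spec.k_scale["myo"]
    k[tissues["rvbp"]] = spec.k_scale["rvbp"]
    k[tissues["lung"]] = spec.k_scale["lung"]
    return k


# ---------------------------------------------------------------------------
# Seed synthesis
# ---------------------------------------------------------------------------


def _jitter(rng: np.random.Generator, arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(arr, dtype=float)
    return np.asarray(arr, dtype=float) + rng.normal(0.0, sigma, np.shape(arr))


def synthesize_seeds(spec: PhantomSpec, method: int, jitter: float | None = None,
                     seed: int | None = None) -> ManualSeeds:
    """Build manual seeds from ground truth with observer-like jitter."""
    jitter = spec.seed_jitter if jitter is None else jitter
    rng = np.random.default_rng(spec.rng_seed + 104729 if seed is None else seed)
    center = np.asarray(spec.lv_center)
    r_mid = 0.5 * (spec.endo_radius_px + spec.epi_radius_px)
    angles = np.linspace(0.0, 360.0, 48, endpoint=False)
    # radial jitter keeps the traced contour star-shaped (never self-crossing)
    r_sigma = min(jitter, 0.35 * (spec.epi_radius_px - spec.endo_radius_px))
    radii = r_mid + (rng.normal(0.0, r_sigma, angles.shape) if r_sigma > 0 else 0.0)
    midwall = np.stack([center + r * geo.unit_vector(a) for r, a in zip(np.atleast_1d(radii), angles)])
    air_point = tuple(_jitter(rng, np.array([12.0, 12.0]), jitter))
    anterior = center + spec.epi_radius_px * geo.unit_vector(_ANTERIOR_INSERTION_DEG)
    inferior = center + spec.epi_radius_px * geo.unit_vector(_ANTERIOR_INSERTION_DEG + 120.0)
    rv_center, rv_radius = _rv_geometry(spec)
    if method == 1:
        kwargs = {}
        if spec.slice_level == "apical":
            (lr, lc), _ = _lung_geometry(spec)
            kwargs["apical_rvbp_point"] = tuple(_jitter(rng, rv_center, jitter))
            kwargs["apical_lung_point"] = tuple(_jitter(rng, np.array([lr, lc - 2.0]), jitter))
        return ManualSeeds(
            midwall_polyline=midwall,
            air_point=air_point,
            method=1,
            insertion_point=tuple(_jitter(rng, anterior, jitter)),
            slice_level=spec.slice_level,
            **kwargs,
        )
    # Method 2: open RVBP contour from the anterior to the inferior insertion
    # point, bulging around the far side of the RV pool; closed lung contour.
    a0 = geo.angle_deg(anterior, tuple(rv_center))[0]
    a1 = geo.angle_deg(inferior, tuple(rv_center))[0]
    # go the long way around the RV (away from the LV)
    sweep = geo.wrap_deg(a1 - a0)
    if sweep < 180.0:
        a1_unwrapped = a0 + sweep - 360.0
    else:
        a1_unwrapped = a0 + sweep
    arc = np.linspace(a0, a1_unwrapped, 16)[1:-1]
    rv_pts = [anterior] + [rv_center + (rv_radius - 1.0) * geo.unit_vector(a) for a in arc] + [inferior]
    rvbp_polyline = _jitter(rng, np.stack(rv_pts), jitter)
    (lr, lc), (sr, sc) = _lung_geometry(spec)
    ellipse_angles = np.linspace(0.0, 360.0, 32, endpoint=False)
    scale = 1.0 + (rng.normal(0.0, 0.03, ellipse_angles.shape) if jitter > 0 else 0.0)
    lung_polyline = np.stack(
        [
            np.array([lr - k * (sr - 2.0) * np.sin(np.radians(a)), lc + k * (sc - 2.0) * np.cos(np.radians(a))])
            for k, a in zip(np.atleast_1d(scale), ellipse_angles)
        ]
    )
    return ManualSeeds(
        midwall_polyline=midwall,
        air_point=air_point,
        method=2,
        rvbp_polyline=rvbp_polyline,
        lung_polyline=lung_polyline,
        slice_level=spec.slice_level,
    )


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[MGESeries, GroundTruth]:
    """Render the phantom series and its ground truth.

    Identical spec (including ``rng_seed``) produces bit-identical output.
    """
    tissues = _tissue_masks(spec)
    t2 = _t2star_image(spec, tissues)
    k = _amplitude_image(spec, tissues)
    te = np.asarray(spec.te_list, dtype=float)
    with np.errstate(invalid="ignore"):
        decay = np.exp(-te[:, None, None] / t2[None, :, :])
    decay = np.nan_to_num(decay, nan=0.0)  # air: K = 0 anyway
    images = k[None, :, :] * decay + spec.offset_c
    if spec.noise_sigma > 0:
        noisy = np.empty_like(images)
        for i in range(images.shape[0]):
            echo_seed = (int(spec.rng_seed) * 8191 + i) % (2**31)
            noisy[i] = add_rician_noise(images[i], spec.noise_sigma, echo_seed)
        images = noisy
    series = MGESeries(
        images=images,
        te_list=te,
        pixel_spacing=spec.pixel_spacing,
        slice_level=spec.slice_level,
        scanner_id="phantom",
    )
    t2_true = np.where(tissues["myo"], t2, np.nan)
    gt = GroundTruth(
        myo_mask=tissues["myo"],
        lvbp_mask=tissues["lv_pool"],  # papillary discs are inside the pool ROI
        rvbp_mask=tissues["rvbp"],
        lung_mask=tissues["lung"],
        air_mask=tissues["air"],
        t2star_true=t2_true,
        seeds_method1=synthesize_seeds(spec, 1),
        seeds_method2=synthesize_seeds(spec, 2),
        lv_center=spec.lv_center,
        insertion_anterior_deg=_ANTERIOR_INSERTION_DEG,
    )
    return series, gt


def default_phantom_set(
    noise_sigma: float = 48.0, rng_seed: int = 7, with_papillary: bool = True
) -> dict[str, tuple[MGESeries, GroundTruth]]:
    """Apical + mid + basal default phantoms, as acquired for one subject."""
    out = {}
    for i, level in enumerate(SLICE_LEVELS):
        spec = default_spec(
            level, noise_sigma=noise_sigma, rng_seed=rng_seed + 13 * i, with_papillary=with_papillary
        )
        out[level] = generate_phantom(spec)
    return out
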