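"""End-to-end orchestration: composite -> LVBP -> borders -> T2* -> report.

One global seed is expanded deterministically into per-stage, per-slice
seeds so any stage can be re-run in isolation with the same randomness.
Failures in one slice abort that slice with a stage-named diagnostic and the
remaining slices proceed; the global summary is then undefined.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import composite as composite_mod
from . import mge_io
from .borders import BorderConfig, delineate_borders
from .lvbp import VFCParams, detect_lvbp
from .metrics import ReproReport, bland_altman, dice, icc_two_way_random, median_mad, repro_cov
from .t2star import SegmentalT2, T2StarConfig, build_t2star_map, partition_aha, segmental_medians, summarize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    composite_method: int = 2
    composite: composite_mod.CompositeConfig = field(default_factory=composite_mod.CompositeConfig)
    vfc: VFCParams = field(default_factory=VFCParams)
    borders: BorderConfig = field(default_factory=BorderConfig)
    t2star: T2StarConfig = field(default_factory=T2StarConfig)
    kmeans_k: int = 3
    seed: int = 0
    save_intermediates: bool = False
    log_level: str = "INFO"

    def stage_seed(self, stage: str, slice_index: int) -> int:
        """Deterministic per-stage, per-slice seed below 2**31."""
        stages = {"lvbp": 1, "borders": 2, "t2star": 3}
        return (int(self.seed) * 100003 + stages.get(stage, 0) * 101 + slice_index) % (2**31)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key '{key}'")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, Mapping):
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        return cfg


@dataclass
class SliceResult:
    slice_level: str
    rois: object
    composite: object
    lvbp: object
    contours: object
    t2map: object
    labels: np.ndarray
    segmental: SegmentalT2
    timing_s: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    slices: dict  # slice_level -> SliceResult
    failures: dict  # slice_level -> diagnostic string
    global_t2star: float | None
    mid_septal_t2star: float | None
    config: PipelineConfig


def run_slice(
    series: mge_io.MGESeries,
    seeds: mge_io.ManualSeeds,
    config: PipelineConfig,
    slice_index: int = 0,
) -> SliceResult:
    """Run the full chain on one slice."""
    timing: dict[str, float] = {}

    def _timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed on {series.slice_level} slice: {exc}") from exc
        timing[stage] = time.perf_counter() - t0
        return out

    rois = _timed("rois", lambda: composite_mod.place_rois(series, seeds, config.composite))
    cnr_table = _timed("cnr", lambda: composite_mod.compute_cnr(series, rois, config.composite.nf))
    selection = _timed("select_tes", lambda: composite_mod.select_optimal_tes(cnr_table))
    comp = _timed(
        "composite",
        lambda: composite_mod.build_composite(series, selection, rois, cnr_table, config.composite.nf),
    )
    lvbp_region = _timed(
        "lvbp",
        lambda: detect_lvbp(
            series, comp, rois, config.vfc, k=config.kmeans_k,
            seed=config.stage_seed("lvbp", slice_index),
        ),
    )
    contours, grid, counts = _timed(
        "borders",
        lambda: delineate_borders(
            lvbp_region, comp, series.slice_level, series.pixel_spacing,
            anchor_deg=rois.insertion_anterior_deg, cfg=config.borders,
            seed=config.stage_seed("borders", slice_index),
        ),
    )
    t2map = _timed("t2star", lambda: build_t2star_map(series, contours, config.t2star))
    labels = _timed(
        "aha",
        lambda: partition_aha(
            contours, rois.insertion_anterior, rois.insertion_inferior, series.slice_level
        ),
    )
    segmental = segmental_medians(t2map, labels, series.slice_level)
    return SliceResult(
        slice_level=series.slice_level,
        rois=rois,
        composite=comp,
        lvbp=lvbp_region,
        contours=contours,
        t2map=t2map,
        labels=labels,
        segmental=segmental,
        timing_s=timing,
    )


def run_pipeline(
    series_list: Sequence[mge_io.MGESeries],
    seeds_list: Sequence[mge_io.ManualSeeds | None],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run 1-3 slices end to end; identical inputs + config give identical outputs."""
    config = config or PipelineConfig()
    if len(series_list) != len(seeds_list) or not (1 <= len(series_list) <= 3):
        raise ValueError("need 1-3 slices, each with matching seeds")
    slices: dict[str, SliceResult] = {}
    failures: dict[str, str] = {}
    for i, (series, seeds) in enumerate(zip(series_list, seeds_list)):
        if seeds is None:
            failures[series.slice_level] = "missing seeds: slice skipped"
            logger.warning("missing seeds for %s slice: skipped", series.slice_level)
            continue
        try:
            slices[series.slice_level] = run_slice(series, seeds, config, slice_index=i)
        except RuntimeError as exc:
            failures[series.slice_level] = str(exc)
            logger.error("%s", exc)
    try:
        global_t2, mid_septal = summarize([s.segmental for s in slices.values()])
    except ValueError as exc:
        # expected for partial (< 3 slice) runs; a warning only when a full
        # subject was requested
        log = logger.warning if len(series_list) == 3 else logger.debug
        log("global summary undefined: %s", exc)
        global_t2, mid_septal = None, None
    result = PipelineResult(
        slices=slices, failures=failures,
        global_t2star=global_t2, mid_septal_t2star=mid_septal, config=config,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _config_dict(config: PipelineConfig) -> dict:
    def _clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [_clean(v) for v in obj]
        return obj

    return _clean(config)


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    segs = [s.segmental for s in result.slices.values()]
    if segs:
        mge_io.write_segmental_report(segs, out_dir / "segmental_t2star.csv")
    for level, sl in result.slices.items():
        mge_io.write_masks(
            {
                f"{level}_myo": sl.contours.myo_mask,
                f"{level}_endo": sl.contours.endo_mask,
                f"{level}_epi": sl.contours.epi_mask,
                f"{level}_lvbp": sl.lvbp.mask,
            },
            out_dir / "masks",
        )
        mge_io.write_contours(
            {"endo": sl.contours.endo_polyline, "epi": sl.contours.epi_polyline},
            out_dir / f"{level}_contours.json",
        )
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(sl.t2map.values, np.eye(4)), str(out_dir / f"{level}_t2star_map.nii.gz")
        )
    provenance = {
        "package_version": __version__,
        "seed": result.config.seed,
        "config": _config_dict(result.config),
        "failures": result.failures,
        "global_t2star_ms": result.global_t2star,
        "mid_septal_t2star_ms": result.mid_septal_t2star,
        "timing_s": {lvl: sl.timing_s for lvl, sl in result.slices.items()},
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Run comparison
# ---------------------------------------------------------------------------


def compare_runs(runs: Sequence[PipelineResult]) -> ReproReport:
    """Reproducibility of >= 2 pipeline runs over the same slices.

    Per-slice Dice on the myocardial masks, Bland-Altman / CoV over paired
    segmental T2* medians (first two runs), and ICC across all runs treated
    as raters when more than two are given.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to compare")
    levels = set(runs[0].slices)
    for run in runs[1:]:
        if set(run.slices) != levels:
            raise ValueError("runs cover different slices")
    report = ReproReport()
    a, b = runs[0], runs[1]
    for level in sorted(levels):
        report.dsc_values.append(dice(a.slices[level].contours.myo_mask, b.slices[level].contours.myo_mask))
    report.dsc_median, report.dsc_mad = median_mad(report.dsc_values)
    pairs = []
    matrix_rows = []
    for level in sorted(levels):
        med_a = a.slices[level].segmental.segment_medians
        for seg_id in sorted(med_a):
            values = [run.slices[level].segmental.segment_medians.get(seg_id) for run in runs]
            if any(v is None for v in values):
                continue
            pairs.append((values[0], values[1]))
            matrix_rows.append(values)
    if len(pairs) >= 2:
        report.mean_difference, report.loa = bland_altman(pairs)
        report.cov_pct = repro_cov(pairs)
    if len(runs) >= 2 and len(matrix_rows) >= 2:
        report.icc = icc_two_way_random(np.asarray(matrix_rows))
    report.n = len(pairs)
    return report
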