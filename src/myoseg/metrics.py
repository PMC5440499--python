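"""Reproducibility statistics.

Contour agreement is measured by the Dice similarity coefficient
DSC = 2|A n B| / (|A| + |B|).  Paired measurement agreement uses
Bland-Altman mean difference with limits of agreement (1.96 x SD of the
differences), the test-retest coefficient of variation (within-pair RMS SD
over the grand mean, as a percentage), and the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ReproReport:
    dsc_values: list = field(default_factory=list)
    dsc_median: float | None = None
    dsc_mad: float | None = None
    mean_difference: float | None = None
    loa: float | None = None
    cov_pct: float | None = None
    icc: float | None = None
    n: int = 0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two boolean masks.

    1 means total overlap, 0 no agreement; two empty masks are defined as
    perfect (vacuous) agreement with a log notice.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.warning("dice of two empty masks: defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def bland_altman(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """(mean difference, limit of agreement = 1.96 x sample SD of differences)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (x, y) pairs")
    d = arr[:, 0] - arr[:, 1]
    return float(d.mean()), float(1.96 * d.std(ddof=1))


def repro_cov(pairs: Sequence[tuple[float, float]]) -> float:
    """Test-retest CoV (%): within-pair RMS SD over the grand mean.

    SD_w = sqrt(mean(d_i^2) / 2) with d_i the paired differences; the
    result is 100 * SD_w / mean of all measurements.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (x, y) pairs")
    grand_mean = float(arr.mean())
    if grand_mean <= 0:
        raise ValueError("CoV undefined for non-positive grand mean")
    d = arr[:, 0] - arr[:, 1]
    sd_w = float(np.sqrt(np.mean(d**2) / 2.0))
    return 100.0 * sd_w / grand_mean


def icc_two_way_random(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``matrix`` is (n subjects x k raters), complete.  Computed from the
    two-way ANOVA decomposition:
    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)).
    A constant matrix has zero variance and returns NaN with a log notice.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete n>=2 x k>=2 matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (no missing values)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        logger.warning("ICC undefined: zero variance in the rating matrix")
        return float("nan")
    return float((ms_r - ms_e) / denom)


def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Median and median absolute deviation (the conventional robust summary)."""
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))
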