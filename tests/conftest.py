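"""Shared fixtures: phantom generation and cached full-pipeline runs.

The heavy end-to-end runs (three slices, noisy and noiseless, plus a
seed-jitter pair) are session-scoped so the acceptance tests and the unit
tests share them instead of re-running the pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from myoseg.phantom import default_phantom_set, default_spec, generate_phantom, synthesize_seeds
from myoseg.pipeline import PipelineConfig, run_pipeline, run_slice

warnings.filterwarnings("ignore", category=UserWarning)

SLICE_LEVELS = ("apical", "mid", "basal")


@pytest.fixture(scope="session")
def noisy_set():
    """Default study-condition phantoms (Rician sigma 48, SNR ~ 20)."""
    return default_phantom_set(noise_sigma=48.0, rng_seed=7)


@pytest.fixture(scope="session")
def noiseless_set():
    return default_phantom_set(noise_sigma=0.0, rng_seed=7)


@pytest.fixture(scope="session")
def noisy_result(noisy_set):
    """Full three-slice pipeline on the default noisy phantom (method 2)."""
    series_list = [noisy_set[lvl][0] for lvl in SLICE_LEVELS]
    seeds_list = [noisy_set[lvl][1].seeds_method2 for lvl in SLICE_LEVELS]
    result = run_pipeline(series_list, seeds_list, PipelineConfig(seed=1))
    assert not result.failures, f"noisy pipeline failures: {result.failures}"
    return result


@pytest.fixture(scope="session")
def noiseless_result(noiseless_set):
    series_list = [noiseless_set[lvl][0] for lvl in SLICE_LEVELS]
    seeds_list = [noiseless_set[lvl][1].seeds_method2 for lvl in SLICE_LEVELS]
    result = run_pipeline(series_list, seeds_list, PipelineConfig(seed=1))
    assert not result.failures, f"noiseless pipeline failures: {result.failures}"
    return result


@pytest.fixture(scope="session")
def jitter_runs():
    """Three runs on one noisy mid slice with independently jittered seeds."""
    spec = default_spec("mid", noise_sigma=48.0, rng_seed=7)
    series, _ = generate_phantom(spec)
    runs = []
    for i, jitter_seed in enumerate((100, 200, 300)):
        seeds = synthesize_seeds(spec, 2, seed=jitter_seed)
        runs.append(run_pipeline([series], [seeds], PipelineConfig(seed=5 + i)))
    for run in runs:
        assert not run.failures
    return runs


@pytest.fixture(scope="session")
def mid_noiseless_slice(noiseless_set):
    series, gt = noiseless_set["mid"]
    return run_slice(series, gt.seeds_method2, PipelineConfig(seed=0)), gt
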