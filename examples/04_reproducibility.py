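"""Observer-variability experiment on one noisy slice.

Re-runs the pipeline with independently jittered manual seeds (emulating
different observers tracing the mid-wall contour) and summarizes contour
and T2* agreement: Dice, Bland-Altman mean difference and limits of
agreement, test-retest CoV, and the two-way random absolute-agreement
ICC across three runs.
"""

from myoseg.phantom import default_spec, generate_phantom, synthesize_seeds
from myoseg.pipeline import PipelineConfig, compare_runs, run_pipeline

spec = default_spec("mid", noise_sigma=48.0, rng_seed=7)
series, _ = generate_phantom(spec)

runs = []
for i, jitter_seed in enumerate((100, 200, 300)):
    seeds = synthesize_seeds(spec, method=2, seed=jitter_seed)
    runs.append(run_pipeline([series], [seeds], PipelineConfig(seed=5 + i)))

report = compare_runs(runs)
print(f"myocardial contour DSC (runs 1 vs 2): {report.dsc_values[0]:.3f}")
print(f"segmental T2* mean difference ± LoA : {report.mean_difference:+.2f} ± {report.loa:.2f} ms")
print(f"segmental T2* test-retest CoV       : {report.cov_pct:.2f}%")
print(f"ICC(2,1) across 3 runs              : {report.icc:.3f}")
# High DSC and ICC with a small mean difference say the segmentation result
# barely depends on the observer's exact mid-wall trace - the reproducibility
# advantage the semi-automatic method is built for.
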