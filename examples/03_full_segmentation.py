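"""Run the full semi-automatic pipeline on a three-slice phantom subject.

For each slice: composite image -> LV blood-pool detection (k-means +
VFC active contours) -> endo/epicardial borders (radial-layer CoV search)
-> pixel-wise T2* map -> AHA segment medians.  Prints the 16 segmental
medians, the iron flags (median <= 20 ms), the global and mid-septal
summaries, and the agreement of the recovered myocardium with the ground
truth.
"""

import numpy as np

from myoseg.metrics import dice
from myoseg.phantom import default_phantom_set
from myoseg.pipeline import PipelineConfig, run_pipeline

phantoms = default_phantom_set(noise_sigma=48.0, rng_seed=7)
levels = ("apical", "mid", "basal")
result = run_pipeline(
    [phantoms[lvl][0] for lvl in levels],
    [phantoms[lvl][1].seeds_method2 for lvl in levels],
    PipelineConfig(seed=1),
)

for lvl in levels:
    sl = result.slices[lvl]
    truth = phantoms[lvl][1]
    d = dice(sl.contours.myo_mask, truth.myo_mask)
    print(f"{lvl:>7}: myocardium DSC vs truth {d:.3f}")
    for seg_id in sorted(sl.segmental.segment_medians):
        med = sl.segmental.segment_medians[seg_id]
        flag = " IRON" if sl.segmental.iron_flags[seg_id] else ""
        print(f"         AHA {seg_id:>2} {sl.segmental.segment_names[seg_id]:<22}"
              f" median {med:6.1f} ms{flag}")

print(f"global T2*     : {result.global_t2star:.1f} ms (mean of the 16 segment medians)")
print(f"mid-septal T2* : {result.mid_septal_t2star:.1f} ms (mean of mid antero-/inferoseptal)")
# Segments flagged IRON have a median at or below the 20 ms iron-loading
# threshold; on this phantom the lateral-wall sector carries the short T2*.
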