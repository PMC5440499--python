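"""Build the contrast-optimized composite image for one slice.

Places the surrounding-tissue ROIs from contoured seeds (method 2),
computes the per-echo CNR between the myocardium and each neighbour
(LV blood pool, RV blood pool, lung), selects the CNR-optimal echoes and
fuses them.  The printed gains say how much contrast-per-noise the
composite adds over the single best echo for each border.
"""

import numpy as np

from myoseg import composite
from myoseg.phantom import default_spec, generate_phantom

series, truth = generate_phantom(default_spec("mid", noise_sigma=48.0, rng_seed=7))
rois = composite.place_rois_method2(series, truth.seeds_method2)
cnr_table = composite.compute_cnr(series, rois)
selection = composite.select_optimal_tes(cnr_table)
comp = composite.build_composite(series, selection, rois, cnr_table)

print("per-echo CNR (region -> list over TE):")
for region in composite.REGIONS:
    cnrs = [r.cnr for r in cnr_table if r.region == region]
    print(f"  {region:>5}: {np.round(cnrs, 1)}")
te = series.te_list
print(f"selected TEs : LVBP {te[selection.te_lvbp]:.2f} ms, "
      f"RVBP {te[selection.te_rvbp]:.2f} ms, lung {te[selection.te_lung]:.2f} ms")
print(f"weights      : { {f'{te[i]:.2f} ms': round(w, 3) for i, w in selection.weights.items()} }")
print("composite CNR gain over best single echo (%):",
      {k: round(v, 1) for k, v in comp.cnr_gain_pct.items()})
# A positive gain means the weighted fusion shows the border more clearly
# than any individual echo - the reason it serves as segmentation template.
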