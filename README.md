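# myoseg

Semi-automatic left-ventricular myocardial segmentation and T2\*
quantification for **bright-blood multi-gradient-echo (MGE) cardiac MRI**.

Myocardial iron loading (thalassemia, hemochromatosis, sickle cell disease)
shortens the effective transverse relaxation time T2\*; a segmental median
T2\* ≤ 20 ms flags iron deposition. Quantifying it requires myocardial
contours on images where bright flowing blood ruins endocardial contrast,
and manual contouring is slow and observer-dependent. `myoseg` implements a
segmentation chain that needs only minimal manual input per slice (a rough
mid-wall trace, an air-background point, and either the anterior RV–LV
insertion point or RV/lung contours) and is aimed at researchers working on
cardiac relaxometry post-processing and segmentation reproducibility.

## Method

1. **Contrast-optimized composite image.** For each echo, the
   contrast-to-noise ratio between the LV myocardium and each surrounding
   region *s* ∈ {LV blood pool, RV blood pool, lung} is

   CNR = NF·|SI<sub>s</sub> − SI<sub>m</sub>| / σ<sub>b</sub>,

   with SI<sub>m</sub> sampled along the mid-wall trace and σ<sub>b</sub>
   the air-background SD. The CNR-optimal echoes are fused (weights 1/3
   each for three distinct echoes, 2:1 for two, 1 for one) into the
   template image for all later steps.
2. **LV blood pool.** A subtraction image (shortest TE minus the
   LVBP-optimal TE) makes the slowly decaying blood dark and homogeneous;
   k-means intensity clustering inside the mid-wall trace seeds the pool
   mask, and two vector-field-convolution (VFC) active contours shape the
   pool, the second re-joining papillary muscles and trabeculae.
3. **Myocardial borders.** One-pixel expansion layers × radial angular
   segments (72 on mid/basal slices, 40 apical; 14 mm / 8 mm expansion
   limits) are grown outward per segment while the cumulative intensity
   coefficient of variance stays ≤ 20%; two-cluster k-means refines the
   low-contrast anterior/septal/posterior borders, sparse outer layers are
   removed by 70%/40% occupancy cut-offs, neighbor layer counts are limited
   to differ by ≤ 2, and the final endo/epicardial contours are chosen among
   ±2-layer shifts by minimizing the scaled-IQR intensity-outlier ratio
   (factor 0.9825).
4. **T2\* mapping.** Pixel-wise bounded nonlinear least squares of the
   offset decay model y = K·e<sup>−TE/T2\*</sup> + C, aggregated as AHA
   16-segment medians (6 basal, 6 mid, 4 apical, anchored at the anterior
   insertion point), with global (mean of 16 medians) and mid-septal
   summaries and the ≤ 20 ms iron flag.
5. **Reproducibility statistics.** Dice similarity coefficient
   DSC = 2|A∩B|/(|A|+|B|), Bland–Altman mean difference with 1.96·SD limits
   of agreement, test–retest CoV, and the two-way random absolute-agreement
   ICC(2,1).

A synthetic short-axis phantom (annular myocardium with a focal low-T2\*
sector, bright blood pools, lung, Rician noise, eight-echo TE ladder) with
exact ground truth makes every stage testable without patient data.

## Worked example

`examples/` contains one narrative script per capability. The full
pipeline on the default three-slice phantom subject
(`python examples/03_full_segmentation.py`) prints, per slice, the
myocardial Dice against ground truth and the AHA segment medians:

```
    mid: myocardium DSC vs truth 0.953
         AHA  7 mid anterior           median   54.1 ms
         AHA  8 mid anteroseptal       median   51.7 ms
         AHA  9 mid inferoseptal       median   30.4 ms
         AHA 10 mid inferior           median   29.3 ms
         AHA 11 mid inferolateral      median   32.2 ms
         AHA 12 mid anterolateral      median   19.0 ms IRON
...
global T2*     : 34.4 ms (mean of the 16 segment medians)
mid-septal T2* : 41.0 ms (mean of mid antero-/inferoseptal)
```

The `IRON` tag marks the segment whose median falls at or below the 20 ms
iron-loading threshold — the phantom places its short-T2\* sector in the
lateral wall, and the pipeline recovers it. (At this noise level, SNR ≈ 20,
individual medians of normal myocardium scatter noticeably; see
`docs/methods.md` on the conditioning of the offset fit.)
`examples/02_composite_cnr.py` shows the per-echo CNR table and the
composite's CNR gain over the best single echo;
`examples/04_reproducibility.py` compares runs with jittered manual seeds
(contour DSC, Bland–Altman, CoV, ICC).

A thin CLI mirrors the library: `myoseg phantom`, `myoseg run`,
`myoseg compare` (see `myoseg --help`).

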