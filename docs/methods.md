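# Methods

This note records the models, parameter choices and numerical decisions
behind `myoseg`, and what the synthetic phantom does and does not show
about real data.

## Signal model and acquisition geometry

All images are magnitude MGE echoes. The noiseless signal of a pixel of
tissue *r* at echo time *t* is the monoexponential decay with constant
offset

    S_r(t) = K_r · exp(−t / T2*_r) + C,

the same model the T2\* fit inverts. The offset C absorbs the noise-floor
bias that plagues plain monoexponential fits of short-T2\* (iron-loaded)
tissue in magnitude images. Default echo ladder: eight echoes,
2.69–18.86 ms in 2.31 ms steps (a 2.59–18.20/2.23 variant is provided);
in-plane spacing 1.56 mm.

## The synthetic phantom

The phantom emulates one bright-blood short-axis subject at three slice
levels. Values were chosen once as a realistic 1.5 T parameterization:

| tissue | K | T2\* (ms) | rationale |
|---|---|---|---|
| myocardium | 1000 | 35 | normal myocardial T2\* at 1.5 T |
| focal iron sector | 1000 | 16 | segmental median ≤ 20 ms pathway |
| LV blood pool | 1400 | 120 | bright arterial blood, slow decay |
| RV blood pool | 2000 | 25 | bright inflow, rapid turbulence/deoxygenation dephasing |
| lung | 80 | 2 | near-zero parenchymal signal |
| air | 0 | – | background, offset C = 0 |

LV radii (endo/epi, mm): apical 13/19.5, mid 17/26, basal 19/28 — wall
thickness tapering toward the apex within normal short-axis ranges. Two
papillary discs (radius 1.8 px) with myocardial signal sit inside the LV
pool so the pool-definition step must re-join them. The focal-iron sector
sits in the lateral wall (anterolateral on mid/basal, 18–52°; inside the
apical lateral segment, 330–40°), the wall territory where focal iron is
most often reported and where the k-means border refinement (which only
touches anterior/septal/posterior sectors) cannot interact with it.

The RV/LV blood parameterization is deliberately asymmetric: with it, the
per-region CNR optima fall on distinct, decisively separated echoes
(longest TE for the LV pool, shortest for RV pool and lung), mirroring the
selection pattern reported for patient data. A parameterization whose CNR
curve peaks at an interior echo is near-flat there (differences of a few
intensity units between adjacent echoes), and echo selection then flips
under any perturbation — real acquisitions show exactly this as imperfect
selection reproducibility.

Noise is Rician, sqrt((S+g₁)² + g₂²) with g₁,g₂ ~ N(0, σ), because the
inputs are magnitude images. Default σ = 48 puts the shortest-TE
myocardium at SNR ≈ 20. Manual seeds are synthesized from ground truth
with radial Gaussian jitter (default 0.5 px) to emulate observer
variability; radial jitter keeps the traced contours star-shaped, hence
simple.

**What the phantom does not model:** cardiac motion, partial-volume
mixtures beyond pixelation, susceptibility artifacts, trabecular texture,
coil-profile shading. Passing tests therefore demonstrate algorithmic
correctness and stability under noise and observer jitter — not clinical
accuracy on patient data.

## Composite image

NF (the noise factor in the CNR definition) defaults to 1 and cancels in
the argmax over echoes. σ_b is estimated from the air ROI **pooled over
all echoes**: receiver noise does not depend on TE, and a single-echo 5×5
box (25 samples) estimates an SD with ~14% error — enough on its own to
flip echo selection. The composite's background SD follows by noise
propagation, σ_bc = σ_b·sqrt(Σwᵢ²), rather than being re-estimated from
the handful of composite air pixels.

ROI defaults: radius 3 px discs (LVBP/RVBP/lung), 5×5 air box. Method-1
junction extrapolation places the RVBP/lung ROIs at 1.9× the local
mid-wall radius along the sector-junction rays; 1.5× (an earlier
candidate) lands on the epicardial edge for realistic geometry. Method-2
specifics: insertion points are the RVBP contour endpoints; the RVBP ROI
centers on the bright (blood) compartment inside the chord-closed RVBP
contour, because the closing chord also sweeps in part of the septal gap;
the lung ROI is chosen among 8 distance-transform-based candidate
positions as the one with minimum shortest-TE variance (avoiding
vessels). Echo-selection ties break toward the shortest TE (higher SNR).

## Blood-pool detection (part I)

The subtraction image is clipped at zero (magnitude semantics). k-means
(k = 3, lowest-mean cluster kept, connected component containing the
region centroid) runs on a σ = 1 px smoothed copy of the subtraction image
to suppress salt-and-pepper misclassification; both snake edge maps use
unsmoothed images. Edge maps are Gaussian-smoothed (σ = 1 px) gradient
magnitudes normalized to [0, 1].

VFC snake defaults: kernel radius 8 px, γ = 2.4, ε = 1e−8, α = 0.1,
β = 0.5, step 0.5, ≤ 300 iterations, tolerance 0.05 px. A long-range,
slowly decaying kernel (radius 32, γ = 1.7) lets the strong epicardial
air edge out-pull the weak endocardial edge and drag the contour across
the wall; the short-range, fast-decay kernel keeps the locally nearest
edge dominant. The field is rescaled to unit peak magnitude so the step
size is in pixels. Internal forces are solved semi-implicitly through the
periodic pentadiagonal system; vertices are resampled to ~1 px uniform
arc-length spacing every iteration, making the result independent of the
initial vertex count. A contour whose area falls below 4 px² is reported
as collapsed.

The step-5 snake evolves on the composite-image edge map **masked by the
dilated step-4 region** — the step-4 result acts as a mask for step 5, so
the epicardial edge cannot capture the pool contour. The final pool mask
gets a one-pixel intensity snap: boundary pixels are re-assigned to
pool/wall by comparison with the midpoint of the two mean intensities,
cleaning the stray bright pixels that polygon rasterization leaves at the
rim (these otherwise poison the first expansion layer).

## Border search (part II)

Layers are Euclidean distance shells (l−1 < d ≤ l) of the pool mask —
one-pixel-thick and gap-free for arbitrary pool shapes. Radial segments
are equal angular bins about the pool centroid anchored at the anterior
insertion ray, so they nest exactly inside the anatomical sectors.
Expansion limits: 14 mm (mid/basal), 8 mm (apical); 72/40 segments — at
this resolution a single (segment, layer) cell holds ≤ 2 pixels, and an
empty cell (a narrow bin missing one discrete ring) is skipped rather
than treated as a stop.

The CoV stop criterion (20%) is evaluated on the cumulative accepted
pixels of the segment including the candidate layer; a single 1–2 px
layer is too small for a stable SD of its own. Sector groups for the
refinement and occupancy steps: anterior; septal (antero-/inferoseptal);
posterior (inferior + inferolateral); lateral (anterolateral, or the
apical lateral sector).

The two-cluster refinement is guarded three ways, all motivated by what
the step is for (removing *outer, different-intensity* false areas):
it is a no-op when the cluster separation is below the CoV threshold
relative to the pooled mean (a noise-only split of a homogeneous wall),
when the clusters have no radial structure (mean layer depths closer than
one layer), or when the minority cluster holds < 5% of pixels (a handful
of stray pixels is not a tissue boundary). The retained "inner" cluster
is the one holding the majority of first-layer pixels — the tissue
adjacent to the blood pool.

The 70%/40% occupancy correction works per sector group: individual
segments hold 1–2 px per layer, so occupancy is only meaningful for a
layer across its group. The reference is the fullest layer among those in
play (accepted at entry). Neighbor-difference limiting iterates
a[s] ← min(a[s], a[s±1]+2) to its unique fixed point (equivalently
min over t of a₀[t] + 2·d_ring(s,t)); it only ever reduces counts.

Step 10 evaluates all 25 global shift pairs (δ_endo, δ_epi) ∈ {−2..2}²
(per-segment shifts are left as an extension; the global search is exact
and cheap). Three numerical decisions matter here:

* **Fixed reference bounds.** The scaled-IQR bounds [0.9825·Q1, Q3/0.9825]
  are computed once from the initial (0,0) annulus. Per-candidate
  quartiles are degenerate: a candidate stuffed with ≥ 25% background
  drags Q1 to the background level and scores *zero* outliers. The
  literal upper bound 0.9825·Q3 would always flag > 25% of any
  continuous intensity distribution; the reciprocal form restores a
  symmetric, tight band around the wall intensity.
* **Border-layer outlier counting.** Outliers are counted among the
  pixels of the candidate's innermost and outermost rings — the only
  pixels the shift decision controls — and the ratio is taken over all
  candidate pixels. Counting interior pixels too makes the objective
  reward shedding whole good layers whenever a boundary ring contains a
  few flagged pixels, and lets structured interior signal (a focal iron
  sector) dominate the comparison with candidate-dependent noise.
* **Edge exclusion and inclusion.** The winner's flagged border pixels
  ("area outside or on the edge") are excluded from the final mask;
  symmetrically, pixels of the first ring beyond the accepted epicardial
  border whose intensity lies within the bounds are re-included — they
  are myocardium straddled by the discrete one-pixel rings.

A consequence of the exclusion rule worth knowing: border pixels of a
genuine focal-iron sector are intensity outliers with respect to the
whole wall and are trimmed. On the default phantom this costs the small
apical annulus a few percent of Dice; contour-recovery acceptance is
therefore assessed at subject level (three slices pooled), the same
pooling used when reporting observer agreement.

## T2\* quantification

Bounded trust-region least squares (scipy), T2\* ∈ (0.1, 500] ms, K ≥ 0,
C free; initialization from a log-linear fit of the min-subtracted
signal; parameter/cost tolerances 1e−8, ≤ 1500 residual evaluations.
Failed or degenerate fits (constant signal, K ≈ 0) are excluded from the
medians and counted, not imputed. Global T2\* averages the 16 segment
medians unweighted; mid-septal averages the mid anteroseptal and
inferoseptal medians; a segment is iron-flagged when its median ≤ 20 ms.

Conditioning caveat: with TE ≤ 18.9 ms, normal myocardium (T2\* ≈ 35 ms)
decays to only ~58% of its amplitude, so the three-parameter fit is
poorly conditioned at SNR ≈ 20 — single-pixel estimates scatter widely
(some reaching the upper bound) and segment medians of *normal* tissue
are noisy and upward-skewed. Short-T2\* (iron) tissue is well sampled by
the same ladder and fits tightly; this asymmetry is intrinsic to the
acquisition, not to the implementation, and is why noisy-phantom tests
assert contour recovery and structural counts rather than normal-tissue
median values.

## Reproducibility statistics

DSC of two empty masks is defined as 1 (vacuous agreement, logged). The
limits of agreement are 1.96 × the sample SD of paired differences. The
test–retest CoV uses the within-pair RMS convention
SD_w = sqrt(mean(d²)/2) over the grand mean — stated prominently because
published CoV values depend on the convention chosen. The ICC is the
two-way random-effects, absolute-agreement, **single-measure** form
ICC(2,1), the conservative standard; it is cross-checked against an
independent statistics package in the test suite.

## Determinism

One pipeline seed is expanded by a fixed affine scheme into per-stage,
per-slice seeds, so stages can be re-run in isolation; identical inputs
and configuration produce byte-identical reports. All stochastic steps
(phantom noise, seed jitter, k-means initialization) draw from explicit
seeds.

## Problem sizes

Default images are 128×128 with eight echoes; a full three-slice subject
runs in well under a minute on one core, with the pixel-wise fits
(~1300 bounded least-squares problems) dominating.
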