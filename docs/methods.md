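# Methods

`woundseg` implements a composite wound-segmentation model: a traditional
skin-with-wound detector that strips environmental background from a
photograph, a small fully-convolutional network that produces a preliminary
per-pixel wound probability, and a rule-based semantic correction that
refines the network mask. This note records the model assumptions, the
numerical choices made where the design was open, what the synthetic scenes
do and do not emulate, and the known limitations.

## Skin-with-wound detection

The detector rests on two assumptions about usable wound photographs: skin
pixels within one image are similar in color, and skin plus wound cover at
least 7% of the frame. Its working representation is the chroma-red (Cr)
plane of YCbCr, where skin concentrates in a narrow band (135–160 in
full-range statistics).

**Color conversion.** Full-range JPEG/JFIF coefficients,
`Cr = 128 + 0.5 R − 0.4187 G − 0.0813 B`, rounded half-up to integers so the
256-bin histogram is exact. The limited-range (BT.601 studio) dialect would
shift the skin band by several units; the choice is centralized in
`color_model` should a data source require switching.

**Fast path.** `p = max_δ N_L/N` over sliding windows `[μ0+δ, μ0+δ+d]`
(inclusive; `d = 25`, `μ0` the smallest occupied Cr value). If `p > ε = 0.92`
the frame is treated as all skin and background removal is skipped: a
distribution that concentrated cannot be a skin/background mixture without
violating the 7% assumption. The sweep is exhaustive over all 256 window
positions — at histogram scale this costs nothing.

**Dynamic thresholds.** Candidate thresholds are minima of the smoothed
histogram (centered moving average, window 5 — raw histograms of natural
images carry spurious single-bin minima) lying inside search windows
A = [130, 140] and B = [155, 165], excluding minima at the ends of the
occupied support. A pair (Cr_A, Cr_B) is accepted when its gap lies in
[15, 30] and the pixel fraction between the thresholds exceeds `gap / L`,
with `L` the width of the central-95% Cr interval (2.5th to 97.5th weighted
percentile). Open details resolved here: a window holding no minimum
contributes its smoothed argmin as candidate; among several admissible pairs
the one with the largest enclosed mass wins; on failure both windows
translate apart by 5 Cr units, at most 6 times, before falling back to the
static band (135, 160). The threshold interval is treated as closed.

**Markers and watershed.** The foreground seed is the hole-filled threshold
mask eroded by a disk of diameter `d1`; disjoint seed components are joined
by 3-px-wide straight lines between their centers of gravity (each centroid
snapped to its component's nearest pixel first, so the anchor lies on the
component even for crescent shapes). The background seed is the erosion of
the mask complement by a disk of diameter `d2`, unified by a one-pixel frame
appended around the plane carrying the mean Cr of the predicted background.
The watershed floods the morphological gradient of the framed Cr plane. Two
numerical choices matter here: the plane is denoised with a 3×3 median filter
before the gradient, and the gradient footprint is a radius-1 disk. With a
wider footprint (or no denoising) the interior texture of a heterogeneous
wound produces gradient responses rivaling true region edges, and the flood
systematically cedes the one- to two-pixel rim of boundary-touching wounds
to the background; the narrow denoised gradient keeps region edges dominant,
which the wound-retention suite verifies directly.

**Dark-wound recovery.** A near-black wound touching the skin silhouette
falls outside the Cr band and leaves a bite in the detected skin. Candidate
regions are collected from two disjoint pools — B, the gap between the skin
and its convex hull, and C, the part of the skin's dilation (disk of
diameter `d2`) outside that hull — cut into local pieces by segments pairing
each skin-hull vertex with the nearest vertex of the dilation's hull.
Keeping the two pools separate is essential: merging them lets a wound bite
share a piece with pure background rim, and the mixed statistics defeat the
color rule. Each piece is judged by mean RGB intensity ("close to black"
means mean < 60) and by the sum of per-channel variances (< 300 means flat
dark background, deleted; above, wound tissue, kept). Both constants are
configurable; the thresholds sit far from both populations the generator
produces (backgrounds are built lighter than 60; dark wound texture has
variance sums several times 300). Kept pieces become foreground seeds and
the watershed runs a second time. In that second run, background seeds
inside the hull of the dilated skin are demoted to unknown: the first-pass
background marking is exactly what the anomaly step distrusts there, and a
wound reaching past the skin hull would otherwise retain background seeds in
its interior that the second flood cannot overcome.

The detector runs with `d1 = 10, d2 = 20` before the network (priority:
never lose a wound pixel) and `d1 = 20, d2 = 10` after it (priority: delete
as much background as possible).

## Preprocessing and augmentation

Standardization is `(X − μ_X)/σ_X` over all pixels and channels of one image
jointly. Augmentation expands one image to 60 training crops as
6 deformations × 10 seeded random 512×512 crops; the deformation set —
identity, horizontal flip, ±10° rotation, and 0.9×/1.1× anisotropic
rescaling — was chosen as the smallest geometric family covering the
flip/rotate/scale variation the method relies on; the 6×10 factorization
itself is a design choice. Masks are transformed
with the identical geometry at nearest-neighbor interpolation so labels stay
binary. The six train/test compositions over raw images and their
background-removed twins are built from a seeded source-level hold-out split
(20%, i.e. 760/190 at the 950-image design size), so a raw image and its
preprocessed twin can never straddle the split.

## Segmentation network

The backbone is the 13 depthwise-separable stages of MobileNet behind a
3×3/stride-2 stem, channel widths scaled by a depth multiplier
DM ∈ {0.25, 0.5, 1.0}. The classifier is replaced by interpolation: a 1×1
two-class score convolution on the last stage (stride 32), bilinearly
upsampled 2×, added to the score of the last stride-16 stage (one fused
layer), and the fused map upsampled 16× to input resolution. Score-level
fusion was chosen over feature-level fusion (projecting the 1024-channel map
onto the 512-channel skip) because the latter would add half a million
parameters at DM = 1.0 and contradict the published size of the model; a 1×1
convolution and bilinear upsampling commute, so fusing at score resolution
is also the cheaper evaluation order of the same function. Both
interpolations are fixed bilinear, not learned. Training uses softmax cross
entropy, Adam, decoupled weight decay 4e-5 (the MobileNet convention; no
value is published for this model), batch normalization, minibatches of 5,
and the stepwise schedule `lr = 0.01 × 0.5^max(0, ⌊step/5000⌋ − 2)` — the
exponent is read as integer division, giving plateau-then-halve behavior
rather than continuous decay. Trainable parameters (conv weights, score
biases, batch-norm scale/shift) number 3.21 M / 0.82 M / 0.21 M for
DM = 1.0 / 0.5 / 0.25.

The layers themselves (im2col convolutions, depthwise convolutions, batch
norm, fixed bilinear resampling as separable dense interpolation matrices,
Adam) are implemented in numpy with explicit backward passes; a
finite-difference directional-derivative test in float64 pins every layer's
gradient. Everything is float32 in production, fully seeded, and
deterministic on CPU.

## Semantic correction

Applied to the binarized (0.5) network output, in order: fill holes (wounds
do not enclose healthy skin; background is 4-connected for the fill,
foreground components are 8-connected), delete minor regions with area below
`ε_d = min(max(A) × P_d, A_d)` (`P_d = 5%`, `A_d = 500` px; areas exactly
equal to `ε_d` survive, honoring the strict inequality), and keep a region
only if the post-profile skin detection covers more than `ε_s = 0.75` of it.
`A_d` is resolution-dependent by nature and therefore exposed as a
parameter; 500 px corresponds to the 512×512 working resolution.

## Synthetic scenes

The generator emulates the statistical structure the detector assumes, not
photographs: an elliptical "limb" whose per-pixel Cr concentrates in
[135, 160] (six base tones from light to dark, channel noise σ = 3), a
connected wound, and a background whose Cr stays at least a fast-path width
below every skin tone — a frame with substantial background must never
masquerade as all-skin. Wounds follow the four-category taxonomy crossing
color contrast with topology. Skin-like wounds are rendered relative to the
scene's own skin tone (offset +22 R, +26 G, −18 B: visibly brighter and
yellower, like slough, yet only ~+1.6 Cr units, so they stay inside the skin
band as "small contrast" requires); an absolute wound color cannot serve,
because against some skin tones it degenerates to an invisible — hence
unlearnable — wound. Near-black wounds use a dark base (mean ≈ 30) with
σ = 18 texture, giving variance sums well above the keep threshold, and are
clipped to the silhouette: wounds live on the body, so a boundary-touching
wound truncates at the limb edge rather than spilling into the scene.
Clutter blobs avoid the silhouette; when enabled, the first distractor is
wound-colored (flat, low-variance — it exercises the delete branch of the
recovery rule as well as the overlap filter).

What passing tests on these scenes shows: the detector's threshold search,
flood, and recovery logic behave as designed when their assumptions hold,
and the network can learn the wound concept from small data. What they do
not show: robustness to real-world violations — textured skin, shadows and
specular highlights, backgrounds sharing the skin's Cr band, wounds whose
appearance drifts between tissue types.

## Desk-scale experiment

The full 512×512 / 50 000-step configuration is supported but deliberately
not exercised by the test suite. The suite's learning experiment uses 40
sources of 160×160 scenes split 30/10, trains DM = 0.25 on 128×128 crops for
2000 steps (batch 5, the standard schedule), with the training side composed
of raw plus background-removed twins and the held-out side background-removed
(group 4) — the composition that matches what the full pipeline feeds the
network at inference. The 160→128 margin matters:
it gives the random crops genuine translation variety, the desk-scale analog
of cropping 512² windows from 800×600 photographs. Held-out IoU is pooled
over the suite (confusion counts summed, then one IoU); per-image averaging
is available as an option in the evaluation CLI. Training-curve summaries
report MaxIoU (curve maximum) and mIoU, the mean of the stationary tail,
by default the last half of the logged points (the stationary region is not
formally defined; the fraction is a parameter).

## Known limitations

- Skin-colored background objects that touch the detector's assumptions
  (Cr inside the band) are misjudged as skin, exactly as the underlying
  method's own error analysis anticipates; the semantic correction removes
  such regions only when the post-profile skin detection rejects them.
- The 16× upsampling smooths wound boundaries; no CRF-style refinement is
  applied.
- The anomaly recovery reaches at most one dilation diameter past the convex
  hull of the detected skin; a dark wound protruding far beyond the limb
  silhouette (not producible by the generator, which clips wounds to the
  body) would be truncated.
- The numpy network trains at desk scale in minutes but is not built for
  512×512 / 50 000-step production training; that configuration is provided
  for completeness, not speed.
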