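# woundseg

Composite wound segmentation for clinical photographs: a traditional
Cr-channel **skin-with-wound detector** removes the environmental background,
a **depthwise-separable fully-convolutional network** produces a preliminary
per-pixel wound probability, and a **semantic correction** stage refines the
mask with rules derived from how wounds relate to skin. The package targets
researchers working on automatic wound measurement and tissue analysis, where
photographs carry cluttered backgrounds that plain pixel classifiers confuse
with wound tissue, and where labeled data is too scarce to train large
networks.

## The model

**Background removal.** Skin pixels concentrate in a narrow band of the
chroma-red channel, Cr = 128 + 0.5R − 0.4187G − 0.0813B. The detector first
predicts the skin proportion

&nbsp;&nbsp;&nbsp;&nbsp;p = max<sub>δ</sub> N<sub>L</sub>/N,&nbsp;&nbsp;
L = {pixel | Cr ∈ [μ₀+δ, μ₀+d+δ]},

and skips background removal when p > ε (ε = 0.92, d = 25): such a frame is
essentially all skin. Otherwise it searches the smoothed Cr histogram for a
minima pair (Cr_A, Cr_B) bracketing the skin band, subject to a gap
constraint L_m ∈ [15, 30] and a mass constraint p_m > L_m/L, thresholds the
plane, cleans the mask into foreground/background seeds (hole filling,
erosion by circular elements d₁/d₂, component joining), and floods the
morphological gradient of the Cr plane with a marker-based watershed.
Near-black wounds cut off at the skin boundary are recovered from the
convex-hull/dilation band of the detected skin by a darkness + variance rule
and a second watershed pass.

**Network.** Thirteen depthwise-separable MobileNet stages (channel widths
scaled by a depth multiplier DM ∈ {0.25, 0.5, 1.0}), two-class 1×1 score
convolutions, one fused skip (stride-16), 16× bilinear upsampling to input
resolution. Training: Adam, weight decay, batch norm, minibatches of 5, and
lr = 0.01 × 0.5^max(0, ⌊step/5000⌋−2). The network is implemented directly
in numpy with explicit backward passes and is fully deterministic on CPU.

**Correction.** On the binarized network output: fill holes (wounds do not
enclose healthy skin); delete regions with area below
ε_d = min(max(A)·P_d, A_d) (P_d = 5%, A_d = 500); keep a region R_w only if
area(R_s ∩ R_w)/area(R_w) > ε_s = 0.75 against a second, background-hostile
skin detection (d₁ = 20, d₂ = 10).

Because the labeled wound-photo corpus this family of methods was developed
on is not publicly available, the package ships a seeded synthetic-scene
generator (`woundseg.synthetic_data`) producing limb/wound/background scenes
with ground-truth labels across the four skin–wound relationship categories;
all tests and the desk-scale training experiment run on it. See
`docs/methods.md` for every modeling choice and its rationale.

## Worked example

```python
from woundseg import detect_skin, confusion, iou
from woundseg.synthetic_data import SceneSpec, generate_scene

scene = generate_scene(SceneSpec(category=4, size=(512, 512),
                                 background_clutter=0, seed=3))
mask, info = detect_skin(scene.image)

print(f"fast path taken: {info['fast_path']}")
print(f"dynamic thresholds: Cr in [{info['thresholds'].cr_low}, {info['thresholds'].cr_high}]")
print(f"skin-with-wound IoU vs ground truth: {iou(confusion(mask, scene.skin_mask)):.4f}")
wound = scene.wound_mask
print(f"wound pixels retained: {(mask & wound).sum() / wound.sum():.1%}")
```

prints

```
fast path taken: False
dynamic thresholds: Cr in [135, 160]
skin-with-wound IoU vs ground truth: 0.9997
wound pixels retained: 99.7%
```

The scene is the hardest category — a near-black wound breaking the skin
silhouette. The detector's threshold step alone would hand that wound to the
background (its Cr lies below the skin band); the recovery pass brings
99.7% of its pixels back while the detected skin-with-wound region matches
the ground-truth silhouette almost exactly.

The same flow from the shell:

```
woundseg synth --n 4 --size 512 --seed 1 --out scenes/
woundseg skin-detect scenes/scene_003.png --out mask.png --profile pre
woundseg train --manifest manifest.json --dm 0.25 --steps 2000 --seed 1 --out model.npz
woundseg run scenes/scene_003.png --model model.npz --out wound.png
```

Checkpoints are numpy `.npz` archives holding all weights, batch-norm
running statistics and the network configuration.

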