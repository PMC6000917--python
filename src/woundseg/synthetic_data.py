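"""Seeded generator of synthetic wound scenes with ground-truth labels.

Each scene is an RGB photograph stand-in containing

* a smooth elliptical *skin* region ("limb") whose per-pixel Cr values
  concentrate in the skin band [135, 160],
* a connected *wound* region, either reddish skin-like or near-black with
  high channel variance, and
* a cluttered non-skin *background* whose Cr stays outside the skin band,
  optionally with distractor blobs (including a wound-colored one).

The four skin/wound relationship categories cross color contrast with
topology:

1. small contrast, wound enclosed by skin;
2. small contrast, wound touching the skin boundary;
3. large contrast (near-black wound), enclosed;
4. large contrast (near-black wound), touching the boundary.

Wounds lie on the body, so boundary-touching wounds are clipped at the skin
silhouette rather than spilling into the background.  Illumination shading is
applied as a common offset on all three channels, which leaves Cr invariant
by construction of the YCbCr transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SceneSpec", "LabeledScene", "generate_scene", "generate_suite",
           "BACKGROUND_LABEL", "SKIN_LABEL", "WOUND_LABEL"]

BACKGROUND_LABEL = 0
SKIN_LABEL = 1
WOUND_LABEL = 2

# Skin base colors, light to dark; all have Cr in [141, 153] so that with the
# sigma=3 channel noise well over 90% of skin pixels stay inside [135, 160].
SKIN_PALETTE = [
    (233, 194, 168),
    (214, 169, 143),
    (188, 152, 124),
    (158, 122, 94),
    (128, 98, 76),
    (96, 72, 56),
]

#: Skin-like wound tissue ("small contrast") is rendered relative to the
#: scene's own skin tone: visibly brighter and yellower, like slough or
#: granulation sheen, but with a near-zero Cr offset so it stays inside the
#: skin band the way the taxonomy requires (0.5*22 - 0.4187*26 + 0.0813*18
#: is about +1.6 Cr units).
WOUND_SKINLIKE_OFFSET = (22.0, 26.0, -18.0)
#: Near-black wound tissue; high per-channel variance is added at render time.
WOUND_DARK = (34, 26, 30)

# Backgrounds: mean intensity above the "close to black" bound, Cr well below
# the skin band (Cr <= 113, more than the fast-path window width away from
# every skin tone, so a scene with substantial background is never mistaken
# for an all-skin image).
BACKGROUND_PALETTE = [
    (80, 105, 140),
    (84, 126, 92),
    (75, 105, 130),
]

# Clutter colors with Cr outside [135, 160] (both below and above the band).
CLUTTER_PALETTE = [
    (60, 80, 110),
    (150, 60, 70),
    (200, 200, 200),
    (90, 140, 80),
]

SKIN_NOISE_SIGMA = 3.0
WOUND_DARK_NOISE_SIGMA = 18.0
BACKGROUND_NOISE_SIGMA = 4.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    category : 1-4 taxonomy described in the module docstring.
    size : (H, W); production scenes are >= 512 px per side, tests may
        override with a smaller scale.
    skin_fraction : fraction of the frame covered by the skin silhouette
        (skin + wound); must be at least 0.07, the detector's working
        assumption about usable wound photographs.
    wound_color_mode : "skin-like" or "near-black"; forced to "near-black"
        for categories 3 and 4.
    background_clutter : number of distractor blobs; when positive, the first
        distractor is wound-colored.
    """

    category: int
    size: tuple[int, int] = (512, 512)
    skin_fraction: float = 0.35
    wound_color_mode: str = "auto"
    background_clutter: int = 0
    wound_fraction: float = 0.12  # wound area as a fraction of the silhouette
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3, 4):
            raise ValueError("category must be 1, 2, 3 or 4")
        if self.skin_fraction < 0.07:
            raise ValueError("skin_fraction must be at least 0.07")
        if min(self.size) < 32:
            raise ValueError("scene too small to draw")

    @property
    def resolved_color_mode(self) -> str:
        if self.wound_color_mode != "auto":
            return self.wound_color_mode
        return "skin-like" if self.category in (1, 2) else "near-black"


@dataclass
class LabeledScene:
    image: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W) uint8 over {BACKGROUND, SKIN, WOUND}_LABEL
    spec: SceneSpec = field(repr=False)

    @property
    def wound_mask(self) -> np.ndarray:
        return self.labels == WOUND_LABEL

    @property
    def skin_mask(self) -> np.ndarray:
        """Skin-with-wound silhouette (the detector's target)."""
        return self.labels != BACKGROUND_LABEL


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _silhouette(spec: SceneSpec, rng: np.random.Generator):
    """Elliptical limb silhouette matching the requested area fraction."""
    h, w = spec.size
    area = spec.skin_fraction * h * w
    for _ in range(50):
        aspect = rng.uniform(1.3, 2.1)
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        if 2 * a > 0.94 * min(h, w):
            continue
        angle = rng.uniform(0, np.pi)
        # footprint of the rotated ellipse along each image axis
        ry = np.sqrt((a * np.sin(angle)) ** 2 + (b * np.cos(angle)) ** 2)
        rx = np.sqrt((a * np.cos(angle)) ** 2 + (b * np.sin(angle)) ** 2)
        if 2 * ry > 0.96 * h or 2 * rx > 0.96 * w:
            continue
        cy = h / 2 + rng.uniform(-1, 1) * (h / 2 - ry - 2)
        cx = w / 2 + rng.uniform(-1, 1) * (w / 2 - rx - 2)
        return _ellipse_mask((h, w), (cy, cx), (a, b), angle), (cy, cx, a, b, angle)
    raise ValueError(
        f"skin_fraction {spec.skin_fraction} cannot be drawn inside a "
        f"{h}x{w} frame"
    )


def _wound_mask(
    spec: SceneSpec,
    silhouette: np.ndarray,
    geom: tuple[float, float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    cy, cx, a, b, angle = geom
    r = np.sqrt(spec.wound_fraction * silhouette.sum() / np.pi)
    c, s = np.cos(angle), np.sin(angle)
    if spec.category in (1, 3):
        # enclosed: center strictly inside, wound circle clear of the boundary
        margin = r + max(3.0, 0.03 * min(a, b))
        if margin >= min(a, b):
            raise ValueError("wound too large to be enclosed by the silhouette")
        phi = rng.uniform(0, 2 * np.pi)
        u = rng.uniform(0, 0.7) * (a - margin) * np.cos(phi)
        v = rng.uniform(0, 0.7) * (b - margin) * np.sin(phi)
    else:
        # boundary-touching: center on the silhouette edge; the wound is
        # clipped to the silhouette (wounds live on the body)
        phi = rng.uniform(0, 2 * np.pi)
        u = a * np.cos(phi)
        v = b * np.sin(phi)
    wy = cy + u * s + v * c
    wx = cx + u * c - v * s
    wound = _ellipse_mask(silhouette.shape, (wy, wx), (r, r), 0.0)
    wound &= silhouette
    if not wound.any():
        raise ValueError("wound placement produced an empty region")
    return wound


def _scene_skin_color(spec: SceneSpec) -> tuple[float, float, float]:
    """Skin palette tone for this scene, a deterministic function of the seed
    (shared between the skin painter and the wound-colored distractor)."""
    idx = np.random.default_rng(spec.seed ^ 0x5EED).integers(len(SKIN_PALETTE))
    return tuple(float(v) for v in SKIN_PALETTE[idx])


def _skinlike_wound_color(skin_color) -> tuple[float, float, float]:
    return tuple(
        float(np.clip(c + o, 0, 255)) for c, o in zip(skin_color, WOUND_SKINLIKE_OFFSET)
    )


def _paint(
    canvas: np.ndarray,
    region: np.ndarray,
    color: tuple[int, int, int],
    sigma: float,
    rng: np.random.Generator,
) -> None:
    n = int(region.sum())
    noise = rng.normal(0.0, sigma, size=(n, 3))
    canvas[region] = np.asarray(color, dtype=np.float64) + noise


def _place_clutter(
    spec: SceneSpec,
    canvas: np.ndarray,
    silhouette: np.ndarray,
    rng: np.random.Generator,
) -> None:
    h, w = spec.size
    forbidden = silhouette.copy()
    skin_color = _scene_skin_color(spec)
    if spec.resolved_color_mode == "skin-like":
        wound_color = _skinlike_wound_color(skin_color)
    else:
        wound_color = WOUND_DARK
    for i in range(spec.background_clutter):
        if i == 0:
            color, sigma = wound_color, 4.0  # wound-colored distractor, low variance
        else:
            color = CLUTTER_PALETTE[rng.integers(len(CLUTTER_PALETTE))]
            sigma = 4.0
        r = rng.uniform(0.04, 0.09) * min(h, w)
        for _ in range(40):
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
            blob = _ellipse_mask((h, w), (cy, cx), (r, r * rng.uniform(0.6, 1.0)),
                                 rng.uniform(0, np.pi))
            if not (blob & forbidden).any():
                _paint(canvas, blob, color, sigma, rng)
                forbidden |= blob
                break


def generate_scene(spec: SceneSpec) -> LabeledScene:
    """Render one labeled scene; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    canvas = np.empty((h, w, 3), dtype=np.float64)

    background = BACKGROUND_PALETTE[rng.integers(len(BACKGROUND_PALETTE))]
    _paint(canvas, np.ones((h, w), dtype=bool), background, BACKGROUND_NOISE_SIGMA, rng)

    silhouette, geom = _silhouette(spec, rng)
    _place_clutter(spec, canvas, silhouette, rng)

    skin_color = _scene_skin_color(spec)
    _paint(canvas, silhouette, skin_color, SKIN_NOISE_SIGMA, rng)

    wound = _wound_mask(spec, silhouette, geom, rng)
    if spec.resolved_color_mode == "skin-like":
        _paint(canvas, wound, _skinlike_wound_color(skin_color), 5.0, rng)
    else:
        _paint(canvas, wound, WOUND_DARK, WOUND_DARK_NOISE_SIGMA, rng)
        # keep dark pixels honestly dark but not pure zero
        canvas[wound] = np.clip(canvas[wound], 3.0, 110.0)

    # illumination gradient: common offset on R, G and B leaves Cr unchanged
    ramp = np.linspace(-6.0, 6.0, w)[None, :, None] * rng.choice([-1.0, 1.0])
    canvas += ramp

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[silhouette] = SKIN_LABEL
    labels[wound] = WOUND_LABEL
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return LabeledScene(image=image, labels=labels, spec=spec)


def generate_suite(
    n: int,
    seed: int,
    size: tuple[int, int] = (512, 512),
    background_clutter: int = 2,
) -> list[LabeledScene]:
    """Generate ``n`` scenes cycling through categories 1..4 with randomized
    nuisance parameters (skin fraction, wound size, palette, geometry)."""
    if n <= 0:
        raise ValueError("n must be positive")
    root = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        sub = int(root.integers(0, 2**31 - 1))
        nuisance = np.random.default_rng(sub)
        spec = SceneSpec(
            category=(i % 4) + 1,
            size=size,
            skin_fraction=float(nuisance.uniform(0.25, 0.45)),
            wound_fraction=float(nuisance.uniform(0.08, 0.16)),
            background_clutter=background_clutter,
            seed=sub,
        )
        scenes.append(generate_scene(spec))
    return scenes
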