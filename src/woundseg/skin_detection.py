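"""Skin-with-wound detection and environmental-background removal.

The detector segments the union of skin and wound from a cluttered
environmental background using only the Cr plane:

1. *Fast path* — if a single sliding Cr window of width ``d`` holds more than
   a fraction ``epsilon`` of all pixels, the image is essentially all skin and
   background removal is skipped.
2. *Dynamic thresholds* — otherwise a pair of histogram minima bracketing the
   skin band is searched for, subject to a gap constraint and a mass
   constraint; a static band is the fallback.
3. *Marker-based watershed* — the thresholded mask is cleaned into foreground
   and background seed markers (hole filling, erosion, joining), and a
   watershed on the morphological gradient of the Cr plane assigns the
   remaining pixels.
4. *Dark-wound recovery* — near-black wounds that touch the skin boundary are
   cut off by the Cr threshold; they are recovered from the convex-hull /
   dilation band of the detected skin by a color + variance rule, and the
   watershed is run a second time with the recovered seeds.

The same detector runs twice in the full pipeline with different erosion
diameters: a wound-preserving profile before the network (``d1=10, d2=20``)
and a background-hostile profile after it (``d1=20, d2=10``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull
from skimage.draw import line as draw_line
from skimage.morphology import convex_hull_image, dilation, disk, erosion
from skimage.segmentation import watershed

from .color_model import CR_SKIN_BAND, cr_histogram, rgb_to_cr

__all__ = [
    "SkinParams",
    "ThresholdPair",
    "MarkerMap",
    "MarkerError",
    "FOREGROUND",
    "BACKGROUND",
    "UNKNOWN",
    "predict_skin_proportion",
    "dynamic_thresholds",
    "threshold_mask",
    "build_markers",
    "watershed_segment",
    "recover_dark_wounds",
    "detect_skin",
    "remove_background",
]

# Marker labels; 0 must stay UNKNOWN because the watershed treats 0 as unseeded.
UNKNOWN = 0
FOREGROUND = 1
BACKGROUND = 2


class MarkerError(ValueError):
    """A morphological marker step produced an empty seed region."""


@dataclass(frozen=True)
class SkinParams:
    """Tunable constants of the skin-with-wound detector.

    epsilon : fast-path proportion threshold.
    d : fast-path window width in Cr units.
    a_interval / b_interval : initial search windows for the lower / upper
        dynamic threshold (Cr units).
    l_min, l_max : admissible gap between the two thresholds (Cr units).
    d1, d2 : diameters (px) of the circular structuring elements eroding the
        foreground and background seed regions.
    black_mean_max : mean intensity below which a recovered region counts as
        "close to black".
    var_sum_min : minimum sum of per-channel RGB variances for a black region
        to be kept as wound rather than deleted as background.
    """

    epsilon: float = 0.92
    d: int = 25
    a_interval: tuple[int, int] = (130, 140)
    b_interval: tuple[int, int] = (155, 165)
    l_min: int = 15
    l_max: int = 30
    d1: int = 10
    d2: int = 20
    black_mean_max: float = 60.0
    var_sum_min: float = 300.0
    # Dynamic-threshold search schedule: windows translated apart by
    # `window_step` Cr units per retry, at most `max_translations` retries.
    window_step: int = 5
    max_translations: int = 6
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if not (self.a_interval[0] < self.a_interval[1] < self.b_interval[0] < self.b_interval[1]):
            raise ValueError("threshold search windows must be ordered and disjoint")
        if not self.l_min < self.l_max:
            raise ValueError("l_min must be smaller than l_max")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("structuring-element diameters must be positive")

    @classmethod
    def pre_profile(cls, **overrides) -> "SkinParams":
        """Wound-preserving profile used before the network (d1=10, d2=20)."""
        return cls(**{"d1": 10, "d2": 20, **overrides})

    @classmethod
    def post_profile(cls, **overrides) -> "SkinParams":
        """Background-hostile profile used after the network (d1=20, d2=10)."""
        return cls(**{"d1": 20, "d2": 10, **overrides})

    def with_overrides(self, **overrides) -> "SkinParams":
        return replace(self, **overrides)


class ThresholdPair(NamedTuple):
    cr_low: int
    cr_high: int

    @property
    def gap(self) -> int:
        return self.cr_high - self.cr_low


@dataclass(frozen=True)
class MarkerMap:
    """Tri-state seed image for the watershed.

    ``labels`` has one extra pixel of frame on every side relative to the
    source image; the frame is labelled BACKGROUND and, on the Cr plane, is
    filled with ``frame_value`` (the mean Cr of the predicted background) so
    that it joins every background patch into a single seed component.
    """

    labels: np.ndarray  # (H+2, W+2) int8 over {UNKNOWN, FOREGROUND, BACKGROUND}
    frame_value: float


def _disk(diameter: int) -> np.ndarray:
    return disk(max(1, diameter // 2))


# ---------------------------------------------------------------------------
# Step 1: fast path
# ---------------------------------------------------------------------------

def predict_skin_proportion(
    hist: np.ndarray, params: SkinParams
) -> tuple[float, tuple[int, int]]:
    """Predicted skin proportion p and the maximising Cr window.

    p is the largest fraction of pixels falling in any window
    ``[mu0 + delta, mu0 + d + delta]`` (inclusive, width ``d``), where ``mu0``
    is the smallest occupied Cr value.  A very concentrated Cr distribution
    cannot be a skin/background mixture, so when ``p > epsilon`` the caller
    treats the whole image as skin and skips background removal.
    """
    hist = np.asarray(hist, dtype=np.int64)
    total = int(hist.sum())
    if total == 0:
        raise ValueError("empty histogram")
    occupied = np.nonzero(hist)[0]
    mu0 = int(occupied[0])
    csum = np.concatenate([[0], np.cumsum(hist)])
    best_p, best_window = -1.0, (mu0, mu0 + params.d)
    for lo in range(mu0, 256):
        hi = min(lo + params.d, 255)
        mass = csum[hi + 1] - csum[lo]
        p = mass / total
        if p > best_p:
            best_p, best_window = p, (lo, lo + params.d)
    return best_p, best_window


# ---------------------------------------------------------------------------
# Step 2: dynamic thresholds
# ---------------------------------------------------------------------------

def _smoothed_histogram(hist: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges padded by replication."""
    half = window // 2
    padded = np.pad(hist.astype(np.float64), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _histogram_minima(hist: np.ndarray, params: SkinParams) -> np.ndarray:
    """Cr values of interior minima of the smoothed histogram.

    Minima lying at the extreme occupied bins of the support are discarded:
    the ends of the support are trivially low and would otherwise always win.
    """
    smoothed = _smoothed_histogram(hist, params.smoothing_window)
    minima, _ = find_peaks(-smoothed)
    occupied = np.nonzero(hist)[0]
    if occupied.size == 0:
        return np.array([], dtype=int)
    lo_occ, hi_occ = int(occupied[0]), int(occupied[-1])
    return minima[(minima > lo_occ) & (minima < hi_occ)]


def _central_interval_width(hist: np.ndarray, coverage: float = 0.95) -> int:
    """Width of the central `coverage` Cr interval (between the 2.5th and
    97.5th weighted percentiles for the default coverage)."""
    total = hist.sum()
    csum = np.cumsum(hist)
    tail = (1.0 - coverage) / 2.0
    lo = int(np.searchsorted(csum, tail * total, side="left"))
    hi = int(np.searchsorted(csum, (1.0 - tail) * total, side="left"))
    return max(hi - lo, 1)


def dynamic_thresholds(hist: np.ndarray, params: SkinParams) -> ThresholdPair:
    """Search the histogram for a (lower, upper) Cr threshold pair.

    Candidate thresholds are smoothed-histogram minima inside the A and B
    search windows (the window's smoothed argmin stands in when a window holds
    no minimum).  A pair (Cr_A, Cr_B) is admissible when its gap
    L_m = Cr_B - Cr_A lies in [l_min, l_max] and the pixel fraction p_m inside
    [Cr_A, Cr_B] exceeds L_m / L, with L the width of the central-95% Cr
    interval.  Among admissible pairs of a round the one with the largest p_m
    wins.  If a round fails, both windows are translated apart by
    ``window_step`` and the search retries; after ``max_translations`` retries
    the static skin band is returned.
    """
    hist = np.asarray(hist, dtype=np.int64)
    total = int(hist.sum())
    if total == 0:
        raise ValueError("empty histogram")
    minima = _histogram_minima(hist, params)
    smoothed = _smoothed_histogram(hist, params.smoothing_window)
    big_l = _central_interval_width(hist)
    csum = np.concatenate([[0], np.cumsum(hist)])

    def candidates(window: tuple[int, int]) -> list[int]:
        lo = max(0, window[0])
        hi = min(255, window[1])
        inside = minima[(minima >= lo) & (minima <= hi)]
        if inside.size:
            return [int(v) for v in inside]
        return [lo + int(np.argmin(smoothed[lo : hi + 1]))]

    for shift in range(params.max_translations + 1):
        step = shift * params.window_step
        a_win = (params.a_interval[0] - step, params.a_interval[1] - step)
        b_win = (params.b_interval[0] + step, params.b_interval[1] + step)
        best: tuple[float, ThresholdPair] | None = None
        for cr_a in candidates(a_win):
            for cr_b in candidates(b_win):
                gap = cr_b - cr_a
                if not params.l_min <= gap <= params.l_max:
                    continue
                p_m = (csum[cr_b + 1] - csum[cr_a]) / total
                if p_m > gap / big_l:
                    if best is None or p_m > best[0]:
                        best = (p_m, ThresholdPair(cr_a, cr_b))
        if best is not None:
            return best[1]
    return ThresholdPair(*CR_SKIN_BAND)


def threshold_mask(crmap: np.ndarray, thresholds: ThresholdPair) -> np.ndarray:
    """Binary mask of pixels with Cr in the closed band [cr_low, cr_high]."""
    crmap = np.asarray(crmap)
    return (crmap >= thresholds.cr_low) & (crmap <= thresholds.cr_high)


# ---------------------------------------------------------------------------
# Step 3: markers + watershed
# ---------------------------------------------------------------------------

def _component_anchor(labels: np.ndarray, component: int) -> tuple[int, int]:
    """Pixel of `component` nearest its center of gravity (the centroid itself
    may fall outside a non-convex component)."""
    rows, cols = np.nonzero(labels == component)
    cy, cx = rows.mean(), cols.mean()
    idx = np.argmin((rows - cy) ** 2 + (cols - cx) ** 2)
    return int(rows[idx]), int(cols[idx])


def _join_components(mask: np.ndarray) -> np.ndarray:
    """Connect all components of a binary mask with 3-px-wide straight lines
    between their centers of gravity (star topology rooted at the largest)."""
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    anchors = [_component_anchor(labels, i) for i in range(1, n + 1)]
    root = anchors[int(np.argmax(areas))]
    joined = mask.copy()
    for anchor in anchors:
        rr, cc = draw_line(root[0], root[1], anchor[0], anchor[1])
        joined[rr, cc] = True
    # dilate only the drawn lines to width 3 so the watershed cannot sever them
    lines = joined & ~mask
    joined |= dilation(lines, disk(1))
    return joined


def build_markers(mask: np.ndarray, crmap: np.ndarray, params: SkinParams) -> MarkerMap:
    """Turn a thresholded skin mask into watershed seed markers.

    Foreground: hole-filled mask eroded by a disk of diameter ``d1``; multiple
    surviving components are joined by thin lines between their centers of
    gravity.  Background: the complement of the filled mask eroded by a disk of
    diameter ``d2``, joined into one component by a 1-px frame appended around
    the image whose Cr value is the mean Cr of the predicted background.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MarkerError("empty skin mask: nothing to mark as foreground")
    filled = ndimage.binary_fill_holes(mask)
    fg = erosion(filled, _disk(params.d1))
    if not fg.any():
        raise MarkerError(
            f"foreground erosion with d1={params.d1} annihilated every seed; "
            "reduce d1 or check the threshold mask"
        )
    fg = _join_components(fg)

    bg = erosion(~filled, _disk(params.d2))
    bg &= ~fg
    background_cr = crmap[~filled] if (~filled).any() else crmap[mask]
    frame_value = float(background_cr.mean())

    labels = np.full((mask.shape[0] + 2, mask.shape[1] + 2), BACKGROUND, dtype=np.int8)
    interior = np.full(mask.shape, UNKNOWN, dtype=np.int8)
    interior[fg] = FOREGROUND
    interior[bg] = BACKGROUND
    labels[1:-1, 1:-1] = interior
    return MarkerMap(labels=labels, frame_value=frame_value)


def _framed_gradient(crmap: np.ndarray, frame_value: float) -> np.ndarray:
    """Morphological gradient of the framed Cr plane.

    The plane is denoised with a 3x3 median filter first and the gradient uses
    a radius-1 disk: a wider footprint or no denoising lets textured wound
    interiors rival true edges, which biases the flood against the narrow rim
    of boundary-touching wounds.
    """
    framed = np.pad(crmap.astype(np.float64), 1, constant_values=frame_value)
    framed = ndimage.median_filter(framed, size=3)
    selem = disk(1)
    return dilation(framed, selem) - erosion(framed, selem)


def watershed_segment(crmap: np.ndarray, markers: MarkerMap) -> np.ndarray:
    """Flood the morphological gradient of the (framed) Cr plane from the seed
    markers; returns the binary skin-with-wound mask with the frame stripped."""
    labels = markers.labels
    if not (labels == FOREGROUND).any() or not (labels == BACKGROUND).any():
        raise MarkerError("markers must contain both a foreground and a background seed")
    gradient = _framed_gradient(np.asarray(crmap), markers.frame_value)
    if gradient.shape != labels.shape:
        raise ValueError("marker map does not match the Cr map it was built from")
    flooded = watershed(gradient, markers=labels.astype(np.int32))
    return (flooded == FOREGROUND)[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# Step 4: dark-wound anomaly recovery
# ---------------------------------------------------------------------------

def _hull_vertices(mask: np.ndarray) -> np.ndarray:
    points = np.column_stack(np.nonzero(mask))
    if len(points) < 3:
        return points
    hull = ConvexHull(points)
    return points[hull.vertices]


def _candidate_regions(mask: np.ndarray, params: SkinParams) -> np.ndarray:
    """Label image of the small candidate regions around the detected skin.

    Two disjoint pools are labeled separately: B, the gap between the skin and
    its convex hull (where a boundary-touching wound leaves its bite), and C,
    the part of the skin's dilation outside that hull (pure rim).  Both pools
    are additionally cut apart by segments pairing each skin-hull vertex with
    the nearest vertex of the dilation's hull, so judgments stay local.
    """
    dilated = dilation(mask, _disk(params.d2))
    hull_skin = convex_hull_image(mask)
    b_area = hull_skin & ~mask
    c_area = dilated & ~hull_skin
    if not (b_area | c_area).any():
        return np.zeros(mask.shape, dtype=np.int32)
    # segments pairing each skin-hull vertex with the nearest dilation-hull vertex
    cuts = np.zeros(mask.shape, dtype=bool)
    v_skin = _hull_vertices(mask)
    v_dil = _hull_vertices(dilated)
    if len(v_skin) and len(v_dil):
        for vy, vx in v_skin:
            d2_all = (v_dil[:, 0] - vy) ** 2 + (v_dil[:, 1] - vx) ** 2
            wy, wx = v_dil[np.argmin(d2_all)]
            rr, cc = draw_line(int(vy), int(vx), int(wy), int(wx))
            cuts[rr, cc] = True
    pieces_b, n_b = ndimage.label(b_area & ~cuts)
    pieces_c, _ = ndimage.label(c_area & ~cuts)
    pieces = pieces_b.astype(np.int32)
    pieces[pieces_c > 0] = pieces_c[pieces_c > 0] + n_b
    return pieces


def recover_dark_wounds(
    mask: np.ndarray,
    image: np.ndarray,
    crmap: np.ndarray,
    params: SkinParams,
) -> np.ndarray:
    """Recover near-black wound parts that the Cr threshold cut off.

    Wounds that touch the skin silhouette and are close to black fall outside
    the skin Cr band, so the first watershed hands them to the background.
    Such a wound leaves a bite in the detected skin; it is found among the
    small regions between the skin, its convex hull and the hull of its
    dilation.  Per region: a non-black mean color means environmental
    background (deleted); near-black with a low sum of per-channel RGB
    variances means dark background (deleted); near-black with a high variance
    sum is wound tissue and is kept.  Kept regions are merged into the
    foreground markers and the watershed runs a second time.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    pieces = _candidate_regions(mask, params)
    n_pieces = int(pieces.max())
    if n_pieces == 0:
        return mask
    rgb = np.asarray(image, dtype=np.float64)
    kept = np.zeros(mask.shape, dtype=bool)
    for i in range(1, n_pieces + 1):
        region = pieces == i
        values = rgb[region]
        if values.mean() >= params.black_mean_max:
            continue  # not close to black: environmental background
        var_sum = values.var(axis=0).sum()
        if var_sum < params.var_sum_min:
            continue  # flat dark region: background (shadow, dark object)
        kept |= region
    if not kept.any():
        return mask
    markers = build_markers(mask, crmap, params)
    labels = markers.labels.copy()
    interior = labels[1:-1, 1:-1]
    fg = _join_components((interior == FOREGROUND) | kept)
    # The first-pass background seeds are untrustworthy inside the anomaly
    # zone (the hull of the dilated skin): a dark wound reaching past the skin
    # hull would otherwise keep background seeds in its interior and the
    # second flood could not reclaim it.
    anomaly_zone = convex_hull_image(dilation(mask, _disk(params.d2)))
    interior[(interior == BACKGROUND) & anomaly_zone] = UNKNOWN
    interior[fg] = FOREGROUND  # joining lines override any background seed
    labels[1:-1, 1:-1] = interior
    second = watershed_segment(crmap, MarkerMap(labels=labels, frame_value=markers.frame_value))
    return second | mask | kept


# ---------------------------------------------------------------------------
# Full detector
# ---------------------------------------------------------------------------

def detect_skin(image: np.ndarray, params: SkinParams | None = None) -> tuple[np.ndarray, dict]:
    """Run the full skin-with-wound detector.

    Returns ``(mask, info)`` where ``mask`` is the binary skin-with-wound mask
    and ``info`` records the path taken (fast path or thresholds used).
    """
    if params is None:
        params = SkinParams.pre_profile()
    image = np.asarray(image)
    crmap = rgb_to_cr(image)
    hist = cr_histogram(crmap)
    p, window = predict_skin_proportion(hist, params)
    if p > params.epsilon:
        return np.ones(crmap.shape, dtype=bool), {
            "fast_path": True,
            "proportion": p,
            "window": window,
        }
    thresholds = dynamic_thresholds(hist, params)
    mask = threshold_mask(crmap, thresholds)
    markers = build_markers(mask, crmap, params)
    mask = watershed_segment(crmap, markers)
    mask = recover_dark_wounds(mask, image, crmap, params)
    return mask, {
        "fast_path": False,
        "proportion": p,
        "window": window,
        "thresholds": thresholds,
    }


def remove_background(image: np.ndarray, params: SkinParams | None = None) -> np.ndarray:
    """Zero every pixel outside the detected skin-with-wound region.

    Images taking the fast path are returned unchanged.
    """
    mask, info = detect_skin(image, params)
    if info["fast_path"]:
        return np.asarray(image).copy()
    out = np.asarray(image).copy()
    out[~mask] = 0
    return out
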