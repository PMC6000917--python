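"""Semantic post-correction of network wound masks.

Three rules, applied in order to the binarized network output:

1. *Hole filling* — wounds do not enclose islands of healthy skin, so every
   background component not connected to the image border becomes wound.
2. *Minor-noise removal* — a wound region is deleted when its area falls
   below ``eps_d = min(max(A) * P_d, A_d)``, with A the area set of all
   detected wounds: regions that are tiny relative to the largest wound, or
   tiny in absolute terms, are exposure/noise artifacts.
3. *Skin-overlap filtering* — wounds are subsets of skin; a region is kept
   only if the fraction of its area covered by the (background-hostile,
   d1=20/d2=10) skin detection exceeds ``eps_s``.

Foreground components are 8-connected; hole filling treats the background as
4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CorrectionParams",
    "RegionSet",
    "fill_holes",
    "remove_minor_wounds",
    "skin_overlap_filter",
    "correct",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CorrectionParams:
    """P_d: minimum area ratio to the largest wound; A_d: smallest reserved
    wound area in pixels; eps_s: minimum skin-overlap fraction."""

    p_d: float = 0.05
    a_d: float = 500.0
    eps_s: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.p_d < 1.0:
            raise ValueError("p_d must lie in (0, 1)")
        if self.a_d <= 0:
            raise ValueError("a_d must be positive")
        if not 0.0 < self.eps_s < 1.0:
            raise ValueError("eps_s must lie in (0, 1)")


@dataclass
class RegionSet:
    """Labeled connected wound regions of one mask."""

    labels: np.ndarray = field(repr=False)  # 0 background, 1..n regions
    ids: list[int] = field(default_factory=list)
    areas: dict[int, int] = field(default_factory=dict)
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RegionSet":
        mask = np.asarray(mask).astype(bool)
        labels, n = ndimage.label(mask, structure=_EIGHT)
        ids = list(range(1, n + 1))
        areas = {}
        centroids = {}
        if n:
            counts = ndimage.sum_labels(np.ones_like(labels), labels, index=ids)
            coms = ndimage.center_of_mass(mask, labels, index=ids)
            for i, a, com in zip(ids, counts, coms):
                areas[i] = int(a)
                centroids[i] = (float(com[0]), float(com[1]))
        return cls(labels=labels, ids=ids, areas=areas, centroids=centroids)

    def subset(self, keep: list[int]) -> "RegionSet":
        keep_set = set(keep)
        labels = np.where(np.isin(self.labels, list(keep_set)), self.labels, 0)
        return RegionSet(
            labels=labels,
            ids=[i for i in self.ids if i in keep_set],
            areas={i: self.areas[i] for i in keep_set},
            centroids={i: self.centroids[i] for i in keep_set},
        )

    def to_mask(self) -> np.ndarray:
        return self.labels > 0

    def __len__(self) -> int:
        return len(self.ids)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill every background component not connected to the border."""
    return ndimage.binary_fill_holes(np.asarray(mask).astype(bool))


def remove_minor_wounds(regions: RegionSet, params: CorrectionParams | None = None) -> RegionSet:
    """Delete regions with area strictly below min(max(A) * P_d, A_d)."""
    if params is None:
        params = CorrectionParams()
    if not regions.ids:
        return regions
    eps_d = min(max(regions.areas.values()) * params.p_d, params.a_d)
    keep = [i for i in regions.ids if regions.areas[i] >= eps_d]
    return regions.subset(keep)


def skin_overlap_filter(
    wounds: RegionSet,
    skin: np.ndarray,
    params: CorrectionParams | None = None,
) -> RegionSet:
    """Keep a wound region iff area(skin ∩ wound) / area(wound) > eps_s."""
    if params is None:
        params = CorrectionParams()
    skin = np.asarray(skin).astype(bool)
    if skin.shape != wounds.labels.shape:
        raise ValueError("skin mask shape does not match the wound regions")
    keep = []
    for i in wounds.ids:
        area = wounds.areas[i]
        if area == 0:
            raise ValueError(f"region {i} has zero area")
        overlap = int(np.count_nonzero(skin & (wounds.labels == i)))
        if overlap / area > params.eps_s:
            keep.append(i)
    return wounds.subset(keep)


def correct(
    prob: np.ndarray,
    skin: np.ndarray,
    params: CorrectionParams | None = None,
    threshold: float = 0.5,
) -> np.ndarray:
    """Full correction pipeline on a network probability mask.

    binarize -> fill holes -> label components -> minor-noise removal ->
    skin-overlap filtering -> rasterize the survivors.  ``skin`` is the
    binary mask from the background-hostile skin detection profile.
    """
    if params is None:
        params = CorrectionParams()
    binary = np.asarray(prob) >= threshold
    filled = fill_holes(binary)
    regions = RegionSet.from_mask(filled)
    regions = remove_minor_wounds(regions, params)
    regions = skin_overlap_filter(regions, skin, params)
    return regions.to_mask()
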