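"""Training-data preprocessing: standardization, deformation + cropping
augmentation, and the six train/test group compositions.

One raw photograph expands to 60 training samples: 6 geometric deformations
(identity, horizontal flip, +-10 degree rotation, and two anisotropic
rescalings) times 10 random 512x512 crops.  Image and mask always receive the
identical geometric transform; masks are interpolated nearest-neighbor so
labels stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import transform

__all__ = ["AugmentConfig", "DatasetGroup", "standardize", "augment", "build_group"]


@dataclass(frozen=True)
class AugmentConfig:
    crop_size: int = 512
    n_deformations: int = 6
    n_crops_per_deformation: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size <= 0:
            raise ValueError("crop_size must be positive")
        if self.n_deformations < 1 or self.n_deformations > 6:
            raise ValueError("between 1 and 6 deformations are available")
        if self.n_crops_per_deformation <= 0:
            raise ValueError("n_crops_per_deformation must be positive")


def standardize(image: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance standardization over all values jointly,
    ``X_N = (X - mu_X) / sigma_X``.

    Raises on a constant image (undefined scale).
    """
    x = np.asarray(image, dtype=np.float64)
    sigma = x.std()
    if sigma == 0.0:
        raise ValueError("constant image cannot be standardized (sigma = 0)")
    return (x - x.mean()) / sigma


def _deformations(image: np.ndarray, mask: np.ndarray, n: int):
    """The fixed deformation set, applied identically to image and mask."""

    def rot(img, angle, order):
        return transform.rotate(
            img, angle, resize=False, order=order, mode="constant",
            cval=0, preserve_range=True,
        )

    def rescale(img, fy, fx, order):
        out_shape = (round(img.shape[0] * fy), round(img.shape[1] * fx))
        if img.ndim == 3:
            out_shape = out_shape + (img.shape[2],)
        return transform.resize(
            img, out_shape, order=order, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )

    pairs = [
        (image, mask),
        (image[:, ::-1], mask[:, ::-1]),
        (rot(image, 10, 1), rot(mask.astype(float), 10, 0)),
        (rot(image, -10, 1), rot(mask.astype(float), -10, 0)),
        (rescale(image, 0.9, 1.1, 1), rescale(mask.astype(float), 0.9, 1.1, 0)),
        (rescale(image, 1.1, 0.9, 1), rescale(mask.astype(float), 1.1, 0.9, 0)),
    ]
    for img, msk in pairs[:n]:
        yield np.clip(np.asarray(img, dtype=np.float64), 0, 255), np.asarray(msk) > 0.5


def _pad_to(img: np.ndarray, size: int) -> np.ndarray:
    pad_h = max(0, size - img.shape[0])
    pad_w = max(0, size - img.shape[1])
    if pad_h == 0 and pad_w == 0:
        return img
    widths = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (img.ndim - 2)
    return np.pad(img, widths, mode="reflect")


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentConfig | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expand one (image, mask) pair into deformed and cropped training pairs.

    Returns ``n_deformations * n_crops_per_deformation`` pairs (60 by
    default), each a (crop_size, crop_size) uint8 image with its boolean
    mask.  Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = AugmentConfig()
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if min(image.shape[:2]) < config.crop_size:
        raise ValueError(
            f"image sides must be at least crop_size={config.crop_size}, "
            f"got {image.shape[:2]}"
        )
    rng = np.random.default_rng(config.seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for img, msk in _deformations(image, mask, config.n_deformations):
        img = _pad_to(img, config.crop_size)
        msk = _pad_to(msk, config.crop_size)
        max_y = img.shape[0] - config.crop_size
        max_x = img.shape[1] - config.crop_size
        for _ in range(config.n_crops_per_deformation):
            y = int(rng.integers(0, max_y + 1))
            x = int(rng.integers(0, max_x + 1))
            crop = img[y : y + config.crop_size, x : x + config.crop_size]
            mcrop = msk[y : y + config.crop_size, x : x + config.crop_size]
            out.append((np.floor(crop + 0.5).astype(np.uint8), mcrop.copy()))
    return out


@dataclass
class DatasetGroup:
    """One train/test composition over raw and background-removed twins.

    The hold-out split is at the *source* level: a raw image and its
    preprocessed twin never straddle the train/test boundary.
    """

    group_id: int
    train: list = field(repr=False)
    test: list = field(repr=False)
    train_sources: list[int] = field(default_factory=list, repr=False)
    test_sources: list[int] = field(default_factory=list, repr=False)


# train recipe, test recipe per group: "raw", "pre" or "both"
_GROUP_RECIPES = {
    1: ("raw", "raw"),
    2: ("raw", "pre"),
    3: ("both", "raw"),
    4: ("both", "pre"),
    5: ("pre", "pre"),
    6: ("both", "both"),
}


def build_group(
    raw: Sequence,
    preprocessed: Sequence,
    group_id: int,
    seed: int = 0,
    test_fraction: float = 190 / 950,
) -> DatasetGroup:
    """Assemble one of the six train/test group compositions.

    ``raw`` and ``preprocessed`` are parallel sequences of the same underlying
    sources.  Sources are split hold-out style (by default 20%, matching a
    760/190 split of 950 sources) with a seeded permutation, then each side is
    materialized from raw images, their preprocessed twins, or both.
    """
    if group_id not in _GROUP_RECIPES:
        raise ValueError(f"unknown group_id {group_id!r}; expected 1..6")
    if len(raw) != len(preprocessed):
        raise ValueError("raw and preprocessed must index the same sources")
    n = len(raw)
    if n < 2:
        raise ValueError("need at least two sources to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, round(n * test_fraction))
    test_idx = sorted(int(i) for i in order[:n_test])
    train_idx = sorted(int(i) for i in order[n_test:])

    def materialize(recipe: str, idx: list[int]) -> list:
        items = []
        if recipe in ("raw", "both"):
            items.extend(raw[i] for i in idx)
        if recipe in ("pre", "both"):
            items.extend(preprocessed[i] for i in idx)
        return items

    train_recipe, test_recipe = _GROUP_RECIPES[group_id]
    return DatasetGroup(
        group_id=group_id,
        train=materialize(train_recipe, train_idx),
        test=materialize(test_recipe, test_idx),
        train_sources=train_idx,
        test_sources=test_idx,
    )
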