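"""End-to-end composite segmentation workflow.

preprocess (wound-preserving background removal) -> network segmentation ->
semantic correction against the background-hostile skin detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .segnet import MobileFCN, segment
from .semantic_correction import CorrectionParams, correct
from .skin_detection import SkinParams, detect_skin

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("woundseg")


@dataclass(frozen=True)
class PipelineConfig:
    skin_pre: SkinParams = field(default_factory=SkinParams.pre_profile)
    skin_post: SkinParams = field(default_factory=SkinParams.post_profile)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(
    image: np.ndarray,
    model: MobileFCN,
    config: PipelineConfig | None = None,
    return_stages: bool = False,
):
    """Segment the wound in one RGB image with the full composite model.

    Returns the final binary wound mask (and, when ``return_stages`` is set, a
    dict with each stage's intermediate output and statistics).
    """
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image)

    pre_mask, pre_info = _stage("background-removal")(detect_skin, image, config.skin_pre)
    if pre_info["fast_path"]:
        preprocessed = image
        logger.info("preprocess: fast path (p=%.3f), background removal skipped",
                    pre_info["proportion"])
    else:
        preprocessed = image.copy()
        preprocessed[~pre_mask] = 0
        logger.info("preprocess: retained %.1f%% of pixels as skin-with-wound",
                    100.0 * pre_mask.mean())

    prob = _stage("network-segmentation")(segment, model, preprocessed)
    logger.info("network: %.1f%% of pixels above 0.5", 100.0 * (prob >= 0.5).mean())

    post_mask, post_info = _stage("post-skin-detection")(detect_skin, image, config.skin_post)
    final = _stage("semantic-correction")(correct, prob, post_mask, config.correction)
    logger.info("correction: final wound covers %.1f%% of pixels", 100.0 * final.mean())

    if return_stages:
        return final, {
            "pre_mask": pre_mask,
            "pre_info": pre_info,
            "preprocessed": preprocessed,
            "prob": prob,
            "post_mask": post_mask,
            "post_info": post_info,
        }
    return final
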