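"""YAML configuration mirroring every tunable constant of the pipeline."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .pipeline import PipelineConfig
from .semantic_correction import CorrectionParams
from .skin_detection import SkinParams

__all__ = ["default_config_dict", "load_pipeline_config", "dump_config"]


def default_config_dict() -> dict:
    cfg = PipelineConfig()
    return {
        "skin_pre": asdict(cfg.skin_pre),
        "skin_post": asdict(cfg.skin_post),
        "correction": asdict(cfg.correction),
        "seed": cfg.seed,
    }


def _tuplify(d: dict) -> dict:
    out = dict(d)
    for key in ("a_interval", "b_interval"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def load_pipeline_config(path: str | None = None) -> PipelineConfig:
    """Load a pipeline configuration from YAML; missing keys keep defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    defaults = default_config_dict()
    merged = {
        section: {**defaults[section], **_tuplify(data.get(section, {}))}
        for section in ("skin_pre", "skin_post", "correction")
    }
    return PipelineConfig(
        skin_pre=SkinParams(**merged["skin_pre"]),
        skin_post=SkinParams(**merged["skin_post"]),
        correction=CorrectionParams(**merged["correction"]),
        seed=int(data.get("seed", defaults["seed"])),
    )


def dump_config(path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(default_config_dict(), fh, sort_keys=False)
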