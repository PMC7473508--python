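"""Flat run configuration: every tunable of the pipeline in one place.

Configuration files are plain YAML ``key: value`` mappings; unknown keys
are rejected so typos fail loudly.  Command-line flags override file
values.  Defaults mirror the reference analysis protocol: 240x240 grid,
256 gray levels, distance-1 symmetric GLCM in four directions, two-level
haar/sym4/bior3.3 wavelets, 4-bin equal-frequency discretization, top-5
selection, stratified 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .features import ExtractionConfig
from .phantom import PhantomSpec


@dataclass
class RunConfig:
    # phantom generation
    n_inflammatory: int = 30
    n_tumor: int = 37
    separation: float = 1.0
    noise_sd: float = 3.0
    noise_model: str = "gaussian"
    rois_min: int = 1
    rois_max: int = 5
    # feature extraction
    levels: int = 256
    glcm_distance: int = 1
    glcm_symmetric: bool = True
    wentropy_style: str = "normalized"
    rescale_mode: str = "minmax"
    target_size: int = 240
    # ranking
    bins: int = 4
    k_select: int = 5
    rank_combine: str = "mean"
    # evaluation
    n_folds: int = 10
    cv_protocol: str = "kfold"      # or "holdout" (75/25 split)
    leaky_top5: bool = False
    # randomness
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a key: value mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            separation=self.separation, noise_sd=self.noise_sd,
            noise_model=self.noise_model,
            n_per_class=(self.n_inflammatory, self.n_tumor),
            rois_per_lesion_range=(self.rois_min, self.rois_max),
            seed=self.seed)

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            levels=self.levels, glcm_distance=self.glcm_distance,
            glcm_symmetric=self.glcm_symmetric,
            wentropy_style=self.wentropy_style,
            rescale_mode=self.rescale_mode,
            target_size=(self.target_size, self.target_size))
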