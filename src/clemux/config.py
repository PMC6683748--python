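"""Pipeline configuration: one validated object covering every stage.

Configs load from YAML; command-line flags override file values.  Every run
logs the fully resolved config and stores it in the run manifest, so any
result can be traced to the exact parameter set that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationParams
from .synthetic import (
    DEFAULT_CHANNELS,
    BarcodePattern,
    ChannelPanel,
    NoiseConfig,
    RenderConfig,
    enumerate_patterns,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class ClusteringConfig:
    k: int | None = None  # None: number of patterns in use
    restarts: int = 50
    low_confidence_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0 < self.low_confidence_quantile <= 1:
            raise ValueError("low_confidence_quantile must be in (0, 1]")


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run.

    ``patterns`` is a list of bit strings over the channel panel; None means
    every nonzero combination.  ``seed`` feeds both the synthetic generator
    and k-means initialization.
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS[:3]
    patterns: list[str] | None = None
    n_cells_per_pattern: int = 4
    seed: int = 0
    dilation_um: float = 0.2
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    segmentation: SegmentationParams | None = None
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    stereology_factor: bool = True
    nav_y_inverted: bool = True

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        ChannelPanel(self.channels)  # validate
        if self.patterns is not None:
            valid = {str(p) for p in enumerate_patterns(self.panel)}
            bad = [p for p in self.patterns if p not in valid]
            if bad:
                raise ValueError(f"patterns not valid over the panel: {bad}")
        if self.n_cells_per_pattern < 1:
            raise ValueError("n_cells_per_pattern must be >= 1")
        if self.dilation_um < 0:
            raise ValueError("dilation_um must be >= 0")
        if self.segmentation is None:
            # synthetic EM pixel size follows from the LM pixel size and scale
            self.segmentation = SegmentationParams(
                pixel_size_nm=self.render.lm_pixel_size_nm / self.render.em_scale
            )

    @property
    def panel(self) -> ChannelPanel:
        return ChannelPanel(self.channels)

    @property
    def patterns_in_use(self) -> list[BarcodePattern]:
        if self.patterns is None:
            return enumerate_patterns(self.panel)
        return [BarcodePattern.from_string(p) for p in self.patterns]

    @property
    def k(self) -> int:
        return self.clustering.k or len(self.patterns_in_use)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d


_SECTION_TYPES = {
    "noise": NoiseConfig,
    "render": RenderConfig,
    "segmentation": SegmentationParams,
    "clustering": ClusteringConfig,
}


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus overrides.

    Override keys matching top-level fields replace file values; nested
    sections (noise, render, segmentation, clustering) are merged field-wise.
    Unknown keys raise.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data.update(raw)
    for key, val in overrides.items():
        if val is None:
            continue
        data[key] = val

    kwargs: dict = {}
    for key, val in data.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(val) - valid
            if bad:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(bad)}")
            # tuples arrive from YAML as lists
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
            }
            kwargs[key] = cls(**coerced)
        else:
            valid = {f.name for f in dataclasses.fields(PipelineConfig)}
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = val
    cfg = PipelineConfig(**kwargs)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg
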