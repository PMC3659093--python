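"""Toolkit configuration.

A single :class:`Config` object carries the knobs shared across the
pipeline: export scaling and JPEG quality, Deep Zoom tile parameters,
heatmap colour overrides, the store root and the random seed. It loads
from a YAML file and individual fields can be overridden by CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from tmakit.heatmap import DEFAULT_COLOUR_MAP, HeatmapSpec

__all__ = ["Config", "load_config"]


@dataclass(frozen=True)
class Config:
    export_scale: float = 0.70
    jpeg_quality: int = 85
    tile_size: int = 254
    overlap: int = 1
    cell_px: int = 24
    colour_map: dict = field(default_factory=lambda: dict(DEFAULT_COLOUR_MAP))
    store_root: str = "store"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.export_scale <= 1):
            raise ValueError("export_scale must be in (0, 1]")
        if not (1 <= self.jpeg_quality <= 100):
            raise ValueError("jpeg_quality must be 1-100")
        if self.tile_size < 1 or self.overlap < 0:
            raise ValueError("tile_size must be >= 1 and overlap >= 0")
        if self.cell_px < 4:
            raise ValueError("cell_px must be >= 4")

    def heatmap_spec(self) -> HeatmapSpec:
        return HeatmapSpec(colour_map=dict(self.colour_map), cell_px=self.cell_px)


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a config file (YAML) and apply keyword overrides.

    Colour-map keys in the file may be strings (YAML mapping keys); they
    are coerced to int score values and colour lists to tuples.
    """
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if "colour_map" in data:
        data["colour_map"] = {
            int(k): tuple(v) for k, v in data["colour_map"].items()
        }
    data.update({k: v for k, v in overrides.items() if v is not None})
    return Config(**data)
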