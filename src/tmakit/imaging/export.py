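"""Scanner-style core-image export and filename conventions.

Exported cores follow the naming pattern ``{slide_id}_{x}_{y}_{version}.JPEG``
so that a directory of JPEGs is self-describing: the grid position and
export version of every core can be recovered from its filename alone.
Parsing is right-anchored — the last three underscore-separated tokens are
version, y and x — so slide identifiers may themselves contain underscores.

By default exports are scaled to 70% of the source resolution (linear
scaling of each axis), a resolution found adequate for manual scoring while
substantially reducing transfer size.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from PIL import Image

from tmakit.imaging.synthetic import CoreImage

__all__ = [
    "CoreFilenameError",
    "core_filename",
    "export_core_image",
    "parse_core_filename",
    "scaled_dimensions",
]

DEFAULT_EXPORT_SCALE = 0.70
DEFAULT_JPEG_QUALITY = 85

_EXTENSIONS = (".JPEG", ".jpeg", ".jpg", ".JPG")


class CoreFilenameError(ValueError):
    """Filename does not follow the slideID_x_y_version convention."""


def core_filename(slide_id: str, x: int, y: int, version: int = 1) -> str:
    if not slide_id:
        raise CoreFilenameError("slide_id must be non-empty")
    return f"{slide_id}_{x}_{y}_{version}.JPEG"


def parse_core_filename(name: str) -> tuple[str, int, int, int]:
    """Recover (slide_id, x, y, version) from an exported core filename.

    The trailing three numeric tokens are read right-to-left as version,
    y, x; everything to their left is the slide identifier.
    """
    stem = None
    for ext in _EXTENSIONS:
        if name.endswith(ext):
            stem = name[: -len(ext)]
            break
    if stem is None:
        raise CoreFilenameError(f"{name!r}: not a .JPEG/.jpeg/.jpg filename")
    parts = stem.split("_")
    if len(parts) < 4:
        raise CoreFilenameError(
            f"{name!r}: expected slideID_x_y_version, found too few tokens"
        )
    sx, sy, sver = parts[-3], parts[-2], parts[-1]
    if not (sx.isdigit() and sy.isdigit() and sver.isdigit()):
        raise CoreFilenameError(
            f"{name!r}: trailing tokens {sx!r}/{sy!r}/{sver!r} must be numeric"
        )
    slide_id = "_".join(parts[:-3])
    if not slide_id:
        raise CoreFilenameError(f"{name!r}: empty slide identifier")
    return slide_id, int(sx), int(sy), int(sver)


def scaled_dimensions(width: int, height: int, scale: float) -> tuple[int, int]:
    """Per-axis linear scaling, round-half-up, floor of 1 pixel."""
    w = max(1, int(math.floor(scale * width + 0.5)))
    h = max(1, int(math.floor(scale * height + 0.5)))
    return w, h


def export_core_image(
    image: CoreImage,
    out_dir: str | Path,
    scale: float = DEFAULT_EXPORT_SCALE,
    quality: int = DEFAULT_JPEG_QUALITY,
) -> Path:
    """Write one core image as a JPEG under the export naming convention.

    Returns the output path. The image is resized to ``scale`` times its
    source dimensions on each axis (bicubic); JPEG ``quality`` is an
    independent knob.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = core_filename(image.slide_id, image.x, image.y, image.version)
    w, h = scaled_dimensions(image.width, image.height, scale)
    pil = Image.fromarray(image.pixels, mode="RGB")
    if (w, h) != (image.width, image.height):
        pil = pil.resize((w, h), Image.Resampling.BICUBIC)
    path = out_dir / name
    pil.save(path, format="JPEG", quality=quality)
    return path


def load_core_image(path: str | Path) -> CoreImage:
    """Read an exported JPEG back into a :class:`CoreImage` (name gives identity)."""
    path = Path(path)
    slide_id, x, y, version = parse_core_filename(path.name)
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return CoreImage(pixels=pixels, slide_id=slide_id, x=x, y=y, version=version)
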