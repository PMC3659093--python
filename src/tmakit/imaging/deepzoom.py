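"""Deep Zoom (DZI) pyramid construction.

A Deep Zoom image is a multi-resolution pyramid: level ``max_level`` holds
the source image, and each lower level halves the previous one (ceiling
dimensions) down to level 0, a single pixel. Each level is cut into
``tile_size`` × ``tile_size`` tiles that extend ``overlap`` pixels past
their nominal edges where a neighbouring tile exists, stored as
``{name}_files/{level}/{col}_{row}.{ext}`` next to a small XML descriptor.
Viewers stream only the tiles covering the current viewport, so arbitrarily
large core scans zoom and pan smoothly.

Downsampling between levels is a 2×2 box mean; at odd edges the mean runs
over the available pixels only, so a flat image stays exactly flat through
every level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from lxml import etree
from PIL import Image

from tmakit.imaging.export import parse_core_filename, CoreFilenameError
from tmakit.imaging.synthetic import CoreImage

logger = logging.getLogger(__name__)

__all__ = [
    "PyramidDescriptor",
    "DeepZoomPyramid",
    "num_pyramid_levels",
    "level_dimensions",
    "downsample_half",
    "build_pyramid",
    "batch_convert",
    "parse_descriptor_xml",
]

DZI_NS = "http://schemas.microsoft.com/deepzoom/2008"
DEFAULT_TILE_SIZE = 254
DEFAULT_OVERLAP = 1


def num_pyramid_levels(width: int, height: int) -> int:
    """Number of pyramid levels, from 1×1 (level 0) up to full size.

    Equals ``ceil(log2(max(width, height))) + 1``.
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    return max(width, height).bit_length() - (
        1 if max(width, height) & (max(width, height) - 1) == 0 else 0
    ) + 1


def _max_level(width: int, height: int) -> int:
    return num_pyramid_levels(width, height) - 1


def level_dimensions(width: int, height: int, level: int) -> tuple[int, int]:
    """Dimensions of a pyramid level: repeated ceiling-halving from full size."""
    top = _max_level(width, height)
    if not (0 <= level <= top):
        raise ValueError(f"level {level} outside 0..{top}")
    w, h = width, height
    for _ in range(top - level):
        w = (w + 1) // 2
        h = (h + 1) // 2
    return w, h


def downsample_half(pixels: np.ndarray) -> np.ndarray:
    """2×2 box-mean downsample with ceiling dimensions.

    Odd trailing rows/columns average only the pixels present (implemented
    by edge replication, which is arithmetically identical). Means are
    rounded half-up to uint8.
    """
    h, w = pixels.shape[:2]
    if h == 1 and w == 1:
        return pixels.copy()
    ph, pw = h % 2, w % 2
    if ph or pw:
        pixels = np.pad(pixels, ((0, ph), (0, pw), (0, 0)), mode="edge")
    f = pixels.astype(np.float64)
    out = (f[0::2, 0::2] + f[1::2, 0::2] + f[0::2, 1::2] + f[1::2, 1::2]) / 4.0
    return np.floor(out + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class PyramidDescriptor:
    """DZI descriptor metadata for one pyramid."""

    width: int
    height: int
    tile_size: int = DEFAULT_TILE_SIZE
    overlap: int = DEFAULT_OVERLAP
    format: str = "jpeg"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")

    @property
    def max_level(self) -> int:
        return _max_level(self.width, self.height)

    @property
    def num_levels(self) -> int:
        return self.max_level + 1

    def level_dimensions(self, level: int) -> tuple[int, int]:
        return level_dimensions(self.width, self.height, level)

    def tile_grid(self, level: int) -> tuple[int, int]:
        """(n_cols, n_rows) of tiles at a level."""
        w, h = self.level_dimensions(level)
        return math.ceil(w / self.tile_size), math.ceil(h / self.tile_size)

    def to_xml(self) -> bytes:
        root = etree.Element(f"{{{DZI_NS}}}Image", nsmap={None: DZI_NS})
        root.set("TileSize", str(self.tile_size))
        root.set("Overlap", str(self.overlap))
        root.set("Format", self.format)
        size = etree.SubElement(root, f"{{{DZI_NS}}}Size")
        size.set("Width", str(self.width))
        size.set("Height", str(self.height))
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def parse_descriptor_xml(xml: bytes | str) -> PyramidDescriptor:
    root = etree.fromstring(xml if isinstance(xml, bytes) else xml.encode())
    if etree.QName(root).localname != "Image":
        raise ValueError(f"expected DZI Image element, got {root.tag}")
    size = root.find(f"{{{DZI_NS}}}Size")
    if size is None:  # tolerate un-namespaced documents
        size = root.find("Size")
    if size is None:
        raise ValueError("DZI descriptor missing Size element")
    return PyramidDescriptor(
        width=int(size.get("Width")),
        height=int(size.get("Height")),
        tile_size=int(root.get("TileSize")),
        overlap=int(root.get("Overlap", "0")),
        format=root.get("Format", "jpeg"),
    )


class DeepZoomPyramid:
    """An in-memory Deep Zoom pyramid for one image.

    Level images are materialised once at construction (the halving chain
    must run sequentially anyway); tiles are cut on demand.
    """

    def __init__(
        self,
        pixels: np.ndarray,
        tile_size: int = DEFAULT_TILE_SIZE,
        overlap: int = DEFAULT_OVERLAP,
        format: str = "jpeg",
    ) -> None:
        pixels = np.asarray(pixels, dtype=np.uint8)
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        h, w = pixels.shape[:2]
        self.descriptor = PyramidDescriptor(
            width=w, height=h, tile_size=tile_size, overlap=overlap, format=format
        )
        levels = [pixels]
        while levels[-1].shape[0] > 1 or levels[-1].shape[1] > 1:
            levels.append(downsample_half(levels[-1]))
        levels.reverse()  # index by level: 0 is 1x1
        self._levels = levels

    def level_image(self, level: int) -> np.ndarray:
        w, h = self.descriptor.level_dimensions(level)
        img = self._levels[level]
        assert img.shape[:2] == (h, w)
        return img

    def tile(self, level: int, col: int, row: int) -> np.ndarray:
        """One tile, including overlap margins where neighbours exist."""
        d = self.descriptor
        n_cols, n_rows = d.tile_grid(level)
        if not (0 <= col < n_cols and 0 <= row < n_rows):
            raise ValueError(f"tile ({col}, {row}) outside {n_cols}x{n_rows} grid")
        img = self.level_image(level)
        h, w = img.shape[:2]
        x0 = col * d.tile_size - (d.overlap if col > 0 else 0)
        y0 = row * d.tile_size - (d.overlap if row > 0 else 0)
        x1 = min((col + 1) * d.tile_size + d.overlap, w)
        y1 = min((row + 1) * d.tile_size + d.overlap, h)
        return img[y0:y1, x0:x1]

    def tiles(self, level: int) -> Iterator[tuple[int, int, np.ndarray]]:
        n_cols, n_rows = self.descriptor.tile_grid(level)
        for row in range(n_rows):
            for col in range(n_cols):
                yield col, row, self.tile(level, col, row)

    def write(
        self,
        out_dir: str | Path,
        name: str,
        quality: int = 85,
    ) -> Path:
        """Write ``{name}.dzi`` plus the ``{name}_files`` tile tree.

        Returns the descriptor path. Tile codec follows the descriptor's
        ``format`` ("jpeg" or "png").
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        d = self.descriptor
        ext = "png" if d.format.lower() == "png" else "jpeg"
        files = out_dir / f"{name}_files"
        for level in range(d.num_levels):
            level_dir = files / str(level)
            level_dir.mkdir(parents=True, exist_ok=True)
            for col, row, tile in self.tiles(level):
                im = Image.fromarray(tile, mode="RGB")
                path = level_dir / f"{col}_{row}.{ext}"
                if ext == "png":
                    im.save(path, format="PNG")
                else:
                    im.save(path, format="JPEG", quality=quality)
        dzi_path = out_dir / f"{name}.dzi"
        dzi_path.write_bytes(d.to_xml())
        return dzi_path


def build_pyramid(
    image: CoreImage | np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    format: str = "jpeg",
) -> DeepZoomPyramid:
    """Build the Deep Zoom pyramid of a core image (in memory)."""
    pixels = image.pixels if isinstance(image, CoreImage) else image
    return DeepZoomPyramid(pixels, tile_size=tile_size, overlap=overlap, format=format)


def batch_convert(
    in_dir: str | Path,
    out_dir: str | Path,
    tile_size: int = DEFAULT_TILE_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    format: str = "jpeg",
    quality: int = 85,
) -> list[dict]:
    """Convert every parseable core JPEG in ``in_dir`` into a Deep Zoom pyramid.

    Returns a manifest: one entry per converted image with the parsed
    (slide_id, x, y, version) identity, the source name and the descriptor
    path. Files whose names do not follow the export convention are
    skipped with a logged warning; an empty input directory yields an
    empty manifest and a warning.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    candidates = sorted(
        p for p in in_dir.iterdir()
        if p.suffix.lower() in (".jpeg", ".jpg", ".png")
    ) if in_dir.is_dir() else []
    if not candidates:
        logger.warning("batch_convert: no images found in %s", in_dir)
        return []
    manifest: list[dict] = []
    n_skipped = 0
    for path in candidates:
        try:
            slide_id, x, y, version = parse_core_filename(path.name)
        except CoreFilenameError as exc:
            logger.warning("batch_convert: skipping %s (%s)", path.name, exc)
            n_skipped += 1
            continue
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
        pyramid = DeepZoomPyramid(
            pixels, tile_size=tile_size, overlap=overlap, format=format
        )
        dzi = pyramid.write(out_dir, path.stem, quality=quality)
        manifest.append(
            {
                "slide_id": slide_id,
                "x": x,
                "y": y,
                "version": version,
                "source": path.name,
                "descriptor": str(dzi.relative_to(out_dir)),
            }
        )
    logger.info(
        "batch_convert: %d converted, %d skipped", len(manifest), n_skipped
    )
    return manifest
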