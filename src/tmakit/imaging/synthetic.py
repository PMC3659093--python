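"""Synthetic TMA core images.

Real input to the pipeline is scanner output: one JPEG per core, showing a
roughly circular disc of stained tissue on a slide background. The
generator here emulates that geometry for fixtures and simulations: a
centred tissue disc of controllable radius on a uniform grey background,
with a controllable fraction of the disc covered by stain "clusters" whose
colour darkens from the unstained tissue tone towards a DAB-brown with the
requested intensity grade (0–3, matching the 0–3 IHC intensity scale).

Everything is deterministic given the spec's seed, so simulated studies
and their Deep Zoom pyramids are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoreImage", "SyntheticCoreSpec", "generate_synthetic_core"]

# unstained counterstain tone (haematoxylin-ish pale mauve) and full-intensity
# DAB brown; stained pixels interpolate between them by intensity/3
_UNSTAINED_RGB = np.array([225, 210, 230], dtype=np.float64)
_DAB_RGB = np.array([101, 67, 33], dtype=np.float64)


@dataclass(frozen=True)
class CoreImage:
    """An 8-bit RGB core image plus its grid identity."""

    pixels: np.ndarray  # H x W x 3 uint8
    slide_id: str
    x: int
    y: int
    version: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be an H x W x 3 array with H, W >= 1")
        object.__setattr__(self, "pixels", px)
        if self.version < 1:
            raise ValueError("version must be >= 1")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class SyntheticCoreSpec:
    """Parameters of one synthetic core.

    size_px: side length of the square frame.
    disc_radius_fraction: disc radius as a fraction of size_px (0, 1].
    stain_intensity: IHC intensity grade 0-3; 0 leaves tissue unstained.
    stained_fraction: fraction of in-disc pixels covered by stain clusters.
    background_grey: grey level outside the disc.
    seed: RNG seed controlling cluster placement.
    """

    size_px: int = 256
    disc_radius_fraction: float = 0.45
    stain_intensity: int = 2
    stained_fraction: float = 0.5
    background_grey: int = 235
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 1:
            raise ValueError("size_px must be >= 1")
        if not (0 < self.disc_radius_fraction <= 1):
            raise ValueError("disc_radius_fraction must be in (0, 1]")
        if self.stain_intensity not in (0, 1, 2, 3):
            raise ValueError("stain_intensity must be an integer 0-3")
        if not (0 <= self.stained_fraction <= 1):
            raise ValueError("stained_fraction must be in [0, 1]")
        if not (0 <= self.background_grey <= 255):
            raise ValueError("background_grey must be 0-255")


def disc_mask(size_px: int, radius_fraction: float) -> np.ndarray:
    """Boolean mask of the centred tissue disc."""
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    r = radius_fraction * size_px
    return (xx - c) ** 2 + (yy - c) ** 2 <= r * r


def generate_synthetic_core(
    spec: SyntheticCoreSpec,
    slide_id: str = "SYN",
    x: int = 1,
    y: int = 1,
    version: int = 1,
) -> CoreImage:
    """Render one synthetic core image, deterministically for a given seed.

    Stain clusters are placed by thresholding a sum of Gaussian blobs at
    the quantile that covers ``stained_fraction`` of the disc, so the
    stained area tracks the requested fraction while staying spatially
    clumped like real DAB staining.
    """
    n = spec.size_px
    rng = np.random.default_rng(spec.seed)
    mask = disc_mask(n, spec.disc_radius_fraction)
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = spec.background_grey
    img[mask] = _UNSTAINED_RGB

    n_disc = int(mask.sum())
    if spec.stained_fraction > 0 and spec.stain_intensity > 0 and n_disc > 0:
        # clumped stain field: sum of random Gaussian blobs inside the disc
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        field = np.zeros((n, n))
        n_blobs = max(3, n // 24)
        radius = spec.disc_radius_fraction * n
        c = (n - 1) / 2.0
        for _ in range(n_blobs):
            ang = rng.uniform(0, 2 * np.pi)
            rad = radius * np.sqrt(rng.uniform())
            bx, by = c + rad * np.cos(ang), c + rad * np.sin(ang)
            sigma = rng.uniform(0.08, 0.25) * radius + 1e-9
            field += np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sigma**2))
        field += 1e-6 * rng.standard_normal((n, n))  # break threshold ties
        in_disc = field[mask]
        if spec.stained_fraction >= 1.0:
            stained = mask
        else:
            thr = np.quantile(in_disc, 1.0 - spec.stained_fraction)
            stained = mask & (field > thr)
        blend = spec.stain_intensity / 3.0
        stain_rgb = (1 - blend) * _UNSTAINED_RGB + blend * _DAB_RGB
        img[stained] = stain_rgb

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return CoreImage(pixels=pixels, slide_id=slide_id, x=x, y=y, version=version)
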