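"""Virtual-slide assembly: arrange core thumbnails on a grid.

The array view places each core thumbnail at its grid coordinate, producing
a single montage image of the whole slide. The same routine builds
"virtual TMA" views, where the entries come from different physical slides
(for example one donor block's cores across several biomarker stains).
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = ["assemble_virtual_slide"]


def assemble_virtual_slide(
    entries: list[tuple[int, int, np.ndarray]],
    cell_px: int,
    n_cols: int,
    n_rows: int,
    background: tuple[int, int, int] = (255, 255, 255),
) -> np.ndarray:
    """Build an (n_rows*cell_px) × (n_cols*cell_px) RGB montage.

    ``entries`` are (x, y, thumbnail) with 1-based grid coordinates;
    thumbnails are resized to ``cell_px`` squares. Cells without an entry
    are filled with ``background``. Duplicate coordinates are an error.
    """
    if cell_px < 1 or n_cols < 1 or n_rows < 1:
        raise ValueError("cell_px and grid dimensions must be >= 1")
    montage = np.empty((n_rows * cell_px, n_cols * cell_px, 3), dtype=np.uint8)
    montage[:] = np.asarray(background, dtype=np.uint8)
    seen: set[tuple[int, int]] = set()
    for x, y, thumb in entries:
        if not (1 <= x <= n_cols and 1 <= y <= n_rows):
            raise ValueError(f"entry ({x}, {y}) outside {n_cols}x{n_rows} grid")
        if (x, y) in seen:
            raise ValueError(f"duplicate entry at ({x}, {y})")
        seen.add((x, y))
        thumb = np.asarray(thumb, dtype=np.uint8)
        if thumb.ndim == 2:
            thumb = np.stack([thumb] * 3, axis=-1)
        if thumb.shape[:2] != (cell_px, cell_px):
            im = Image.fromarray(thumb, mode="RGB")
            thumb = np.asarray(
                im.resize((cell_px, cell_px), Image.Resampling.BILINEAR)
            )
        r0, c0 = (y - 1) * cell_px, (x - 1) * cell_px
        montage[r0 : r0 + cell_px, c0 : c0 + cell_px] = thumb
    return montage
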