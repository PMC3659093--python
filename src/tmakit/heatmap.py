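"""Slide heatmaps and scorer comparison.

The heatmap view renders one cell per grid position of a slide, coloured
by the latest recorded score for that core: the 0–3 intensity legend runs
pale yellow → intense yellow → pale blue → intense blue; orientation
marker cores are grey, no-tumour cores pink, unscored cores white; the
currently viewed position is outlined in black. For scoring systems with
other numeric ranges (the Allred total 0–8, percentage staining) cell
colours interpolate linearly between the pale-yellow and intense-blue
endpoints.

``compare_scorers`` builds the side-by-side discrepancy report used to
review inter-observer disagreement and spot slide defects such as uneven
staining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from tmakit.scoring import NO_TUMOUR, ScoreRecord
from tmakit.slidemap import SlideMap

__all__ = [
    "HeatmapSpec",
    "DiscrepancyReport",
    "score_to_colour",
    "render_heatmap",
    "heatmap_png",
    "heatmap_svg",
    "compare_scorers",
    "render_discrepancy_heatmap",
    "latest_scores",
]

RGB = tuple[int, int, int]

#: 0-3 intensity legend
DEFAULT_COLOUR_MAP: dict[int, RGB] = {
    0: (255, 255, 204),  # pale yellow
    1: (255, 215, 0),    # intense yellow
    2: (173, 216, 230),  # pale blue
    3: (0, 0, 205),      # intense blue
}


@dataclass(frozen=True)
class HeatmapSpec:
    """Colour and geometry configuration for heatmap rendering."""

    colour_map: Mapping[int, RGB] = field(
        default_factory=lambda: dict(DEFAULT_COLOUR_MAP)
    )
    marker_colour: RGB = (128, 128, 128)     # grey
    no_tumour_colour: RGB = (255, 192, 203)  # pink
    unscored_colour: RGB = (255, 255, 255)   # white
    current_outline_colour: RGB = (0, 0, 0)  # black
    cell_px: int = 24
    # linear-interpolation endpoints for systems outside the discrete map
    scale_low: RGB = (255, 255, 204)
    scale_high: RGB = (0, 0, 205)
    scale_max: float = 3.0

    def __post_init__(self) -> None:
        if self.cell_px < 4:
            raise ValueError("cell_px must be >= 4")
        for colour in (
            self.marker_colour, self.no_tumour_colour, self.unscored_colour,
            self.current_outline_colour, self.scale_low, self.scale_high,
            *self.colour_map.values(),
        ):
            if len(colour) != 3 or any(not (0 <= c <= 255) for c in colour):
                raise ValueError(f"invalid RGB colour {colour!r}")
        object.__setattr__(self, "colour_map", dict(self.colour_map))


def score_to_colour(value, spec: HeatmapSpec | None = None, status: str = "scored") -> RGB:
    """Map a score value or a cell status to its heatmap colour.

    ``status`` may be ``scored`` (value used), ``marker``, ``no_tumour``
    or ``unscored``. Numeric values outside the discrete colour map are
    interpolated between the scale endpoints; values outside [0,
    scale_max] are an error.
    """
    spec = spec or HeatmapSpec()
    if status == "marker":
        return spec.marker_colour
    if status == NO_TUMOUR:
        return spec.no_tumour_colour
    if status == "unscored":
        return spec.unscored_colour
    if status != "scored":
        raise ValueError(f"unknown cell status {status!r}")
    if isinstance(value, (int, np.integer)) and int(value) in spec.colour_map:
        return spec.colour_map[int(value)]
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unmappable score value {value!r}") from None
    if not (0 <= v <= spec.scale_max):
        raise ValueError(f"score value {v} outside 0..{spec.scale_max}")
    t = v / spec.scale_max if spec.scale_max else 0.0
    return tuple(
        int(round((1 - t) * lo + t * hi))
        for lo, hi in zip(spec.scale_low, spec.scale_high)
    )


def latest_scores(
    scores: Sequence[ScoreRecord],
) -> dict[tuple[int, int], ScoreRecord]:
    """Latest record_version per (x, y)."""
    latest: dict[tuple[int, int], ScoreRecord] = {}
    for rec in scores:
        key = (rec.x, rec.y)
        if key not in latest or rec.record_version > latest[key].record_version:
            latest[key] = rec
    return latest


def _cell_value(rec: ScoreRecord, value_field: str | None):
    if value_field is not None:
        return rec.values.get(value_field)
    if len(rec.values) == 1:
        return next(iter(rec.values.values()))
    return rec.values.get("total") or next(iter(rec.values.values()), None)


def render_heatmap(
    slidemap: SlideMap,
    scores: Sequence[ScoreRecord],
    spec: HeatmapSpec | None = None,
    current: tuple[int, int] | None = None,
    value_field: str | None = None,
) -> np.ndarray:
    """Render the slide heatmap as an RGB array.

    One ``cell_px`` square per grid position; each scored cell takes the
    colour of its core's latest record. ``value_field`` names the score
    field to colour by (defaults to the record's single field, or
    ``total``). ``current`` outlines one cell in the outline colour.
    """
    spec = spec or HeatmapSpec()
    blk = slidemap.recipient_block
    if current is not None:
        cx, cy = current
        if not (1 <= cx <= blk.n_cols and 1 <= cy <= blk.n_rows):
            raise ValueError(f"current position {current} outside grid")
    for rec in scores:
        if slidemap.core_at(rec.x, rec.y) is None:
            raise ValueError(f"score at ({rec.x}, {rec.y}) has no map position")
    latest = latest_scores(scores)
    cp = spec.cell_px
    img = np.empty((blk.n_rows * cp, blk.n_cols * cp, 3), dtype=np.uint8)
    img[:] = spec.unscored_colour
    for y in range(1, blk.n_rows + 1):
        for x in range(1, blk.n_cols + 1):
            pos = slidemap.core_at(x, y)
            if pos is not None and pos.kind == "marker":
                colour = spec.marker_colour
            elif (x, y) in latest:
                rec = latest[(x, y)]
                if rec.status == NO_TUMOUR:
                    colour = spec.no_tumour_colour
                else:
                    colour = score_to_colour(_cell_value(rec, value_field), spec)
            else:
                colour = spec.unscored_colour
            r0, c0 = (y - 1) * cp, (x - 1) * cp
            img[r0 : r0 + cp, c0 : c0 + cp] = colour
    if current is not None:
        cx, cy = current
        r0, c0 = (cy - 1) * cp, (cx - 1) * cp
        outline = np.asarray(spec.current_outline_colour, dtype=np.uint8)
        img[r0, c0 : c0 + cp] = outline
        img[r0 + cp - 1, c0 : c0 + cp] = outline
        img[r0 : r0 + cp, c0] = outline
        img[r0 : r0 + cp, c0 + cp - 1] = outline
    return img


def heatmap_png(
    slidemap: SlideMap,
    scores: Sequence[ScoreRecord],
    path: str | Path,
    spec: HeatmapSpec | None = None,
    current: tuple[int, int] | None = None,
    value_field: str | None = None,
) -> Path:
    img = render_heatmap(slidemap, scores, spec, current, value_field)
    Image.fromarray(img, mode="RGB").save(Path(path), format="PNG")
    return Path(path)


def heatmap_svg(
    slidemap: SlideMap,
    scores: Sequence[ScoreRecord],
    spec: HeatmapSpec | None = None,
    current: tuple[int, int] | None = None,
    value_field: str | None = None,
) -> str:
    """Vector rendering: one SVG rect per cell, same colouring as the raster."""
    spec = spec or HeatmapSpec()
    blk = slidemap.recipient_block
    latest = latest_scores(scores)
    cp = spec.cell_px
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{blk.n_cols * cp}" height="{blk.n_rows * cp}">',
    ]
    for y in range(1, blk.n_rows + 1):
        for x in range(1, blk.n_cols + 1):
            pos = slidemap.core_at(x, y)
            if pos is not None and pos.kind == "marker":
                colour = spec.marker_colour
            elif (x, y) in latest:
                rec = latest[(x, y)]
                colour = (
                    spec.no_tumour_colour
                    if rec.status == NO_TUMOUR
                    else score_to_colour(_cell_value(rec, value_field), spec)
                )
            else:
                colour = spec.unscored_colour
            parts.append(
                f'<rect x="{(x - 1) * cp}" y="{(y - 1) * cp}" '
                f'width="{cp}" height="{cp}" fill="rgb{tuple(colour)}"/>'
            )
    if current is not None:
        cx, cy = current
        parts.append(
            f'<rect x="{(cx - 1) * cp}" y="{(cy - 1) * cp}" width="{cp}" '
            f'height="{cp}" fill="none" '
            f'stroke="rgb{tuple(spec.current_outline_colour)}" stroke-width="2"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# Scorer comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscrepancyReport:
    """Cells where two scorers' latest values differ.

    ``cells`` lists (x, y, value_a, value_b) for every discrepant cell;
    ``n_compared`` counts the cells both scorers scored.
    """

    cells: tuple[tuple[int, int, object, object], ...]
    n_discrepant: int
    n_compared: int


def _comparable_value(rec: ScoreRecord, value_field: str | None):
    if rec.status == NO_TUMOUR:
        return NO_TUMOUR
    return _cell_value(rec, value_field)


def compare_scorers(
    slidemap: SlideMap,
    scores_a: Sequence[ScoreRecord],
    scores_b: Sequence[ScoreRecord],
    value_field: str | None = None,
) -> DiscrepancyReport:
    """Compare two scorers' latest scores on the same slide.

    A cell enters the comparison only when both scorers scored it;
    it is discrepant when their latest values differ (a no-tumour call
    counts as a value).
    """
    latest_a = latest_scores(scores_a)
    latest_b = latest_scores(scores_b)
    common = sorted(set(latest_a) & set(latest_b), key=lambda p: (p[1], p[0]))
    cells = []
    for (x, y) in common:
        va = _comparable_value(latest_a[(x, y)], value_field)
        vb = _comparable_value(latest_b[(x, y)], value_field)
        if va != vb:
            cells.append((x, y, va, vb))
    return DiscrepancyReport(
        cells=tuple(cells), n_discrepant=len(cells), n_compared=len(common)
    )


def render_discrepancy_heatmap(
    slidemap: SlideMap,
    report: DiscrepancyReport,
    spec: HeatmapSpec | None = None,
    discrepant_colour: RGB = (220, 20, 60),
) -> np.ndarray:
    """Third-heatmap view of a comparison: discrepant cells highlighted."""
    spec = spec or HeatmapSpec()
    blk = slidemap.recipient_block
    cp = spec.cell_px
    img = np.empty((blk.n_rows * cp, blk.n_cols * cp, 3), dtype=np.uint8)
    img[:] = spec.unscored_colour
    discrepant = {(x, y) for x, y, _, _ in report.cells}
    # only discrepant cells and marker cores are distinguishable from the
    # report alone; agreeing cells keep the unscored background
    for y in range(1, blk.n_rows + 1):
        for x in range(1, blk.n_cols + 1):
            pos = slidemap.core_at(x, y)
            r0, c0 = (y - 1) * cp, (x - 1) * cp
            if pos is not None and pos.kind == "marker":
                img[r0 : r0 + cp, c0 : c0 + cp] = spec.marker_colour
            elif (x, y) in discrepant:
                img[r0 : r0 + cp, c0 : c0 + cp] = discrepant_colour
    return img
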