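"""Recipient-block array layouts (slidemaps).

A slidemap records the geometry of a TMA recipient block and the grid of
core positions on one slide: which donor block each core was punched from,
which positions are gaps, and which hold orientation marker cores. It is
the linkage table that lets a score at grid position (x, y) be traced back
to the donor tissue block (and hence, outside this system, the patient).

Layout tables arrive as rectangular grids of cells (CSV, or one XLSX sheet
per block): each cell holds a donor-block identifier, the sentinel
``MARKER`` (case-insensitive) for an orientation core, or is empty for a
gap. ``parse_layout_table`` converts such a grid into a :class:`SlideMap`;
``write_slidemap_xml``/``parse_slidemap_xml`` serialise it to the project's
slidemap XML dialect, whose elements are annotated with the CDE names of
the metadata registry for interoperability.

Coordinates are 1-based: x is the column, y the row, origin at the top-left
corner with y increasing downward.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "CorePosition",
    "RecipientBlock",
    "SlideMap",
    "SlideMapError",
    "SlideMapParseError",
    "MARKER_SENTINEL",
    "parse_layout_table",
    "read_layout_csv",
    "read_layout_xlsx",
    "render_layout_table",
    "write_slidemap_xml",
    "parse_slidemap_xml",
    "donor_index",
]

MARKER_SENTINEL = "MARKER"


class SlideMapError(ValueError):
    """Layout or slidemap invariant violation."""


class SlideMapParseError(SlideMapError):
    """Malformed slidemap XML."""


@dataclass(frozen=True)
class CorePosition:
    """One grid position on a slide.

    ``kind`` is ``tissue`` (a scored core from a donor block), ``marker``
    (an orientation core) or ``empty`` (a gap where no core was inserted).
    """

    x: int
    y: int
    donor_block_id: str = ""
    used: bool = True
    kind: str = "tissue"

    def __post_init__(self) -> None:
        if self.kind not in ("tissue", "marker", "empty"):
            raise SlideMapError(f"unknown core kind {self.kind!r}")
        if self.x < 1 or self.y < 1:
            raise SlideMapError(f"coordinates are 1-based, got ({self.x}, {self.y})")
        if (self.kind == "empty") != (not self.used):
            raise SlideMapError(
                f"position ({self.x}, {self.y}): used flag must be false "
                "exactly for empty positions"
            )
        if self.kind == "tissue" and not self.donor_block_id:
            raise SlideMapError(
                f"tissue core at ({self.x}, {self.y}) needs a donor block id"
            )


@dataclass(frozen=True)
class RecipientBlock:
    """Physical recipient-block metadata."""

    block_id: str
    n_cols: int
    n_rows: int
    core_diameter: float = 0.6  # mm; typical TMA punch
    core_spacing: float = 1.0  # mm centre-to-centre
    slice_number: int = 1

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise SlideMapError("grid dimensions must be >= 1")
        if self.core_diameter <= 0 or self.core_spacing <= 0:
            raise SlideMapError("core diameter and spacing must be positive")
        if self.slice_number < 1:
            raise SlideMapError("slice number must be >= 1")


@dataclass(frozen=True)
class SlideMap:
    """A slide's array layout: recipient-block geometry plus core positions."""

    slide_id: str
    recipient_block: RecipientBlock
    positions: tuple[CorePosition, ...]
    marker_name: str = ""

    def __post_init__(self) -> None:
        if not self.slide_id:
            raise SlideMapError("slide_id must be non-empty")
        # canonical row-major order so structural equality is order-free
        object.__setattr__(
            self,
            "positions",
            tuple(sorted(self.positions, key=lambda p: (p.y, p.x))),
        )
        seen = set()
        blk = self.recipient_block
        for p in self.positions:
            if (p.x, p.y) in seen:
                raise SlideMapError(f"duplicate core position ({p.x}, {p.y})")
            seen.add((p.x, p.y))
            if p.x > blk.n_cols or p.y > blk.n_rows:
                raise SlideMapError(
                    f"position ({p.x}, {p.y}) outside {blk.n_cols}x{blk.n_rows} grid"
                )

    # -- queries -----------------------------------------------------------

    def core_at(self, x: int, y: int) -> CorePosition | None:
        """The position record at (x, y), or None when the map has no entry.

        Coordinates outside the grid raise; coordinates are 1-based.
        """
        blk = self.recipient_block
        if not (1 <= x <= blk.n_cols and 1 <= y <= blk.n_rows):
            raise SlideMapError(
                f"coordinates ({x}, {y}) outside 1..{blk.n_cols} x 1..{blk.n_rows}"
            )
        for p in self.positions:
            if p.x == x and p.y == y:
                return p
        return None

    @property
    def tissue_positions(self) -> tuple[CorePosition, ...]:
        return tuple(p for p in self.positions if p.kind == "tissue")

    @property
    def used_count(self) -> int:
        return sum(1 for p in self.positions if p.used)


# ---------------------------------------------------------------------------
# Layout tables
# ---------------------------------------------------------------------------

def parse_layout_table(
    rows: Sequence[Sequence[str]],
    block: RecipientBlock,
    slide_id: str,
    marker_name: str = "",
) -> SlideMap:
    """Convert a rectangular grid of layout cells into a :class:`SlideMap`.

    Cell (row r, column c) maps to position (x=c, y=r), both 1-based.
    Empty cells become gaps, the ``MARKER`` sentinel becomes an orientation
    core, anything else is a donor-block identifier. Duplicate donor ids
    across cells are allowed — donor blocks contribute replicate cores.
    """
    if not rows:
        raise SlideMapError("layout table is empty")
    width = len(rows[0])
    for r, row in enumerate(rows, start=1):
        if len(row) != width:
            raise SlideMapError(
                f"ragged layout: row {r} has {len(row)} cells, expected {width}"
            )
    if width > block.n_cols or len(rows) > block.n_rows:
        raise SlideMapError(
            f"layout grid {width}x{len(rows)} exceeds block grid "
            f"{block.n_cols}x{block.n_rows}"
        )
    positions = []
    for r, row in enumerate(rows, start=1):
        for c, cell in enumerate(row, start=1):
            cell = (cell or "").strip()
            if not cell:
                positions.append(
                    CorePosition(x=c, y=r, used=False, kind="empty")
                )
            elif cell.upper() == MARKER_SENTINEL:
                positions.append(CorePosition(x=c, y=r, kind="marker"))
            else:
                positions.append(
                    CorePosition(x=c, y=r, donor_block_id=cell, kind="tissue")
                )
    return SlideMap(
        slide_id=slide_id,
        recipient_block=block,
        positions=tuple(positions),
        marker_name=marker_name,
    )


def render_layout_table(slidemap: SlideMap) -> list[list[str]]:
    """Inverse of :func:`parse_layout_table` on cell contents."""
    blk = slidemap.recipient_block
    n_rows = max((p.y for p in slidemap.positions), default=blk.n_rows)
    n_cols = max((p.x for p in slidemap.positions), default=blk.n_cols)
    grid = [["" for _ in range(n_cols)] for _ in range(n_rows)]
    for p in slidemap.positions:
        if p.kind == "marker":
            grid[p.y - 1][p.x - 1] = MARKER_SENTINEL
        elif p.kind == "tissue":
            grid[p.y - 1][p.x - 1] = p.donor_block_id
    return grid


def read_layout_csv(
    path: str | Path,
    block: RecipientBlock,
    slide_id: str,
    marker_name: str = "",
    header: bool = False,
) -> SlideMap:
    """Read a layout table from CSV. ``header=True`` skips the first row."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [list(r) for r in csv.reader(fh)]
    if header:
        rows = rows[1:]
    return parse_layout_table(rows, block, slide_id, marker_name)


def read_layout_xlsx(
    path: str | Path,
    block: RecipientBlock,
    slide_id: str,
    marker_name: str = "",
    sheet: str | None = None,
    header: bool = False,
) -> SlideMap:
    """Read a layout table from an XLSX workbook (one sheet = one block)."""
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    rows = [
        ["" if c is None else str(c) for c in row]
        for row in ws.iter_rows(values_only=True)
    ]
    wb.close()
    if header:
        rows = rows[1:]
    return parse_layout_table(rows, block, slide_id, marker_name)


# ---------------------------------------------------------------------------
# Slidemap XML
# ---------------------------------------------------------------------------
#
# Project dialect. Element/attribute names reuse the TMA DES tag vocabulary
# (block_identifier, block_core_size, ...) where the registry records one,
# so slidemaps are self-describing to DES-aware consumers.

def write_slidemap_xml(slidemap: SlideMap) -> bytes:
    blk = slidemap.recipient_block
    root = etree.Element("slideMap")
    root.set("slide_identifier", slidemap.slide_id)
    if slidemap.marker_name:
        root.set("marker", slidemap.marker_name)
    b = etree.SubElement(root, "recipientBlock")
    b.set("block_identifier", blk.block_id)
    b.set("block_core_size", repr(blk.core_diameter))
    b.set("block_core_spacing", repr(blk.core_spacing))
    b.set("sliceNumber", str(blk.slice_number))
    b.set("columns", str(blk.n_cols))
    b.set("rows", str(blk.n_rows))
    for p in sorted(slidemap.positions, key=lambda p: (p.y, p.x)):
        c = etree.SubElement(root, "core")
        c.set("x", str(p.x))
        c.set("y", str(p.y))
        c.set("positionUsed", "true" if p.used else "false")
        c.set("kind", p.kind)
        if p.donor_block_id:
            c.set("donorBlock", p.donor_block_id)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def parse_slidemap_xml(xml: bytes | str) -> SlideMap:
    """Parse slidemap XML; a missing sliceNumber defaults to 1 with a warning."""
    try:
        root = etree.fromstring(xml if isinstance(xml, bytes) else xml.encode())
    except etree.XMLSyntaxError as exc:
        raise SlideMapParseError(f"malformed XML: {exc}") from exc
    if root.tag != "slideMap":
        raise SlideMapParseError(f"/{root.tag}: expected root element slideMap")
    slide_id = root.get("slide_identifier")
    if not slide_id:
        raise SlideMapParseError("/slideMap: missing slide_identifier")
    b = root.find("recipientBlock")
    if b is None:
        raise SlideMapParseError("/slideMap/recipientBlock: missing")
    slice_attr = b.get("sliceNumber")
    if slice_attr is None:
        logger.warning(
            "slidemap %s: recipientBlock omits sliceNumber, defaulting to 1",
            slide_id,
        )
        slice_number = 1
    else:
        slice_number = int(slice_attr)
    try:
        block = RecipientBlock(
            block_id=b.get("block_identifier", ""),
            core_diameter=float(b.get("block_core_size", "0.6")),
            core_spacing=float(b.get("block_core_spacing", "1.0")),
            slice_number=slice_number,
            n_cols=int(b.get("columns", "0")),
            n_rows=int(b.get("rows", "0")),
        )
    except (ValueError, SlideMapError) as exc:
        raise SlideMapParseError(f"/slideMap/recipientBlock: {exc}") from exc
    positions = []
    for i, c in enumerate(root.findall("core")):
        path = f"/slideMap/core[{i + 1}]"
        try:
            positions.append(
                CorePosition(
                    x=int(c.get("x", "0")),
                    y=int(c.get("y", "0")),
                    donor_block_id=c.get("donorBlock", ""),
                    used=c.get("positionUsed", "true") == "true",
                    kind=c.get("kind", "tissue"),
                )
            )
        except (ValueError, SlideMapError) as exc:
            raise SlideMapParseError(f"{path}: {exc}") from exc
    try:
        return SlideMap(
            slide_id=slide_id,
            recipient_block=block,
            positions=tuple(positions),
            marker_name=root.get("marker", ""),
        )
    except SlideMapError as exc:
        raise SlideMapParseError(f"/slideMap: {exc}") from exc


# ---------------------------------------------------------------------------
# Donor index
# ---------------------------------------------------------------------------

def donor_index(
    maps: SlideMap | Iterable[SlideMap],
) -> dict[str, list[tuple[str, int, int]]]:
    """Map donor_block_id -> [(slide_id, x, y), ...] across one or many slides.

    Every tissue position appears exactly once; replicate cores from the
    same donor block yield multiple entries. This supports reviewing all
    cores from one patient's donor block across different biomarker stains.
    """
    if isinstance(maps, SlideMap):
        maps = [maps]
    index: dict[str, list[tuple[str, int, int]]] = {}
    for m in maps:
        for p in m.positions:
            if p.kind == "tissue":
                index.setdefault(p.donor_block_id, []).append((m.slide_id, p.x, p.y))
    return index
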