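"""TMA DES XML exchange.

The Association for Pathology Informatics TMA Data Exchange Specification
(TMA DES) defines a shared XML vocabulary for tissue-microarray data, so
that blocks, slides, cores and results can move between systems. Only a
subset of its Common Data Elements is required for a valid document, and
the vocabulary is extensible.

This module maps the toolkit's CDE-named fields onto the DES tag
vocabulary where an equivalent exists — block_identifier,
block_core_size, block_core_spacing, slide_identifier,
core_histo-repository_donor-block, core_results_percent-tissue-staining
and core_results_tissue-intensity — and writes everything without a DES
equivalent (grid coordinates, position-used, slice number, Allred
components, HER2 and binary results) as extension elements in the
project namespace, prefix ``cg``. Importing reverses the mapping;
unrecognised vendor elements are preserved as opaque annotations rather
than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

from lxml import etree

from tmakit import __version__
from tmakit.scoring import NO_TUMOUR, ScoreRecord
from tmakit.slidemap import CorePosition, RecipientBlock, SlideMap

logger = logging.getLogger(__name__)

__all__ = [
    "CG_NS",
    "DES_TAGS",
    "TmaDesImport",
    "export_tmades",
    "import_tmades",
]

#: project extension namespace
CG_NS = "https://tmakit.example.org/ns/tmades-ext/1"

#: DES vocabulary emitted without a namespace: the structural containers
#: plus every Table-style CDE tag with a direct internal equivalent
DES_TAGS = frozenset(
    {
        "tma_des",
        "header",
        "block",
        "slide",
        "core",
        "block_identifier",
        "block_core_size",
        "block_core_spacing",
        "slide_identifier",
        "core_histo-repository_donor-block",
        "core_results_percent-tissue-staining",
        "core_results_tissue-intensity",
    }
)

#: scoring-system fields that export under a DES results tag; everything
#: else becomes a cg:field extension element
SYSTEM_FIELD_DES_TAGS = {
    ("intensity-0-3", "intensity"): "core_results_tissue-intensity",
    ("percentage", "percent_staining"): "core_results_percent-tissue-staining",
}
_DES_TAG_TO_FIELD = {v: k[1] for k, v in SYSTEM_FIELD_DES_TAGS.items()}


def _cg(tag: str) -> str:
    return f"{{{CG_NS}}}{tag}"


def _scalar_to_text(value) -> tuple[str, str]:
    if isinstance(value, bool):
        return str(value), "str"
    if isinstance(value, int):
        return str(value), "int"
    if isinstance(value, float):
        return repr(value), "float"
    return str(value), "str"


def _text_to_scalar(text: str, kind: str):
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    return text


def export_tmades(store, study: str, marker: str, today: str | None = None) -> bytes:
    """Export one (study, marker) collection as a TMA DES document.

    One ``block``/``slide`` pair per slidemap; per-core elements carry the
    donor linkage under the DES tag and coordinates/kind as ``cg:``
    extensions; each scorer's *latest* score per core is written as a
    ``cg:score`` element whose values use the DES results tags where one
    exists. An empty collection produces a header-only document with a
    logged warning.
    """
    nsmap = {"cg": CG_NS}
    root = etree.Element("tma_des", nsmap=nsmap)
    header = etree.SubElement(root, "header")
    etree.SubElement(header, _cg("origin")).text = f"{study}/{marker}"
    etree.SubElement(header, _cg("date")).text = today or date.today().isoformat()
    etree.SubElement(header, _cg("generator")).text = f"tmakit {__version__}"

    slide_ids = store.slide_ids(study, marker)
    if not slide_ids:
        logger.warning("export_tmades: collection %s/%s is empty", study, marker)
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                              pretty_print=True)
    scorers = store.scorers(study, marker)
    for slide_id in slide_ids:
        slidemap = store.get_slidemap(study, marker, slide_id)
        blk = slidemap.recipient_block
        block = etree.SubElement(root, "block")
        etree.SubElement(block, "block_identifier").text = blk.block_id
        size = etree.SubElement(block, "block_core_size")
        size.text = repr(blk.core_diameter)
        size.set("units", "mm")
        spacing = etree.SubElement(block, "block_core_spacing")
        spacing.text = repr(blk.core_spacing)
        spacing.set("units", "mm")
        etree.SubElement(block, _cg("slice_number")).text = str(blk.slice_number)
        etree.SubElement(block, _cg("columns")).text = str(blk.n_cols)
        etree.SubElement(block, _cg("rows")).text = str(blk.n_rows)
        slide = etree.SubElement(block, "slide")
        etree.SubElement(slide, "slide_identifier").text = slidemap.slide_id
        etree.SubElement(slide, _cg("marker")).text = slidemap.marker_name
        latest_by_scorer = {
            sc: store.latest_scores(study, marker, sc, slide_id) for sc in scorers
        }
        for p in slidemap.positions:
            core = etree.SubElement(slide, "core")
            etree.SubElement(core, _cg("x")).text = str(p.x)
            etree.SubElement(core, _cg("y")).text = str(p.y)
            etree.SubElement(core, _cg("position_used")).text = (
                "true" if p.used else "false"
            )
            etree.SubElement(core, _cg("kind")).text = p.kind
            if p.donor_block_id:
                etree.SubElement(
                    core, "core_histo-repository_donor-block"
                ).text = p.donor_block_id
            for sc in scorers:
                rec = latest_by_scorer[sc].get((p.x, p.y))
                if rec is None:
                    continue
                s = etree.SubElement(core, _cg("score"))
                s.set("scorer", sc)
                s.set("version", str(rec.record_version))
                s.set("timestamp", rec.timestamp)
                s.set("status", rec.status)
                for field_name, value in rec.values.items():
                    text, kind = _scalar_to_text(value)
                    des_tag = _des_tag_for(store, study, marker, sc, slide_id,
                                           field_name)
                    if des_tag is not None:
                        el = etree.SubElement(s, des_tag)
                        el.text = text
                        el.set(_cg("type"), kind)
                        el.set(_cg("field"), field_name)
                    else:
                        el = etree.SubElement(s, _cg("field"))
                        el.set("name", field_name)
                        el.set("type", kind)
                        el.text = text
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _des_tag_for(store, study, marker, scorer, slide_id, field_name):
    # resolve the slide document's scoring system to pick the DES tag
    try:
        path = store._slide_doc_path(study, marker, scorer, slide_id)
        system_name = etree.fromstring(path.read_bytes()).get("system")
    except Exception:  # pragma: no cover - defensive
        system_name = None
    return SYSTEM_FIELD_DES_TAGS.get((system_name, field_name))


@dataclass
class TmaDesImport:
    """Result of parsing a TMA DES document."""

    slidemaps: list[SlideMap] = field(default_factory=list)
    scores: list[ScoreRecord] = field(default_factory=list)
    #: (element path, serialized XML) of unrecognised vendor elements
    annotations: list[tuple[str, str]] = field(default_factory=list)
    #: cores lacking coordinates, kept as opaque donor references
    unplaced_cores: list[dict] = field(default_factory=list)
    header: dict = field(default_factory=dict)


_KNOWN_CORE_TAGS = {
    _cg("x"), _cg("y"), _cg("position_used"), _cg("kind"), _cg("score"),
    "core_histo-repository_donor-block",
}


def import_tmades(xml: bytes | str) -> TmaDesImport:
    """Parse a TMA DES document back into slidemaps and score records.

    Recognised DES tags and project extension elements map to internal
    fields. Unrecognised elements are kept as annotations and logged.
    A core without coordinates is imported as an unplaced core with a
    warning; a slide without a ``slide_identifier`` is an error.
    """
    root = etree.fromstring(xml if isinstance(xml, bytes) else xml.encode())
    if etree.QName(root).localname != "tma_des":
        raise ValueError(f"expected tma_des document, got {root.tag}")
    result = TmaDesImport()
    header = root.find("header")
    if header is not None:
        for el in header:
            result.header[etree.QName(el).localname] = el.text or ""
    for bi, block in enumerate(root.findall("block")):
        block_id = block.findtext("block_identifier") or ""
        diameter = float(block.findtext("block_core_size") or "0.6")
        spacing = float(block.findtext("block_core_spacing") or "1.0")
        slice_number = int(block.findtext(_cg("slice_number")) or "1")
        n_cols = block.findtext(_cg("columns"))
        n_rows = block.findtext(_cg("rows"))
        for slide in block.findall("slide"):
            slide_id = slide.findtext("slide_identifier")
            if not slide_id:
                raise ValueError(
                    f"/tma_des/block[{bi + 1}]/slide: missing slide_identifier"
                )
            marker_name = slide.findtext(_cg("marker")) or ""
            positions: list[CorePosition] = []
            max_x = max_y = 0
            for core in slide.findall("core"):
                x_text, y_text = core.findtext(_cg("x")), core.findtext(_cg("y"))
                donor = core.findtext("core_histo-repository_donor-block") or ""
                if x_text is None or y_text is None:
                    logger.warning(
                        "import_tmades: core on slide %s lacks coordinates; "
                        "imported unplaced", slide_id,
                    )
                    result.unplaced_cores.append(
                        {"slide_id": slide_id, "donor_block_id": donor}
                    )
                    continue
                x, y = int(x_text), int(y_text)
                max_x, max_y = max(max_x, x), max(max_y, y)
                used = (core.findtext(_cg("position_used")) or "true") == "true"
                kind = core.findtext(_cg("kind")) or (
                    "tissue" if used else "empty"
                )
                positions.append(
                    CorePosition(x=x, y=y, donor_block_id=donor, used=used,
                                 kind=kind)
                )
                for sc in core.findall(_cg("score")):
                    values = {}
                    for v in sc:
                        tag = etree.QName(v).localname
                        ns = etree.QName(v).namespace
                        if ns == CG_NS and tag == "field":
                            values[v.get("name")] = _text_to_scalar(
                                v.text or "", v.get("type", "str")
                            )
                        elif ns is None and tag in _DES_TAG_TO_FIELD:
                            field_name = v.get(_cg("field")) or _DES_TAG_TO_FIELD[tag]
                            values[field_name] = _text_to_scalar(
                                v.text or "", v.get(_cg("type"), "str")
                            )
                        else:
                            result.annotations.append(
                                (f"{slide_id}/core[{x},{y}]/score",
                                 etree.tostring(v, encoding="unicode"))
                            )
                            logger.warning(
                                "import_tmades: unknown score element %s kept "
                                "as annotation", v.tag,
                            )
                    result.scores.append(
                        ScoreRecord(
                            slide_id=slide_id, x=x, y=y,
                            scorer=sc.get("scorer", ""),
                            marker=marker_name,
                            values=values,
                            timestamp=sc.get("timestamp", ""),
                            record_version=int(sc.get("version", "1")),
                            status=sc.get("status", "scored"),
                        )
                    )
                for el in core:
                    if el.tag not in _KNOWN_CORE_TAGS:
                        result.annotations.append(
                            (f"{slide_id}/core[{x},{y}]",
                             etree.tostring(el, encoding="unicode"))
                        )
                        logger.warning(
                            "import_tmades: unknown core element %s kept as "
                            "annotation", el.tag,
                        )
            block_meta = RecipientBlock(
                block_id=block_id,
                core_diameter=diameter,
                core_spacing=spacing,
                slice_number=slice_number,
                n_cols=int(n_cols) if n_cols else max(max_x, 1),
                n_rows=int(n_rows) if n_rows else max(max_y, 1),
            )
            result.slidemaps.append(
                SlideMap(
                    slide_id=slide_id,
                    recipient_block=block_meta,
                    positions=tuple(positions),
                    marker_name=marker_name,
                )
            )
    return result
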