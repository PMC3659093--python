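"""Hierarchical study store.

Scoring data lives in a directory tree of XML documents mirroring the
study → marker → scorer → slide collection hierarchy:

.. code-block:: text

    root/
      permissions.xml
      {study}/
        {marker}/
          _slidemaps/{slide_id}.xml     canonical slidemap per slide
          {scorer}/{slide_id}.xml       one scorer's slide document

A slide document holds a reference to the canonical slidemap (path plus
SHA-256 checksum, so a silently edited layout is detected), the score-form
template generated from it, and the scorer's append-only score records.
The documents are the sole source of truth — closing and reopening a store
changes nothing — and patient identities never appear: cores are linked to
the outside world only through donor-block identifiers.

Permissions are advisory grants enforced by the library API: a scorer may
open and write slide documents only under (study, marker) pairs they have
been granted. Authentication is deployment, not method, and is out of
scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from lxml import etree

from tmakit.registry import Registry, load_default_cdes
from tmakit.scoring import (
    NO_TUMOUR,
    ScoreRecord,
    ScoringSystem,
    get_builtin_system,
    validate_score,
)
from tmakit.slidemap import SlideMap, parse_slidemap_xml, write_slidemap_xml

__all__ = [
    "StudyStore",
    "StoreError",
    "PermissionError_",
    "ScoreFormTemplate",
    "TemplateEntry",
    "make_score_template",
    "template_to_xml",
    "template_from_xml",
]


class StoreError(ValueError):
    """Store invariant violation (duplicate ids, missing collections...)."""


class PermissionError_(StoreError):
    """Scorer lacks a grant for the (study, marker) collection."""


def _path_safe(name: str) -> str:
    if not name or any(c in name for c in "/\\\0") or name.startswith("."):
        raise StoreError(f"identifier {name!r} is not path-safe")
    return name


# ---------------------------------------------------------------------------
# Score-form templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateEntry:
    """One core entry on a scoring form."""

    x: int
    y: int
    donor_block_id: str
    image_ref: str
    kind: str  # tissue | marker
    slots: tuple[str, ...]  # empty score slots, one per system field


@dataclass(frozen=True)
class ScoreFormTemplate:
    """The scoring form generated from a slidemap for one scoring system.

    Contains one entry per *used* position: tissue cores carry empty score
    slots (one per system field); marker cores are flagged and carry none.
    """

    slide_id: str
    marker: str
    system_name: str
    entries: tuple[TemplateEntry, ...]

    @property
    def scoreable_entries(self) -> tuple[TemplateEntry, ...]:
        return tuple(e for e in self.entries if e.kind == "tissue")


def make_score_template(
    slidemap: SlideMap, system: ScoringSystem
) -> ScoreFormTemplate:
    entries = []
    for p in slidemap.positions:
        if not p.used:
            continue
        entries.append(
            TemplateEntry(
                x=p.x,
                y=p.y,
                donor_block_id=p.donor_block_id,
                image_ref=f"{slidemap.slide_id}_{p.x}_{p.y}_1.JPEG",
                kind=p.kind,
                slots=system.field_names if p.kind == "tissue" else (),
            )
        )
    return ScoreFormTemplate(
        slide_id=slidemap.slide_id,
        marker=slidemap.marker_name,
        system_name=system.name,
        entries=tuple(entries),
    )


def template_to_xml(template: ScoreFormTemplate) -> bytes:
    root = etree.Element("scoreTemplate")
    root.set("slide_id", template.slide_id)
    root.set("marker", template.marker)
    root.set("system", template.system_name)
    for e in template.entries:
        el = etree.SubElement(root, "entry")
        el.set("x", str(e.x))
        el.set("y", str(e.y))
        el.set("kind", e.kind)
        if e.donor_block_id:
            el.set("donorBlock", e.donor_block_id)
        el.set("imageRef", e.image_ref)
        for slot in e.slots:
            etree.SubElement(el, "slot", field=slot)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def template_from_xml(xml: bytes | str) -> ScoreFormTemplate:
    root = etree.fromstring(xml if isinstance(xml, bytes) else xml.encode())
    if root.tag != "scoreTemplate":
        raise StoreError(f"expected scoreTemplate element, got {root.tag}")
    entries = tuple(
        TemplateEntry(
            x=int(e.get("x")),
            y=int(e.get("y")),
            donor_block_id=e.get("donorBlock", ""),
            image_ref=e.get("imageRef", ""),
            kind=e.get("kind", "tissue"),
            slots=tuple(s.get("field") for s in e.findall("slot")),
        )
        for e in root.findall("entry")
    )
    return ScoreFormTemplate(
        slide_id=root.get("slide_id"),
        marker=root.get("marker", ""),
        system_name=root.get("system", ""),
        entries=entries,
    )


# ---------------------------------------------------------------------------
# Score-value serialisation (typed, so round trips are exact)
# ---------------------------------------------------------------------------

def _value_to_xml(parent, field_name: str, value) -> None:
    el = etree.SubElement(parent, "value", field=field_name)
    if isinstance(value, bool):
        el.set("type", "str")
        el.text = str(value)
    elif isinstance(value, int):
        el.set("type", "int")
        el.text = str(value)
    elif isinstance(value, float):
        el.set("type", "float")
        el.text = repr(value)
    else:
        el.set("type", "str")
        el.text = str(value)


def _value_from_xml(el):
    text = el.text or ""
    kind = el.get("type", "str")
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    return text


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------

class StudyStore:
    """Directory-backed study/marker/scorer/slide document store."""

    SLIDEMAP_DIR = "_slidemaps"

    def __init__(self, root: str | Path, registry: Registry | None = None) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.registry = registry or load_default_cdes()

    # -- permissions -------------------------------------------------------

    @property
    def _permissions_path(self) -> Path:
        return self.root / "permissions.xml"

    def _load_grants(self) -> set[tuple[str, str, str]]:
        path = self._permissions_path
        if not path.exists():
            return set()
        root = etree.fromstring(path.read_bytes())
        return {
            (g.get("scorer"), g.get("study"), g.get("marker"))
            for g in root.findall("grant")
        }

    def _save_grants(self, grants: set[tuple[str, str, str]]) -> None:
        root = etree.Element("permissions")
        for scorer, study, marker in sorted(grants):
            etree.SubElement(root, "grant", scorer=scorer, study=study,
                             marker=marker)
        self._permissions_path.write_bytes(
            etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                           pretty_print=True)
        )

    def grant(self, scorer: str, study: str, marker: str) -> None:
        """Grant a scorer read/write access to one (study, marker) collection."""
        _path_safe(scorer)
        self._marker_dir(study, marker)  # validates existence
        grants = self._load_grants()
        grants.add((scorer, study, marker))
        self._save_grants(grants)

    def has_grant(self, scorer: str, study: str, marker: str) -> bool:
        return (scorer, study, marker) in self._load_grants()

    def _require_grant(self, scorer: str, study: str, marker: str) -> None:
        if not self.has_grant(scorer, study, marker):
            raise PermissionError_(
                f"scorer {scorer!r} has no grant for {study}/{marker}"
            )

    # -- collections -------------------------------------------------------

    def create_study(self, study_id: str) -> Path:
        path = self.root / _path_safe(study_id)
        if path.exists():
            raise StoreError(f"study {study_id!r} already exists")
        path.mkdir()
        return path

    def add_marker(self, study_id: str, marker: str) -> Path:
        study = self.root / _path_safe(study_id)
        if not study.is_dir():
            raise StoreError(f"no study {study_id!r}")
        path = study / _path_safe(marker)
        if path.exists():
            raise StoreError(f"marker {marker!r} already exists in {study_id!r}")
        path.mkdir()
        (path / self.SLIDEMAP_DIR).mkdir()
        return path

    def _marker_dir(self, study: str, marker: str) -> Path:
        path = self.root / _path_safe(study) / _path_safe(marker)
        if not path.is_dir():
            raise StoreError(f"no collection {study}/{marker}")
        return path

    def studies(self) -> list[str]:
        return sorted(
            p.name for p in self.root.iterdir()
            if p.is_dir() and not p.name.startswith("_")
        )

    def markers(self, study: str) -> list[str]:
        study_dir = self.root / _path_safe(study)
        if not study_dir.is_dir():
            raise StoreError(f"no study {study!r}")
        return sorted(
            p.name for p in study_dir.iterdir()
            if p.is_dir() and not p.name.startswith("_")
        )

    def scorers(self, study: str, marker: str) -> list[str]:
        return sorted(
            p.name for p in self._marker_dir(study, marker).iterdir()
            if p.is_dir() and p.name != self.SLIDEMAP_DIR
        )

    # -- slidemaps ---------------------------------------------------------

    def add_slidemap(self, study: str, marker: str, slidemap: SlideMap) -> Path:
        path = (
            self._marker_dir(study, marker)
            / self.SLIDEMAP_DIR
            / f"{_path_safe(slidemap.slide_id)}.xml"
        )
        if path.exists():
            raise StoreError(
                f"slidemap {slidemap.slide_id!r} already in {study}/{marker}"
            )
        path.write_bytes(write_slidemap_xml(slidemap))
        return path

    def get_slidemap(self, study: str, marker: str, slide_id: str) -> SlideMap:
        path = (
            self._marker_dir(study, marker)
            / self.SLIDEMAP_DIR
            / f"{_path_safe(slide_id)}.xml"
        )
        if not path.exists():
            raise StoreError(f"no slidemap {slide_id!r} in {study}/{marker}")
        return parse_slidemap_xml(path.read_bytes())

    def slide_ids(self, study: str, marker: str) -> list[str]:
        smdir = self._marker_dir(study, marker) / self.SLIDEMAP_DIR
        return sorted(p.stem for p in smdir.glob("*.xml"))

    def _slidemap_checksum(self, study: str, marker: str, slide_id: str) -> str:
        path = self._marker_dir(study, marker) / self.SLIDEMAP_DIR / f"{slide_id}.xml"
        return hashlib.sha256(path.read_bytes()).hexdigest()

    # -- slide documents ---------------------------------------------------

    def _slide_doc_path(
        self, study: str, marker: str, scorer: str, slide_id: str
    ) -> Path:
        return (
            self._marker_dir(study, marker)
            / _path_safe(scorer)
            / f"{_path_safe(slide_id)}.xml"
        )

    def open_slide(
        self,
        study: str,
        marker: str,
        scorer: str,
        slide_id: str,
        system: ScoringSystem | str,
    ) -> ScoreFormTemplate:
        """Open (creating on first use) a scorer's slide document.

        On first open the score-form template is generated from the
        canonical slidemap and stored under the scorer's collection.
        Requires a grant.
        """
        self._require_grant(scorer, study, marker)
        if isinstance(system, str):
            system = get_builtin_system(system)
        path = self._slide_doc_path(study, marker, scorer, slide_id)
        if path.exists():
            return self._read_doc(path)[0]
        slidemap = self.get_slidemap(study, marker, slide_id)
        template = make_score_template(slidemap, system)
        root = etree.Element("slideDocument")
        root.set("slide_id", slide_id)
        root.set("study", study)
        root.set("marker", marker)
        root.set("scorer", scorer)
        root.set("system", system.name)
        root.set("slidemapRef", f"../{self.SLIDEMAP_DIR}/{slide_id}.xml")
        root.set("slidemapChecksum", self._slidemap_checksum(study, marker, slide_id))
        t = etree.fromstring(template_to_xml(template))
        root.append(t)
        etree.SubElement(root, "scores")
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(
            etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                           pretty_print=True)
        )
        return template

    def _read_doc(self, path: Path):
        root = etree.fromstring(path.read_bytes())
        template = template_from_xml(
            etree.tostring(root.find("scoreTemplate"))
        )
        records = []
        study, marker = root.get("study"), root.get("marker")
        scorer, slide_id = root.get("scorer"), root.get("slide_id")
        for s in root.find("scores").findall("score"):
            records.append(
                ScoreRecord(
                    slide_id=slide_id,
                    x=int(s.get("x")),
                    y=int(s.get("y")),
                    scorer=scorer,
                    marker=marker,
                    values={
                        v.get("field"): _value_from_xml(v)
                        for v in s.findall("value")
                    },
                    timestamp=s.get("timestamp", ""),
                    record_version=int(s.get("version")),
                    status=s.get("status", "scored"),
                    note=s.get("note", ""),
                )
            )
        return template, records, root

    def record_score(
        self,
        study: str,
        marker: str,
        record: ScoreRecord,
        system: ScoringSystem | str | None = None,
    ) -> ScoreRecord:
        """Append a validated score to the scorer's slide document.

        The record's ``record_version`` is assigned automatically: one more
        than the latest version already recorded for that core by that
        scorer. Validation failures leave the document unchanged.
        """
        self._require_grant(record.scorer, study, marker)
        path = self._slide_doc_path(study, marker, record.scorer, record.slide_id)
        if not path.exists():
            raise StoreError(
                f"no slide document for {record.scorer!r} on "
                f"{record.slide_id!r}; open_slide first"
            )
        template, existing, root = self._read_doc(path)
        if system is None:
            system = get_builtin_system(template.system_name)
        elif isinstance(system, str):
            system = get_builtin_system(system)
        result = validate_score(system, self.registry, record)
        if not result.valid:
            raise StoreError(f"score rejected: {result.message}")
        if not any(
            e.x == record.x and e.y == record.y and e.kind == "tissue"
            for e in template.entries
        ):
            raise StoreError(
                f"({record.x}, {record.y}) is not a scoreable position on "
                f"{record.slide_id!r}"
            )
        version = 1 + max(
            (r.record_version for r in existing
             if (r.x, r.y) == (record.x, record.y)),
            default=0,
        )
        stored = ScoreRecord(
            slide_id=record.slide_id, x=record.x, y=record.y,
            scorer=record.scorer, marker=record.marker,
            values=record.values, timestamp=record.timestamp,
            record_version=version, status=record.status, note=record.note,
        )
        s = etree.SubElement(root.find("scores"), "score")
        s.set("x", str(stored.x))
        s.set("y", str(stored.y))
        s.set("version", str(version))
        s.set("timestamp", stored.timestamp)
        s.set("status", stored.status)
        if stored.note:
            s.set("note", stored.note)
        for field_name, value in stored.values.items():
            _value_to_xml(s, field_name, value)
        path.write_bytes(
            etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                           pretty_print=True)
        )
        return stored

    def get_scores(
        self, study: str, marker: str, scorer: str, slide_id: str
    ) -> list[ScoreRecord]:
        path = self._slide_doc_path(study, marker, scorer, slide_id)
        if not path.exists():
            return []
        return self._read_doc(path)[1]

    def latest_scores(
        self, study: str, marker: str, scorer: str, slide_id: str
    ) -> dict[tuple[int, int], ScoreRecord]:
        latest: dict[tuple[int, int], ScoreRecord] = {}
        for rec in self.get_scores(study, marker, scorer, slide_id):
            key = (rec.x, rec.y)
            if key not in latest or rec.record_version > latest[key].record_version:
                latest[key] = rec
        return latest

    # -- export and queries ------------------------------------------------

    def export_table(
        self, study: str, marker: str, scorer: str | None = None
    ) -> pd.DataFrame:
        """Latest scores as a tidy table, one row per (core, scorer).

        Columns: study, marker, scorer, slide_id, x, y, donor_block_id,
        status, one column per score field, timestamp. The donor-block
        linkage comes from the slidemap, so every row ties a score back to
        the tissue it came from.
        """
        scorers = [scorer] if scorer else self.scorers(study, marker)
        rows = []
        field_names: list[str] = []
        for sc in scorers:
            for slide_id in self.slide_ids(study, marker):
                slidemap = self.get_slidemap(study, marker, slide_id)
                donors = {
                    (p.x, p.y): p.donor_block_id for p in slidemap.positions
                }
                for (x, y), rec in sorted(self.latest_scores(
                    study, marker, sc, slide_id
                ).items(), key=lambda kv: (kv[0][1], kv[0][0])):
                    row = {
                        "study": study, "marker": marker, "scorer": sc,
                        "slide_id": slide_id, "x": x, "y": y,
                        "donor_block_id": donors.get((x, y), ""),
                        "status": rec.status,
                    }
                    for field_name, value in rec.values.items():
                        row[field_name] = value
                        if field_name not in field_names:
                            field_names.append(field_name)
                    row["timestamp"] = rec.timestamp
                    rows.append(row)
        columns = [
            "study", "marker", "scorer", "slide_id", "x", "y",
            "donor_block_id", "status", *field_names, "timestamp",
        ]
        return pd.DataFrame(rows, columns=columns)

    def query_by_donor(self, donor_block_id: str) -> list[dict]:
        """All cores from one donor block, across studies and markers.

        Each entry carries (study, marker, slide_id, x, y) plus the latest
        score of every scorer who scored that core. Replicate cores yield
        one entry per position; an unknown donor yields an empty list.
        """
        results = []
        for study in self.studies():
            for marker in self.markers(study):
                for slide_id in self.slide_ids(study, marker):
                    slidemap = self.get_slidemap(study, marker, slide_id)
                    for p in slidemap.positions:
                        if p.kind != "tissue" or p.donor_block_id != donor_block_id:
                            continue
                        latest = {}
                        for sc in self.scorers(study, marker):
                            rec = self.latest_scores(
                                study, marker, sc, slide_id
                            ).get((p.x, p.y))
                            if rec is not None:
                                latest[sc] = rec
                        results.append(
                            {
                                "study": study, "marker": marker,
                                "slide_id": slide_id, "x": p.x, "y": p.y,
                                "latest_scores": latest,
                            }
                        )
        return results
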