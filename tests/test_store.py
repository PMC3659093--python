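"""Study store: hierarchy, permissions, templates, versioned scores, export."""

import numpy as np
import pytest
from lxml import etree

from tmakit.scoring import NO_TUMOUR, ScoreRecord, get_builtin_system
from tmakit.store import (
    PermissionError_,
    StoreError,
    StudyStore,
    make_score_template,
    template_from_xml,
    template_to_xml,
)

from conftest import random_slidemap


@pytest.fixture()
def store(tmp_path, slidemap_3x3):
    s = StudyStore(tmp_path / "store")
    s.create_study("BCAC")
    s.add_marker("BCAC", "ER")
    s.add_slidemap("BCAC", "ER", slidemap_3x3)
    return s


def _rec(x, y, intensity, scorer="path1", slide_id="S1"):
    return ScoreRecord(slide_id, x, y, scorer, "ER",
                       values={"intensity": intensity},
                       timestamp="2013-05-01T09:00:00")


class TestHierarchyAndPermissions:
    def test_paths_follow_collection_hierarchy(self, store, tmp_path):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        assert (tmp_path / "store" / "BCAC" / "ER" / "path1" / "S1.xml").exists()

    def test_duplicate_study_rejected(self, store):
        with pytest.raises(StoreError):
            store.create_study("BCAC")

    def test_granted_write_accepted(self, store):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        stored = store.record_score("BCAC", "ER", _rec(1, 1, 2))
        assert stored.record_version == 1

    def test_ungranted_write_is_permission_error(self, store):
        with pytest.raises(PermissionError_):
            store.open_slide("BCAC", "ER", "path2", "S1", "intensity-0-3")

    def test_scorer_granted_two_markers_writes_both(self, store, slidemap_3x3):
        store.add_marker("BCAC", "PR")
        pr_map = type(slidemap_3x3)(
            slide_id="S1-PR",
            recipient_block=slidemap_3x3.recipient_block,
            positions=slidemap_3x3.positions,
            marker_name="PR",
        )
        store.add_slidemap("BCAC", "PR", pr_map)
        store.grant("path1", "BCAC", "ER")
        store.grant("path1", "BCAC", "PR")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        store.open_slide("BCAC", "PR", "path1", "S1-PR", "intensity-0-3")
        store.record_score("BCAC", "ER", _rec(1, 1, 1))
        store.record_score(
            "BCAC", "PR",
            ScoreRecord("S1-PR", 1, 1, "path1", "PR", values={"intensity": 2}),
        )

    def test_randomized_grants_never_allow_ungranted_writes(self, store, rng):
        scorers = [f"user{i}" for i in range(4)]
        granted = {s for s in scorers if rng.uniform() < 0.5}
        for s in granted:
            store.grant(s, "BCAC", "ER")
        for s in scorers:
            if s in granted:
                store.open_slide("BCAC", "ER", s, "S1", "intensity-0-3")
            else:
                with pytest.raises(PermissionError_):
                    store.open_slide("BCAC", "ER", s, "S1", "intensity-0-3")
                with pytest.raises(PermissionError_):
                    store.record_score("BCAC", "ER", _rec(1, 1, 1, scorer=s))


class TestTemplates:
    def test_entry_counts(self, slidemap_3x3):
        # 9 positions: 1 gap, 1 marker -> 8 entries of which 7 scoreable
        template = make_score_template(
            slidemap_3x3, get_builtin_system("intensity-0-3")
        )
        assert len(template.entries) == 8
        assert len(template.scoreable_entries) == 7

    def test_allred_template_has_three_slots_per_entry(self, slidemap_3x3):
        template = make_score_template(slidemap_3x3, get_builtin_system("allred"))
        for entry in template.scoreable_entries:
            assert entry.slots == ("intensity", "proportion", "total")

    def test_marker_entries_flagged_without_slots(self, slidemap_3x3):
        template = make_score_template(
            slidemap_3x3, get_builtin_system("intensity-0-3")
        )
        markers = [e for e in template.entries if e.kind == "marker"]
        assert len(markers) == 1 and markers[0].slots == ()

    def test_xml_round_trip(self, slidemap_3x3, rng):
        for system_name in ("intensity-0-3", "allred", "percentage"):
            t = make_score_template(slidemap_3x3, get_builtin_system(system_name))
            assert template_from_xml(template_to_xml(t)) == t
        for _ in range(20):
            t = make_score_template(
                random_slidemap(rng), get_builtin_system("allred")
            )
            assert template_from_xml(template_to_xml(t)) == t


class TestRecordScore:
    def test_versions_increment_and_latest_view(self, store):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        first = store.record_score("BCAC", "ER", _rec(1, 1, 0))
        second = store.record_score("BCAC", "ER", _rec(1, 1, 3))
        assert (first.record_version, second.record_version) == (1, 2)
        latest = store.latest_scores("BCAC", "ER", "path1", "S1")
        assert latest[(1, 1)].values["intensity"] == 3
        assert len(store.get_scores("BCAC", "ER", "path1", "S1")) == 2

    def test_invalid_value_rejected_store_unchanged(self, store, tmp_path):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        doc = tmp_path / "store" / "BCAC" / "ER" / "path1" / "S1.xml"
        before = doc.read_bytes()
        with pytest.raises(StoreError, match="rejected"):
            store.record_score("BCAC", "ER", _rec(1, 1, 4))
        assert doc.read_bytes() == before

    def test_unscoreable_position_rejected(self, store):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        with pytest.raises(StoreError, match="not a scoreable"):
            store.record_score("BCAC", "ER", _rec(2, 1, 1))  # the gap
        with pytest.raises(StoreError, match="not a scoreable"):
            store.record_score("BCAC", "ER", _rec(3, 1, 1))  # the marker core

    def test_no_tumour_record_accepted(self, store):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        rec = ScoreRecord("S1", 1, 1, "path1", "ER", status=NO_TUMOUR)
        stored = store.record_score("BCAC", "ER", rec)
        assert stored.status == NO_TUMOUR

    def test_store_survives_reopen_byte_identically(self, store, tmp_path):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        store.record_score("BCAC", "ER", _rec(1, 1, 2))
        root = tmp_path / "store"
        files = {p: p.read_bytes() for p in root.rglob("*.xml")}
        reopened = StudyStore(root)
        assert reopened.get_scores("BCAC", "ER", "path1", "S1") == \
            store.get_scores("BCAC", "ER", "path1", "S1")
        assert {p: p.read_bytes() for p in root.rglob("*.xml")} == files

    def test_slidemap_checksum_recorded(self, store, tmp_path):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        doc = etree.fromstring(
            (tmp_path / "store" / "BCAC" / "ER" / "path1" / "S1.xml").read_bytes()
        )
        assert len(doc.get("slidemapChecksum")) == 64
        assert doc.get("slidemapRef").endswith("_slidemaps/S1.xml")


class TestExportAndQueries:
    def _populate(self, store, scores_by_scorer):
        for scorer, cells in scores_by_scorer.items():
            store.grant(scorer, "BCAC", "ER")
            store.open_slide("BCAC", "ER", scorer, "S1", "intensity-0-3")
            for (x, y), v in cells.items():
                store.record_score("BCAC", "ER", _rec(x, y, v, scorer=scorer))

    def test_rows_carry_donor_linkage(self, store):
        self._populate(store, {"path1": {(1, 1): 2, (2, 2): 3}})
        table = store.export_table("BCAC", "ER")
        assert len(table) == 2
        assert set(table["donor_block_id"]) == {"DB1"}  # replicate donor cells
        assert list(table.columns[:7]) == [
            "study", "marker", "scorer", "slide_id", "x", "y", "donor_block_id",
        ]

    def test_no_scores_gives_header_only(self, store):
        store.grant("path1", "BCAC", "ER")
        store.open_slide("BCAC", "ER", "path1", "S1", "intensity-0-3")
        table = store.export_table("BCAC", "ER")
        assert len(table) == 0 and "donor_block_id" in table.columns

    def test_all_mode_lists_both_scorers(self, store):
        self._populate(store, {"path1": {(1, 1): 2}, "path2": {(1, 1): 3}})
        assert len(store.export_table("BCAC", "ER")) == 2
        assert len(store.export_table("BCAC", "ER", scorer="path1")) == 1

    def test_row_count_matches_document_scan_oracle(self, store, rng, tmp_path):
        cells = [(x, y) for x in (1, 2, 3) for y in (2, 3)]
        scores = {
            scorer: {
                c: int(rng.integers(0, 4)) for c in cells if rng.uniform() < 0.7
            }
            for scorer in ("path1", "path2")
        }
        self._populate(store, scores)
        # oracle: scan slide documents directly, counting distinct scored cores
        n_pairs = 0
        for doc in (tmp_path / "store" / "BCAC" / "ER").rglob("*/S1.xml"):
            if doc.parent.name == "_slidemaps":
                continue
            root = etree.fromstring(doc.read_bytes())
            cores = {
                (s.get("x"), s.get("y"))
                for s in root.find("scores").findall("score")
            }
            n_pairs += len(cores)
        assert len(store.export_table("BCAC", "ER")) == n_pairs

    def test_query_by_donor_spans_markers(self, store, slidemap_3x3):
        store.add_marker("BCAC", "PR")
        pr_map = type(slidemap_3x3)(
            slide_id="S1-PR",
            recipient_block=slidemap_3x3.recipient_block,
            positions=slidemap_3x3.positions,
            marker_name="PR",
        )
        store.add_slidemap("BCAC", "PR", pr_map)
        entries = store.query_by_donor("DB1")  # replicated twice per slide
        assert len(entries) == 4
        assert {e["marker"] for e in entries} == {"ER", "PR"}

    def test_unknown_donor_empty(self, store):
        assert store.query_by_donor("NOPE") == []

    def test_replicates_give_one_entry_per_core(self, store):
        # brute-force scan oracle on the slidemap itself
        slidemap = store.get_slidemap("BCAC", "ER", "S1")
        expected = [
            p for p in slidemap.tissue_positions if p.donor_block_id == "DB1"
        ]
        assert len(store.query_by_donor("DB1")) == len(expected) == 2
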