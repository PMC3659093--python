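"""Scoring systems and score records.

A :class:`ScoringSystem` is an ordered set of named fields, each bound to a
CDE in the metadata registry that supplies its value domain; a system may
also declare derived fields whose value is fixed by a derivation rule over
the other fields (the Allred total is the canonical example). Scores are
immutable, versioned :class:`ScoreRecord` objects: re-scoring a core
appends a record with a higher ``record_version`` rather than overwriting,
preserving an audit trail.

The Allred system grades oestrogen-receptor (ER) immunohistochemistry with
two components — staining intensity (0–3) and the proportion of stained
cells (0–5) — whose sum is the total score. The components are coupled: a
tissue with no stained cells has both components zero, so a total of 1 is
impossible and the total ranges over {0} ∪ [2, 8]. Totals of 3 and above
are read as ER positive; 2 and 3 are the borderline grades that separate
ER-negative from ER-positive tumours.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

from tmakit.registry import (
    CDEDefinition,
    Registry,
    ValidationResult,
    load_default_cdes,
    validate_value,
)

__all__ = [
    "ScoringSystem",
    "ScoreRecord",
    "AllredScore",
    "AllredError",
    "allred_total",
    "classify_er_status",
    "validate_score",
    "builtin_systems",
    "get_builtin_system",
    "NO_TUMOUR",
    "scores_to_csv",
    "scores_from_csv",
]

#: status value recorded when a core contains no scorable tumour tissue
NO_TUMOUR = "no_tumour"


class AllredError(ValueError):
    """Illegal Allred component combination."""


def allred_total(intensity: int, proportion: int) -> int:
    """Composite Allred score: intensity (0-3) + proportion (0-5).

    The components must be zero together (no staining) or non-zero
    together; mixed zero/non-zero pairs violate the coupling rule and
    raise :class:`AllredError`.
    """
    if intensity not in range(4):
        raise AllredError(f"intensity {intensity} outside 0-3")
    if proportion not in range(6):
        raise AllredError(f"proportion {proportion} outside 0-5")
    if (intensity == 0) != (proportion == 0):
        raise AllredError(
            f"intensity {intensity} and proportion {proportion} must be zero "
            "together or non-zero together"
        )
    return intensity + proportion


def classify_er_status(total: int) -> str:
    """ER status from the Allred total: ``negative`` iff total <= 2.

    A total of 1 is unreachable under the coupling rule and is rejected.
    """
    if total == 1 or total not in range(9):
        raise AllredError(f"total {total} not in {{0}} ∪ [2, 8]")
    return "positive" if total >= 3 else "negative"


@dataclass(frozen=True)
class AllredScore:
    """A validated Allred component pair with its total."""

    intensity: int
    proportion: int
    total: int = None  # type: ignore[assignment]  # derived when omitted

    def __post_init__(self) -> None:
        expected = allred_total(self.intensity, self.proportion)
        if self.total is None:
            object.__setattr__(self, "total", expected)
        elif self.total != expected:
            raise AllredError(
                f"total {self.total} != intensity + proportion = {expected}"
            )

    @property
    def er_status(self) -> str:
        return classify_er_status(self.total)


# ---------------------------------------------------------------------------
# Scoring systems
# ---------------------------------------------------------------------------

def _allred_total_rule(values: Mapping[str, object]) -> ValidationResult:
    try:
        expected = allred_total(int(values["intensity"]), int(values["proportion"]))
    except (KeyError, TypeError, ValueError, AllredError) as exc:
        return ValidationResult(False, f"allred components: {exc}")
    if int(values["total"]) != expected:
        return ValidationResult(
            False,
            f"total {values['total']} != intensity + proportion = {expected}",
        )
    return ValidationResult(True)


#: registry of derivation rules referenced by ScoringSystem.derived_fields
DERIVATION_RULES: dict[str, Callable[[Mapping[str, object]], ValidationResult]] = {
    "allred-total": _allred_total_rule,
}


@dataclass(frozen=True)
class ScoringSystem:
    """A named scoring form: fields bound to CDEs plus derivation rules."""

    name: str
    fields: tuple[tuple[str, str], ...]  # (field_name, CDE identifier)
    derived_fields: tuple[tuple[str, str], ...] = ()  # (field_name, rule id)

    def __post_init__(self) -> None:
        names = [f for f, _ in self.fields]
        if len(set(names)) != len(names):
            raise ValueError(f"system {self.name!r} repeats a field name")
        for _, rule in self.derived_fields:
            if rule not in DERIVATION_RULES:
                raise ValueError(f"unknown derivation rule {rule!r}")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.fields)

    def cde_for(self, field_name: str, registry: Registry) -> CDEDefinition:
        for f, cde_id in self.fields:
            if f == field_name:
                return registry.get(cde_id)
        raise KeyError(f"system {self.name!r} has no field {field_name!r}")


def builtin_systems() -> tuple[ScoringSystem, ...]:
    """The built-in scoring systems, bound to the default CDE registry.

    Returns five systems: ``allred`` (intensity + proportion with the
    derived total), ``intensity-0-3`` (the generic 0-3 IHC intensity
    grade), ``percentage`` (percent tissue staining), ``her2-ihc``
    (categories 0/1+/2+/3+) and ``binary`` (positive/negative).
    """
    return (
        ScoringSystem(
            name="allred",
            fields=(
                ("intensity", "allred-intensity-score"),
                ("proportion", "allred-proportion-score"),
                ("total", "allred-score-er-status"),
            ),
            derived_fields=(("total", "allred-total"),),
        ),
        ScoringSystem(
            name="intensity-0-3",
            fields=(("intensity", "allred-intensity-score"),),
        ),
        ScoringSystem(
            name="percentage",
            fields=(("percent_staining", "percentage-tissue-staining"),),
        ),
        ScoringSystem(
            name="her2-ihc",
            fields=(("her2_status", "her2-status-ihc"),),
        ),
        ScoringSystem(
            name="binary",
            fields=(("result", "binary-biomarker-staining"),),
        ),
    )


def get_builtin_system(name: str) -> ScoringSystem:
    for system in builtin_systems():
        if system.name == name:
            return system
    raise KeyError(f"no builtin scoring system named {name!r}")


# ---------------------------------------------------------------------------
# Score records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreRecord:
    """One scorer's values for one core under one scoring system.

    ``status`` distinguishes ordinary scored records ("scored") from
    no-tumour calls (:data:`NO_TUMOUR`), which carry no field values.
    ``note`` is an optional free-text comment carried opaquely.
    """

    slide_id: str
    x: int
    y: int
    scorer: str
    marker: str
    values: Mapping[str, object] = field(default_factory=dict)
    timestamp: str = ""
    record_version: int = 1
    status: str = "scored"
    note: str = ""

    def __post_init__(self) -> None:
        if self.record_version < 1:
            raise ValueError("record_version must be >= 1")
        if self.status not in ("scored", NO_TUMOUR):
            raise ValueError(f"unknown record status {self.status!r}")
        object.__setattr__(self, "values", dict(self.values))

    @property
    def core(self) -> tuple[str, int, int]:
        return (self.slide_id, self.x, self.y)


def validate_score(
    system: ScoringSystem,
    registry: Registry,
    record: ScoreRecord,
) -> ValidationResult:
    """Check a record against a system: field presence, CDE domains, rules.

    No-tumour records are valid with no field values. Unknown field names,
    missing fields, out-of-domain values and derivation-rule violations
    each produce an invalid result with an explanatory message.
    """
    if record.status == NO_TUMOUR:
        if record.values:
            return ValidationResult(False, "no-tumour record must carry no values")
        return ValidationResult(True)
    known = set(system.field_names)
    unknown = set(record.values) - known
    if unknown:
        return ValidationResult(
            False, f"unknown field(s) {sorted(unknown)} for system {system.name!r}"
        )
    missing = known - set(record.values)
    if missing:
        return ValidationResult(
            False, f"missing field(s) {sorted(missing)} for system {system.name!r}"
        )
    for field_name, cde_id in system.fields:
        result = validate_value(registry.get(cde_id), record.values[field_name])
        if not result.valid:
            return ValidationResult(False, f"{field_name}: {result.message}")
    for _, rule_id in system.derived_fields:
        result = DERIVATION_RULES[rule_id](record.values)
        if not result.valid:
            return result
    return ValidationResult(True)


# ---------------------------------------------------------------------------
# CSV exchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = (
    "slide_id", "x", "y", "scorer", "marker", "field", "value", "timestamp",
)


def scores_to_csv(records: Iterable[ScoreRecord], path: str | Path) -> Path:
    """Write records in long form: one row per (record, field).

    No-tumour records emit a single row with field ``status`` and value
    ``no_tumour``.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            base = [rec.slide_id, rec.x, rec.y, rec.scorer, rec.marker]
            if rec.status == NO_TUMOUR:
                writer.writerow(base + ["status", NO_TUMOUR, rec.timestamp])
            else:
                for field_name, value in rec.values.items():
                    writer.writerow(base + [field_name, value, rec.timestamp])
    return path


def scores_from_csv(path: str | Path) -> list[ScoreRecord]:
    """Read long-form score CSV back into records (one per core/scorer/marker).

    Values are parsed as int, then float, then kept as text; record_version
    is assigned 1 — versioning is the store's concern on ingestion.
    """
    grouped: dict[tuple, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = (row["slide_id"], int(row["x"]), int(row["y"]),
                   row["scorer"], row["marker"])
            entry = grouped.setdefault(
                key, {"values": {}, "timestamp": row["timestamp"], "status": "scored"}
            )
            if row["field"] == "status" and row["value"] == NO_TUMOUR:
                entry["status"] = NO_TUMOUR
            else:
                entry["values"][row["field"]] = _parse_scalar(row["value"])
    records = []
    for (slide_id, x, y, scorer, marker), entry in grouped.items():
        records.append(
            ScoreRecord(
                slide_id=slide_id, x=x, y=y, scorer=scorer, marker=marker,
                values=entry["values"] if entry["status"] == "scored" else {},
                timestamp=entry["timestamp"], status=entry["status"],
            )
        )
    return records


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text
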