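"""Common Data Element (CDE) registry.

A CDE is a registered metadata definition: a name, an informal definition,
a value domain (the set of allowed values), optional units, and a list of
alternative names under which the element is known in other vocabularies —
in particular the tag names of the Association for Pathology Informatics
TMA Data Exchange Specification (TMA DES).

The registry governs data capture throughout the toolkit: every scoring-form
field and every slidemap attribute is bound to a CDE, and values are checked
against the CDE's value domain before being recorded.

The registry serialises to a minimal ISO/IEC 11179-flavoured XML dialect
(``dataElementRegistry``/``dataElement`` elements); see
:func:`serialize_registry` / :func:`parse_registry`.
"""

from __future__ import annotations

import numbers
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from lxml import etree

__all__ = [
    "ValueDomain",
    "CDEDefinition",
    "Registry",
    "ValidationResult",
    "RegistryError",
    "RegistryParseError",
    "load_default_cdes",
    "serialize_registry",
    "parse_registry",
    "validate_value",
]


class RegistryError(ValueError):
    """Raised on registry invariant violations (duplicate ids/names)."""


class RegistryParseError(ValueError):
    """Raised when registry XML is malformed; carries the offending element path."""


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    message: str = ""

    def __bool__(self) -> bool:  # allows ``if validate_value(...)``
        return self.valid


@dataclass(frozen=True)
class ValueDomain:
    """The set of allowed values for a CDE.

    Parameters
    ----------
    kind
        One of ``"enumerated"``, ``"integer-range"``, ``"real-range"``,
        ``"free-text"``.
    values
        For enumerated domains, ``(code, meaning)`` pairs. Codes are the
        permitted values; meanings are human-readable glosses.
    min, max
        Inclusive bounds for range domains.
    step
        Optional step for range domains (values must be ``min + k*step``).
    pattern
        Optional regular expression for free-text domains; matched in full.
    """

    kind: str
    values: tuple[tuple[str, str], ...] = ()
    min: float | None = None
    max: float | None = None
    step: float | None = None
    pattern: str | None = None

    KINDS = ("enumerated", "integer-range", "real-range", "free-text")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise RegistryError(f"unknown value-domain kind {self.kind!r}")
        if self.kind == "enumerated":
            codes = [c for c, _ in self.values]
            if not codes:
                raise RegistryError("enumerated domain needs at least one code")
            if len(set(codes)) != len(codes):
                raise RegistryError("enumerated domain codes must be distinct")
        elif self.kind in ("integer-range", "real-range"):
            if self.min is None or self.max is None:
                raise RegistryError(f"{self.kind} domain needs min and max")
            if self.min > self.max:
                raise RegistryError(
                    f"range domain min {self.min} exceeds max {self.max}"
                )

    @staticmethod
    def enumerated(*values: tuple[str, str] | str) -> "ValueDomain":
        pairs = tuple(
            (v, "") if isinstance(v, str) else (v[0], v[1]) for v in values
        )
        return ValueDomain(kind="enumerated", values=pairs)

    @staticmethod
    def integer_range(lo: int, hi: int, step: int | None = None) -> "ValueDomain":
        return ValueDomain(kind="integer-range", min=lo, max=hi, step=step)

    @staticmethod
    def real_range(lo: float, hi: float) -> "ValueDomain":
        return ValueDomain(kind="real-range", min=lo, max=hi)

    @staticmethod
    def free_text(pattern: str | None = None) -> "ValueDomain":
        return ValueDomain(kind="free-text", pattern=pattern)

    def contains(self, value) -> ValidationResult:
        """Membership test with an explanatory message on failure."""
        if self.kind == "enumerated":
            codes = [c for c, _ in self.values]
            if str(value) in codes:
                return ValidationResult(True)
            return ValidationResult(
                False, f"value {value!r} not one of {{{', '.join(codes)}}}"
            )
        if self.kind == "integer-range":
            if isinstance(value, bool) or not isinstance(value, numbers.Real):
                return ValidationResult(False, f"value {value!r} is not numeric")
            if float(value) != int(value):
                return ValidationResult(False, f"value {value!r} is not an integer")
            v = int(value)
            if not (self.min <= v <= self.max):
                return ValidationResult(
                    False,
                    f"value {v} outside integer range "
                    f"[{int(self.min)}, {int(self.max)}]",
                )
            if self.step and (v - int(self.min)) % int(self.step) != 0:
                return ValidationResult(
                    False, f"value {v} not aligned to step {self.step}"
                )
            return ValidationResult(True)
        if self.kind == "real-range":
            if isinstance(value, bool) or not isinstance(value, numbers.Real):
                return ValidationResult(False, f"value {value!r} is not numeric")
            v = float(value)
            if not (self.min <= v <= self.max):
                return ValidationResult(
                    False, f"value {v} outside range [{self.min}, {self.max}]"
                )
            return ValidationResult(True)
        # free-text
        if not isinstance(value, str):
            return ValidationResult(False, f"value {value!r} is not text")
        if self.pattern is not None and re.fullmatch(self.pattern, value) is None:
            return ValidationResult(
                False, f"value {value!r} does not match pattern {self.pattern!r}"
            )
        return ValidationResult(True)


@dataclass(frozen=True)
class CDEDefinition:
    """A single Common Data Element."""

    identifier: str
    name: str
    definition: str
    value_domain: ValueDomain
    units: str = ""
    alternative_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.identifier:
            raise RegistryError("CDE identifier must be non-empty")
        if not self.name:
            raise RegistryError("CDE name must be non-empty")
        if len(set(self.alternative_names)) != len(self.alternative_names):
            raise RegistryError(
                f"CDE {self.identifier!r} repeats an alternative name"
            )


def validate_value(cde: CDEDefinition, value) -> ValidationResult:
    """Check ``value`` against the CDE's value domain.

    Invalid values are a *result*, not an exception: drop-down style
    constraint checking reports why a value was rejected.
    """
    result = cde.value_domain.contains(value)
    if result.valid:
        return result
    return ValidationResult(False, f"{cde.name}: {result.message}")


class Registry:
    """A collection of CDEs with identifier, name and alternative-name indices.

    Lookups are case-sensitive and exact-match. Names and alternative names
    must be unique across the whole registry so that a lookup by any known
    name resolves to exactly one element.
    """

    def __init__(self, cdes: Sequence[CDEDefinition] = ()) -> None:
        self._by_id: dict[str, CDEDefinition] = {}
        self._by_name: dict[str, CDEDefinition] = {}
        self._by_alt: dict[str, CDEDefinition] = {}
        for cde in cdes:
            self.register(cde)

    def register(self, cde: CDEDefinition) -> "Registry":
        if cde.identifier in self._by_id:
            raise RegistryError(f"duplicate CDE identifier {cde.identifier!r}")
        if cde.name in self._by_name or cde.name in self._by_alt:
            raise RegistryError(f"duplicate CDE name {cde.name!r}")
        for alt in cde.alternative_names:
            if alt in self._by_alt or alt in self._by_name:
                raise RegistryError(f"duplicate alternative name {alt!r}")
        self._by_id[cde.identifier] = cde
        self._by_name[cde.name] = cde
        for alt in cde.alternative_names:
            self._by_alt[alt] = cde
        return self

    def get(self, identifier: str) -> CDEDefinition:
        try:
            return self._by_id[identifier]
        except KeyError:
            raise KeyError(f"no CDE with identifier {identifier!r}") from None

    def lookup(self, name: str) -> CDEDefinition:
        """Resolve by canonical name or any alternative name."""
        if name in self._by_name:
            return self._by_name[name]
        if name in self._by_alt:
            return self._by_alt[name]
        raise KeyError(f"no CDE named {name!r}")

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[CDEDefinition]:
        return iter(self._by_id.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self._by_id == other._by_id


# ---------------------------------------------------------------------------
# Default CDE set
# ---------------------------------------------------------------------------

def _cde(identifier, name, definition, domain, units="", alts=()):
    return CDEDefinition(
        identifier=identifier,
        name=name,
        definition=definition,
        value_domain=domain,
        units=units,
        alternative_names=tuple(alts),
    )


# Identifiers are stable slugs; alternative names carry the TMA DES tag name
# where the exchange specification defines an equivalent element.
_DEFAULT_CDES = (
    _cde(
        "donor-tissue-block-identifier",
        "Donor Tissue Block Identifier",
        "Identifier of the donor tissue block from which a core was punched; "
        "links a core back to the patient's tissue block without storing "
        "patient details.",
        ValueDomain.free_text(),
        alts=("core_histo-repository_donor-block",),
    ),
    _cde(
        "tma-recipient-block-identifier",
        "Tissue Microarray Recipient Block Identifier",
        "Identifier of the recipient paraffin block into which donor cores "
        "are arrayed.",
        ValueDomain.free_text(),
        alts=("block_identifier",),
    ),
    _cde(
        "tma-recipient-block-core-diameter",
        "Tissue Microarray Recipient Block Core Diameter",
        "Diameter of the cylindrical cores in the recipient block.",
        ValueDomain.real_range(0.05, 10.0),
        units="mm",
        alts=("block_core_size",),
    ),
    _cde(
        "tma-recipient-block-core-spacing",
        "Tissue Microarray Recipient Block Core Spacing",
        "Centre-to-centre spacing between adjacent cores in the recipient "
        "block.",
        ValueDomain.real_range(0.05, 20.0),
        units="mm",
        alts=("block_core_spacing",),
    ),
    _cde(
        "tma-recipient-block-core-position-used",
        "Tissue Microarray Recipient Block Core Position Used",
        "Whether a core has been inserted at a grid position; false marks a "
        "gap in the recipient block.",
        ValueDomain.enumerated(("true", "core present"), ("false", "gap")),
    ),
    _cde(
        "tma-recipient-block-slice-number",
        "Tissue Microarray Recipient Block Slice Number",
        "Serial section number of the slice cut from the recipient block; "
        "adjacent slice numbers indicate physically adjacent core images.",
        ValueDomain.integer_range(1, 10000),
    ),
    _cde(
        "tma-recipient-block-x-coordinate",
        "Tissue Microarray Recipient Block x coordinate",
        "1-based column index of a core position in the block array.",
        ValueDomain.integer_range(1, 10000),
    ),
    _cde(
        "tma-recipient-block-y-coordinate",
        "Tissue Microarray Recipient Block y coordinate",
        "1-based row index of a core position in the block array.",
        ValueDomain.integer_range(1, 10000),
    ),
    _cde(
        "tma-slide-identifier",
        "Tissue Microarray Slide Identifier",
        "Identifier of a stained slide sectioned from a recipient block.",
        ValueDomain.free_text(),
        alts=("slide_identifier",),
    ),
    _cde(
        "tma-core-element-identifier",
        "Tissue Microarray Core Element Identifier",
        "Unique identifier of a core within a recipient block.",
        ValueDomain.free_text(),
    ),
    _cde(
        "allred-intensity-score",
        "Allred Intensity Score",
        "Allred staining-intensity component: 0 none, 1 weak, 2 intermediate, "
        "3 strong.",
        ValueDomain.integer_range(0, 3),
    ),
    _cde(
        "allred-proportion-score",
        "Allred Proportion Score",
        "Allred stained-proportion component: 0 none, 1 <1%, 2 1-10%, "
        "3 11-33%, 4 34-66%, 5 >66% of cells stained.",
        ValueDomain.integer_range(0, 5),
    ),
    _cde(
        "allred-score-er-status",
        "Allred Score for ER status",
        "Composite Allred score (intensity + proportion); 0 or 2-8. Totals "
        "of 3 and above are read as oestrogen-receptor positive.",
        ValueDomain.integer_range(0, 8),
    ),
    _cde(
        "percentage-tissue-staining",
        "Percentage tissue staining",
        "Percentage of the tissue area positively stained.",
        ValueDomain.real_range(0.0, 100.0),
        units="percent",
        alts=("core_results_percent-tissue-staining",),
    ),
    _cde(
        "her2-status-ihc",
        "HER2 status by immunohistochemistry",
        "HER2 immunohistochemistry category.",
        ValueDomain.enumerated(
            ("0", "negative"),
            ("1+", "negative, faint staining"),
            ("2+", "equivocal"),
            ("3+", "positive"),
        ),
    ),
    _cde(
        "binary-biomarker-staining",
        "Binary biomarker staining result",
        "Binary value indicating whether the tissue stains positively or "
        "negatively for a marker.",
        ValueDomain.enumerated(("positive", ""), ("negative", "")),
    ),
)


def load_default_cdes() -> Registry:
    """Build the built-in registry of 16 TMA CDEs.

    The set covers array layout (block/slide identifiers, core geometry,
    grid coordinates, position-used, slice number) and the common IHC
    scoring systems (Allred components and total, percentage staining,
    HER2 IHC, binary staining). Where the TMA DES exchange specification
    defines an equivalent tag, the tag name is recorded as an alternative
    name.
    """
    return Registry(_DEFAULT_CDES)


# ---------------------------------------------------------------------------
# XML serialisation (project ISO-11179-flavoured dialect)
# ---------------------------------------------------------------------------

def serialize_registry(registry: Registry) -> bytes:
    """Serialise a registry to UTF-8 XML."""
    root = etree.Element("dataElementRegistry")
    for cde in registry:
        el = etree.SubElement(root, "dataElement", identifier=cde.identifier)
        etree.SubElement(el, "name").text = cde.name
        etree.SubElement(el, "definition").text = cde.definition
        vd = etree.SubElement(el, "valueDomain", kind=cde.value_domain.kind)
        d = cde.value_domain
        if d.kind == "enumerated":
            for code, meaning in d.values:
                v = etree.SubElement(vd, "value", code=code)
                if meaning:
                    v.text = meaning
        elif d.kind in ("integer-range", "real-range"):
            vd.set("min", repr(d.min))
            vd.set("max", repr(d.max))
            if d.step is not None:
                vd.set("step", repr(d.step))
        elif d.pattern is not None:
            vd.set("pattern", d.pattern)
        if cde.units:
            etree.SubElement(el, "unit").text = cde.units
        for alt in cde.alternative_names:
            etree.SubElement(el, "alternativeName").text = alt
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _parse_number(text: str, path: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise RegistryParseError(f"{path}: non-numeric bound {text!r}") from None


def parse_registry(xml: bytes | str) -> Registry:
    """Parse registry XML back into a :class:`Registry`.

    Raises :class:`RegistryParseError` naming the element path on malformed
    documents or missing mandatory fields.
    """
    try:
        root = etree.fromstring(xml if isinstance(xml, bytes) else xml.encode())
    except etree.XMLSyntaxError as exc:
        raise RegistryParseError(f"malformed XML: {exc}") from exc
    if root.tag != "dataElementRegistry":
        raise RegistryParseError(
            f"/{root.tag}: expected root element dataElementRegistry"
        )
    cdes = []
    for i, el in enumerate(root.findall("dataElement")):
        path = f"/dataElementRegistry/dataElement[{i + 1}]"
        identifier = el.get("identifier")
        if not identifier:
            raise RegistryParseError(f"{path}: missing identifier attribute")
        name_el = el.find("name")
        if name_el is None or not (name_el.text or "").strip():
            raise RegistryParseError(f"{path}/name: missing or empty")
        vd_el = el.find("valueDomain")
        if vd_el is None:
            raise RegistryParseError(f"{path}/valueDomain: missing")
        kind = vd_el.get("kind")
        if kind not in ValueDomain.KINDS:
            raise RegistryParseError(
                f"{path}/valueDomain: unknown kind {kind!r}"
            )
        if kind == "enumerated":
            values = tuple(
                (v.get("code"), v.text or "") for v in vd_el.findall("value")
            )
            if not values or any(c is None for c, _ in values):
                raise RegistryParseError(
                    f"{path}/valueDomain: enumerated domain needs value "
                    "elements with code attributes"
                )
            domain = ValueDomain(kind="enumerated", values=values)
        elif kind in ("integer-range", "real-range"):
            lo = _parse_number(vd_el.get("min", ""), f"{path}/valueDomain@min")
            hi = _parse_number(vd_el.get("max", ""), f"{path}/valueDomain@max")
            step = vd_el.get("step")
            domain = ValueDomain(
                kind=kind,
                min=lo,
                max=hi,
                step=_parse_number(step, f"{path}/valueDomain@step")
                if step is not None
                else None,
            )
        else:
            domain = ValueDomain(kind="free-text", pattern=vd_el.get("pattern"))
        unit_el = el.find("unit")
        cdes.append(
            CDEDefinition(
                identifier=identifier,
                name=name_el.text,
                definition=(el.findtext("definition") or ""),
                value_domain=domain,
                units=(unit_el.text or "") if unit_el is not None else "",
                alternative_names=tuple(
                    a.text for a in el.findall("alternativeName") if a.text
                ),
            )
        )
    try:
        return Registry(cdes)
    except RegistryError as exc:
        raise RegistryParseError(str(exc)) from exc
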