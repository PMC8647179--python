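"""Machine-readable dictionary model and the compliance validator.

A dictionary declares, per category: its key items, whether the category is
mandatory, and per item a data type, mandatory flag, optionally a controlled
vocabulary or a numeric range, and optionally a parent link to another item
(the child's values must appear among the parent's values).

Dictionary files use a small mmCIF-dialect schema (see
``docs/dictionary-format.md``): a ``_dictionary`` header plus two loops,
``_category_def`` and ``_item_def``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .cif import CifDocument, CifValue, parse_document


class DictionaryError(ValueError):
    """Malformed or inconsistent dictionary definitions."""


@dataclass
class ItemDefinition:
    category: str
    name: str
    type_code: str  # int | float | text | code | yyyy-mm-dd
    mandatory: bool = False
    enumeration: Optional[frozenset[str]] = None
    range_min: Optional[float] = None
    range_max: Optional[float] = None
    min_open: bool = False
    max_open: bool = False
    parent: Optional[tuple[str, str]] = None  # (category, item)
    description: str = ""

    def __post_init__(self):
        if self.type_code not in ("int", "float", "text", "code", "yyyy-mm-dd"):
            raise DictionaryError(
                f"_{self.category}.{self.name}: bad type code {self.type_code!r}"
            )
        has_range = self.range_min is not None or self.range_max is not None
        if self.enumeration is not None and has_range:
            raise DictionaryError(
                f"_{self.category}.{self.name}: enumeration and range are "
                "mutually exclusive"
            )


@dataclass
class CategoryDefinition:
    name: str
    key_items: list[str] = field(default_factory=list)
    mandatory: bool = False
    item_defs: dict[str, ItemDefinition] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.key_items) - set(self.item_defs)
        if missing:
            raise DictionaryError(
                f"category {self.name}: key items {sorted(missing)} undefined"
            )


@dataclass
class DictionaryModel:
    title: str = ""
    version: str = ""
    categories: dict[str, CategoryDefinition] = field(default_factory=dict)

    def item(self, category: str, name: str) -> Optional[ItemDefinition]:
        cat = self.categories.get(category)
        return cat.item_defs.get(name) if cat else None


class FindingKind(str, Enum):
    MISSING_MANDATORY_CATEGORY = "MISSING_MANDATORY_CATEGORY"
    MISSING_MANDATORY_ITEM = "MISSING_MANDATORY_ITEM"
    BAD_TYPE = "BAD_TYPE"
    ENUM_VIOLATION = "ENUM_VIOLATION"
    RANGE_VIOLATION = "RANGE_VIOLATION"
    PARENT_MISSING = "PARENT_MISSING"
    DUPLICATE_KEY = "DUPLICATE_KEY"
    UNKNOWN_CATEGORY = "UNKNOWN_CATEGORY"
    UNKNOWN_ITEM = "UNKNOWN_ITEM"


@dataclass(frozen=True)
class Location:
    block: Optional[str] = None
    category: Optional[str] = None
    item: Optional[str] = None
    row: Optional[int] = None

    def __str__(self) -> str:
        parts = []
        if self.block is not None:
            parts.append(f"block {self.block}")
        if self.category is not None:
            parts.append(f"category {self.category}")
        if self.item is not None:
            parts.append(f"item {self.item}")
        if self.row is not None:
            parts.append(f"row {self.row}")
        return ", ".join(parts) or "(document)"


@dataclass
class Finding:
    severity: str  # error | warning
    kind: FindingKind
    location: Location
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.kind.value} at {self.location}: {self.message}"


@dataclass
class ComplianceReport:
    findings: list[Finding]

    @property
    def counts_by_kind(self) -> dict[str, int]:
        return dict(Counter(f.kind.value for f in self.findings))

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def compliant(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "compliant": self.compliant,
            "counts_by_kind": self.counts_by_kind,
            "findings": [
                {
                    "severity": f.severity,
                    "kind": f.kind.value,
                    "block": f.location.block,
                    "category": f.location.category,
                    "item": f.location.item,
                    "row": f.location.row,
                    "message": f.message,
                }
                for f in self.findings
            ],
        }

    def render_text(self) -> str:
        lines = [
            f"compliant: {'yes' if self.compliant else 'no'}",
            f"findings: {len(self.findings)} "
            f"({len(self.errors)} errors, {len(self.warnings)} warnings)",
        ]
        lines.extend(str(f) for f in self.findings)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Loading


def _cell_text(v: Optional[CifValue]) -> Optional[str]:
    return None if v is None or v.is_sentinel else v.text


def load_dictionary(source: str) -> DictionaryModel:
    """Load a dictionary from its mmCIF-dialect text form."""
    doc = parse_document(source)
    if not doc.blocks:
        return DictionaryModel()
    if len(doc.blocks) != 1:
        raise DictionaryError(
            f"a dictionary must be a single data block, found {len(doc.blocks)}"
        )
    block = doc.sole_block
    model = DictionaryModel()
    head = block.find("dictionary")
    if head:
        row = head.row_dict(0)
        model.title = _cell_text(row.get("title")) or ""
        model.version = _cell_text(row.get("version")) or ""

    raw_items: dict[str, list[ItemDefinition]] = {}
    item_cat = block.find("item_def")
    if item_cat:
        for r in item_cat.iter_dicts():
            cat = _cell_text(r.get("category"))
            name = _cell_text(r.get("name"))
            if not cat or not name:
                raise DictionaryError(
                    "item_def rows need non-empty category and name"
                )
            enum_txt = _cell_text(r.get("enum"))
            parent_cat = _cell_text(r.get("parent_category"))
            parent_item = _cell_text(r.get("parent_item"))
            if (parent_cat is None) != (parent_item is None):
                raise DictionaryError(
                    f"_{cat}.{name}: parent category and item must both be given"
                )

            def num(key):
                t = _cell_text(r.get(key))
                return None if t is None else float(t)

            d = ItemDefinition(
                category=cat,
                name=name,
                type_code=_cell_text(r.get("type_code")) or "text",
                mandatory=(_cell_text(r.get("mandatory")) or "no").lower() == "yes",
                enumeration=(
                    frozenset(x.strip() for x in enum_txt.split(","))
                    if enum_txt else None
                ),
                range_min=num("range_min"),
                range_max=num("range_max"),
                min_open=(_cell_text(r.get("min_open")) or "no").lower() == "yes",
                max_open=(_cell_text(r.get("max_open")) or "no").lower() == "yes",
                parent=(parent_cat, parent_item) if parent_cat else None,
                description=_cell_text(r.get("description")) or "",
            )
            bucket = raw_items.setdefault(cat, [])
            if any(x.name == name for x in bucket):
                raise DictionaryError(f"duplicate definition for _{cat}.{name}")
            bucket.append(d)

    cat_def = block.find("category_def")
    if cat_def:
        for r in cat_def.iter_dicts():
            name = _cell_text(r.get("name"))
            if not name:
                raise DictionaryError("category_def rows need a non-empty name")
            if name in model.categories:
                raise DictionaryError(f"duplicate definition for category {name}")
            keys_txt = _cell_text(r.get("keys"))
            defs = {d.name: d for d in raw_items.pop(name, [])}
            model.categories[name] = CategoryDefinition(
                name=name,
                key_items=keys_txt.split() if keys_txt else [],
                mandatory=(_cell_text(r.get("mandatory")) or "no").lower() == "yes",
                item_defs=defs,
            )
    if raw_items:
        stray = sorted(raw_items)
        raise DictionaryError(f"item definitions for undeclared categories: {stray}")

    for cat in model.categories.values():
        for d in cat.item_defs.values():
            if d.parent is not None:
                pc, pi = d.parent
                if model.item(pc, pi) is None:
                    raise DictionaryError(
                        f"_{d.category}.{d.name}: parent link to undefined "
                        f"item _{pc}.{pi}"
                    )
    return model


# ---------------------------------------------------------------------------
# Validation

_INT_RE = re.compile(r"^[+-]?[0-9]+$")
_FLOAT_RE = re.compile(r"^[+-]?((\d+\.?\d*)|(\.\d+))([eE][+-]?\d+)?$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def check_type(type_code: str, text: str) -> bool:
    """Does a cell's text satisfy the declared data type?

    Integers are pure decimal; floats also accept scientific notation;
    ``code`` values are single whitespace-free tokens; ``text`` is anything.
    """
    if type_code == "int":
        return bool(_INT_RE.match(text))
    if type_code == "float":
        return bool(_FLOAT_RE.match(text))
    if type_code == "yyyy-mm-dd":
        return bool(_DATE_RE.match(text))
    if type_code == "code":
        return bool(text) and not any(c.isspace() for c in text)
    return True  # text


def _check_value(
    d: ItemDefinition, text: str, loc: Location, findings: list[Finding]
) -> None:
    if not check_type(d.type_code, text):
        findings.append(Finding(
            "error", FindingKind.BAD_TYPE, loc,
            f"value {text!r} is not a valid {d.type_code}",
        ))
        return
    if d.enumeration is not None and text not in d.enumeration:
        findings.append(Finding(
            "error", FindingKind.ENUM_VIOLATION, loc,
            f"value {text!r} not in {{{', '.join(sorted(d.enumeration))}}}",
        ))
    if d.range_min is not None or d.range_max is not None:
        try:
            x = float(text)
        except ValueError:
            return  # BAD_TYPE already reported for numeric types
        lo_bad = d.range_min is not None and (
            x < d.range_min or (d.min_open and x == d.range_min)
        )
        hi_bad = d.range_max is not None and (
            x > d.range_max or (d.max_open and x == d.range_max)
        )
        if lo_bad or hi_bad:
            findings.append(Finding(
                "error", FindingKind.RANGE_VIOLATION, loc,
                f"value {x} outside allowed range",
            ))


def validate_document(doc: CifDocument, dictionary: DictionaryModel) -> ComplianceReport:
    """Validate every block of a document against a dictionary.

    All rule classes are checked per row: mandatory categories and items
    (the ``?`` and ``.`` sentinels do not satisfy a mandatory item), data
    types, controlled vocabularies, numeric ranges, parent-child integrity,
    and key uniqueness.  Categories and items absent from the dictionary
    yield warnings, not errors.
    """
    findings: list[Finding] = []
    for block in doc.blocks:
        present = {c.name for c in block.categories}
        for cname, cdef in dictionary.categories.items():
            if cdef.mandatory and cname not in present:
                findings.append(Finding(
                    "error", FindingKind.MISSING_MANDATORY_CATEGORY,
                    Location(block.name, cname),
                    f"mandatory category {cname} is absent",
                ))
        # cache parent value sets per (category, item)
        parent_values: dict[tuple[str, str], set[str]] = {}

        def values_of(cat_name: str, item: str) -> set[str]:
            key = (cat_name, item)
            if key not in parent_values:
                cat = block.find(cat_name)
                vals: set[str] = set()
                if cat and item in cat.item_names:
                    for v in cat.column(item):
                        if not v.is_sentinel:
                            vals.add(v.text)
                parent_values[key] = vals
            return parent_values[key]

        for cat in block.categories:
            cdef = dictionary.categories.get(cat.name)
            if cdef is None:
                findings.append(Finding(
                    "warning", FindingKind.UNKNOWN_CATEGORY,
                    Location(block.name, cat.name),
                    f"category {cat.name} not defined in dictionary",
                ))
                continue
            for item in cat.item_names:
                if item not in cdef.item_defs:
                    findings.append(Finding(
                        "warning", FindingKind.UNKNOWN_ITEM,
                        Location(block.name, cat.name, item),
                        f"item {item} not defined in dictionary",
                    ))
            for iname, d in cdef.item_defs.items():
                if d.mandatory and iname not in cat.item_names:
                    findings.append(Finding(
                        "error", FindingKind.MISSING_MANDATORY_ITEM,
                        Location(block.name, cat.name, iname),
                        f"mandatory item {iname} is absent",
                    ))
            for ridx, row in enumerate(cat.rows):
                for iname, v in zip(cat.item_names, row):
                    d = cdef.item_defs.get(iname)
                    if d is None:
                        continue
                    loc = Location(block.name, cat.name, iname, ridx)
                    if v.is_sentinel:
                        if d.mandatory:
                            findings.append(Finding(
                                "error", FindingKind.MISSING_MANDATORY_ITEM, loc,
                                "mandatory item left "
                                + ("unknown (?)" if v.is_unknown else "inapplicable (.)"),
                            ))
                        continue
                    _check_value(d, v.text, loc, findings)
                    if d.parent is not None:
                        pc, pi = d.parent
                        if v.text not in values_of(pc, pi):
                            findings.append(Finding(
                                "error", FindingKind.PARENT_MISSING, loc,
                                f"value {v.text!r} has no parent in _{pc}.{pi}",
                            ))
            if cdef.key_items and all(k in cat.item_names for k in cdef.key_items):
                seen: dict[tuple, int] = {}
                idxs = [cat.item_names.index(k) for k in cdef.key_items]
                for ridx, row in enumerate(cat.rows):
                    key = tuple(row[i].as_str() for i in idxs)
                    if key in seen:
                        findings.append(Finding(
                            "error", FindingKind.DUPLICATE_KEY,
                            Location(block.name, cat.name, None, ridx),
                            f"key {key} duplicates row {seen[key]}",
                        ))
                    else:
                        seen[key] = ridx
    return ComplianceReport(findings)


def validate_row(
    dictionary: DictionaryModel, category: str, payload: dict[str, Optional[str]]
) -> list[Finding]:
    """Validate one record (a metadata form) against a category's rules.

    Checks mandatory items, types, vocabularies and ranges; parent-child and
    key checks need full-document context and are not applied here.
    """
    findings: list[Finding] = []
    cdef = dictionary.categories.get(category)
    if cdef is None:
        raise DictionaryError(f"unknown category {category!r}")
    for iname, d in cdef.item_defs.items():
        val = payload.get(iname)
        loc = Location(None, category, iname)
        if val is None or val in ("?", "."):
            if d.mandatory:
                findings.append(Finding(
                    "error", FindingKind.MISSING_MANDATORY_ITEM, loc,
                    f"mandatory item {iname} missing",
                ))
            continue
        _check_value(d, str(val), loc, findings)
    for key in payload:
        if key not in cdef.item_defs:
            findings.append(Finding(
                "warning", FindingKind.UNKNOWN_ITEM, Location(None, category, key),
                f"item {key} not defined in dictionary",
            ))
    return findings
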