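"""Lossless reading and writing of PDBx/mmCIF (STAR-subset) files.

This layer is purely syntactic: a file is a sequence of data blocks, each
holding categories of tabular string values.  Two sentinel values of the
format are modelled explicitly: ``?`` (value unknown) and ``.`` (value
inapplicable/absent).  Typing and semantics are the dictionary layer's job.

Supported syntax: ``data_`` blocks, ``_category.item value`` pairs,
``loop_`` constructs, single/double-quoted values, semicolon-fenced
multiline values, and ``#`` comments.  Save frames, ``global_`` and CIF2
constructs are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


class CifSyntaxError(ValueError):
    """Malformed mmCIF input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CifWriteError(ValueError):
    """Value that the mmCIF dialect cannot encode."""


_KIND_TEXT = 0
_KIND_UNKNOWN = 1
_KIND_INAPPLICABLE = 2


class CifValue:
    """A single cell: text content or one of the two format sentinels."""

    __slots__ = ("_kind", "_text")

    def __init__(self, kind: int, text: str = ""):
        self._kind = kind
        self._text = text

    @property
    def is_unknown(self) -> bool:
        return self._kind == _KIND_UNKNOWN

    @property
    def is_inapplicable(self) -> bool:
        return self._kind == _KIND_INAPPLICABLE

    @property
    def is_sentinel(self) -> bool:
        return self._kind != _KIND_TEXT

    @property
    def text(self) -> str:
        if self._kind != _KIND_TEXT:
            raise ValueError("sentinel value has no text content")
        return self._text

    def as_str(self) -> str:
        """Plain-string view: sentinels map to their one-character marker."""
        if self._kind == _KIND_UNKNOWN:
            return "?"
        if self._kind == _KIND_INAPPLICABLE:
            return "."
        return self._text

    def __eq__(self, other) -> bool:
        if not isinstance(other, CifValue):
            return NotImplemented
        return self._kind == other._kind and (
            self._kind != _KIND_TEXT or self._text == other._text
        )

    def __hash__(self) -> int:
        return hash((self._kind, self._text if self._kind == _KIND_TEXT else ""))

    def __repr__(self) -> str:
        if self._kind == _KIND_UNKNOWN:
            return "CifValue(?)"
        if self._kind == _KIND_INAPPLICABLE:
            return "CifValue(.)"
        return f"CifValue({self._text!r})"


UNKNOWN = CifValue(_KIND_UNKNOWN)
INAPPLICABLE = CifValue(_KIND_INAPPLICABLE)


def text_value(s: str) -> CifValue:
    return CifValue(_KIND_TEXT, s)


def value_of(x) -> CifValue:
    """Coerce python objects to cells: None -> ``.``; else str(x) text."""
    if isinstance(x, CifValue):
        return x
    if x is None:
        return INAPPLICABLE
    if isinstance(x, bool):
        return CifValue(_KIND_TEXT, "YES" if x else "NO")
    return CifValue(_KIND_TEXT, str(x))


_NAME_RE = re.compile(r"^[a-z0-9_]+$")


@dataclass
class CifCategory:
    """An ordered table: item (column) names and rows of CifValue."""

    name: str
    item_names: list[str]
    rows: list[list[CifValue]] = field(default_factory=list)

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise ValueError(f"bad category name {self.name!r}")
        if len(set(self.item_names)) != len(self.item_names):
            raise ValueError(f"duplicate item names in category {self.name}")
        for row in self.rows:
            if len(row) != len(self.item_names):
                raise ValueError(
                    f"row width {len(row)} != {len(self.item_names)} in {self.name}"
                )

    def column(self, item: str) -> list[CifValue]:
        i = self.item_names.index(item)
        return [row[i] for row in self.rows]

    def get(self, item: str, row: int) -> Optional[CifValue]:
        try:
            i = self.item_names.index(item)
        except ValueError:
            return None
        return self.rows[row][i]

    def row_dict(self, row: int) -> dict[str, CifValue]:
        return dict(zip(self.item_names, self.rows[row]))

    def iter_dicts(self) -> Iterator[dict[str, CifValue]]:
        for i in range(len(self.rows)):
            yield self.row_dict(i)

    def append(self, row: Iterable) -> None:
        vals = [value_of(v) for v in row]
        if len(vals) != len(self.item_names):
            raise ValueError("row width mismatch")
        self.rows.append(vals)


@dataclass
class CifBlock:
    name: str
    categories: list[CifCategory] = field(default_factory=list)

    def find(self, name: str) -> Optional[CifCategory]:
        for cat in self.categories:
            if cat.name == name:
                return cat
        return None

    def add(self, cat: CifCategory) -> CifCategory:
        if self.find(cat.name) is not None:
            raise ValueError(f"duplicate category {cat.name} in block {self.name}")
        self.categories.append(cat)
        return cat

    def category_names(self) -> list[str]:
        return [c.name for c in self.categories]


@dataclass
class CifDocument:
    blocks: list[CifBlock] = field(default_factory=list)

    def find_block(self, name: str) -> Optional[CifBlock]:
        for b in self.blocks:
            if b.name == name:
                return b
        return None

    @property
    def sole_block(self) -> CifBlock:
        if len(self.blocks) != 1:
            raise ValueError(f"expected one data block, found {len(self.blocks)}")
        return self.blocks[0]


# ---------------------------------------------------------------------------
# Tokenizer

_T_DATA = "DATA"
_T_LOOP = "LOOP"
_T_NAME = "NAME"
_T_VALUE = "VALUE"

_WHITESPACE = " \t\r"


def _tokenize(source: str):
    """Yield (kind, payload, quoted, line_no) tokens from mmCIF text."""
    lines = source.split("\n")
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            # semicolon fence: runs until a line whose first char is ';'
            fence_start = i + 1
            parts = [line[1:]]
            i += 1
            while i < n and not lines[i].startswith(";"):
                parts.append(lines[i])
                i += 1
            if i >= n:
                raise CifSyntaxError("unterminated semicolon fence", fence_start)
            yield (_T_VALUE, "\n".join(parts), True, fence_start)
            # remainder of the closing line after ';' must be empty/comment
            rest = lines[i][1:].strip()
            if rest and not rest.startswith("#"):
                raise CifSyntaxError("text after closing semicolon", i + 1)
            i += 1
            continue
        pos = 0
        length = len(line)
        while pos < length:
            ch = line[pos]
            if ch in _WHITESPACE:
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = _find_closing_quote(line, pos, ch)
                if end is None:
                    raise CifSyntaxError("unterminated quoted value", i + 1)
                yield (_T_VALUE, line[pos + 1 : end], True, i + 1)
                pos = end + 1
                continue
            start = pos
            while pos < length and line[pos] not in _WHITESPACE:
                pos += 1
            tok = line[start:pos]
            low = tok.lower()
            if low.startswith("data_"):
                yield (_T_DATA, tok[5:], False, i + 1)
            elif low == "loop_":
                yield (_T_LOOP, "", False, i + 1)
            elif low.startswith(("save_", "global_", "stop_")):
                raise CifSyntaxError(f"unsupported STAR construct {tok!r}", i + 1)
            elif tok.startswith("_"):
                yield (_T_NAME, tok, False, i + 1)
            else:
                yield (_T_VALUE, tok, False, i + 1)
        i += 1


def _find_closing_quote(line: str, start: int, quote: str) -> Optional[int]:
    # closing quote must be followed by whitespace or end-of-line
    pos = start + 1
    while True:
        end = line.find(quote, pos)
        if end == -1:
            return None
        if end + 1 >= len(line) or line[end + 1] in _WHITESPACE:
            return end
        pos = end + 1


def _make_value(payload: str, quoted: bool) -> CifValue:
    if not quoted:
        if payload == "?":
            return UNKNOWN
        if payload == ".":
            return INAPPLICABLE
    return CifValue(_KIND_TEXT, payload)


def _split_name(tok: str, line: int) -> tuple[str, str]:
    body = tok[1:]
    if "." not in body:
        raise CifSyntaxError(f"item name {tok!r} lacks a category", line)
    cat, item = body.split(".", 1)
    cat = cat.lower()
    item = item.lower()
    if not _NAME_RE.match(cat) or not _NAME_RE.match(item):
        raise CifSyntaxError(f"bad item name {tok!r}", line)
    return cat, item


# ---------------------------------------------------------------------------
# Parser


class _BlockBuilder:
    def __init__(self, name: str, line: int):
        self.block = CifBlock(name)
        # kv categories are materialized as placeholders at first appearance
        # so the category order of the source is preserved exactly
        self.kv: dict[str, tuple[list[str], list[CifValue]]] = {}
        self.line = line

    def add_pair(self, cat: str, item: str, value: CifValue, line: int) -> None:
        if cat not in self.kv:
            if self.block.find(cat) is not None:
                raise CifSyntaxError(
                    f"category {cat} already defined by a loop", line
                )
            self.kv[cat] = ([], [])
            self.block.categories.append(CifCategory(cat, []))
        items, vals = self.kv[cat]
        if item in items:
            raise CifSyntaxError(f"duplicate item _{cat}.{item}", line)
        items.append(item)
        vals.append(value)

    def add_loop(self, cat: str, items: list[str], values: list[CifValue], line: int) -> None:
        if cat in self.kv or self.block.find(cat) is not None:
            raise CifSyntaxError(f"duplicate category {cat}", line)
        ncols = len(items)
        if len(values) % ncols != 0:
            raise CifSyntaxError(
                f"loop over {cat}: {len(values)} values not a multiple of "
                f"{ncols} columns",
                line,
            )
        rows = [values[i : i + ncols] for i in range(0, len(values), ncols)]
        self.block.add(CifCategory(cat, items, rows))

    def finish(self) -> CifBlock:
        for cat, (items, vals) in self.kv.items():
            placeholder = self.block.find(cat)
            placeholder.item_names = items
            placeholder.rows = [vals]
        return self.block


def parse_document(source: str) -> CifDocument:
    """Parse mmCIF text into a CifDocument.

    Raises CifSyntaxError (with line number) on malformed input.
    """
    doc = CifDocument()
    builder: Optional[_BlockBuilder] = None
    tokens = _tokenize(source.replace("\r\n", "\n").replace("\r", "\n"))
    pending = None  # pushed-back token

    def next_token():
        nonlocal pending
        if pending is not None:
            t, pending = pending, None
            return t
        return next(tokens, None)

    while True:
        tok = next_token()
        if tok is None:
            break
        kind, payload, quoted, line = tok
        if kind == _T_DATA:
            if builder is not None:
                doc.blocks.append(builder.finish())
            if not payload:
                raise CifSyntaxError("empty data block name", line)
            if doc.find_block(payload) is not None or (
                builder is not None and builder.block.name == payload
            ):
                raise CifSyntaxError(f"duplicate data block {payload!r}", line)
            builder = _BlockBuilder(payload, line)
        elif kind == _T_NAME:
            if builder is None:
                raise CifSyntaxError("item outside any data block", line)
            cat, item = _split_name(payload, line)
            val_tok = next_token()
            if val_tok is None or val_tok[0] != _T_VALUE:
                raise CifSyntaxError(f"missing value for _{cat}.{item}", line)
            builder.add_pair(cat, item, _make_value(val_tok[1], val_tok[2]), line)
        elif kind == _T_LOOP:
            if builder is None:
                raise CifSyntaxError("loop_ outside any data block", line)
            names: list[tuple[str, str]] = []
            values: list[CifValue] = []
            while True:
                t = next_token()
                if t is None:
                    break
                if t[0] == _T_NAME:
                    if values:
                        pending = t
                        break
                    names.append(_split_name(t[1], t[3]))
                elif t[0] == _T_VALUE:
                    values.append(_make_value(t[1], t[2]))
                else:
                    pending = t
                    break
            if not names:
                raise CifSyntaxError("loop_ with no item names", line)
            if not values:
                raise CifSyntaxError("loop_ with no values", line)
            cats = {c for c, _ in names}
            if len(cats) != 1:
                raise CifSyntaxError(
                    f"loop mixes categories {sorted(cats)}", line
                )
            builder.add_loop(
                names[0][0], [i for _, i in names], values, line
            )
        else:  # bare VALUE
            raise CifSyntaxError(f"unexpected value {payload!r}", line)
    if builder is not None:
        doc.blocks.append(builder.finish())
    return doc


# ---------------------------------------------------------------------------
# Writer

_SPECIAL_LEAD = set("_#$'\";[]")
_RESERVED = ("data_", "loop_", "save_", "global_", "stop_")


def _needs_quoting(s: str) -> bool:
    if s == "" or s in ("?", "."):
        return True
    if s[0] in _SPECIAL_LEAD:
        return True
    if any(c in " \t" for c in s):
        return True
    if s.lower().startswith(_RESERVED):
        return True
    return False


def format_value(v: CifValue) -> str:
    """Render one cell, choosing plain/quoted/fenced form as needed."""
    if v.is_unknown:
        return "?"
    if v.is_inapplicable:
        return "."
    s = v.text
    if "\n" in s or ("'" in s and '"' in s):
        for ln in s.split("\n")[1:]:
            if ln.startswith(";"):
                raise CifWriteError(
                    "value contains a line starting with ';' and cannot be "
                    "semicolon-fenced"
                )
        return f"\n;{s}\n;\n"
    if _needs_quoting(s):
        if "'" not in s:
            return f"'{s}'"
        if '"' not in s:
            return f'"{s}"'
        raise AssertionError("unreachable")  # both-quotes case fenced above
    return s


def write_document(doc: CifDocument) -> str:
    """Serialize a CifDocument; the output always re-parses equal."""
    out: list[str] = []
    for block in doc.blocks:
        out.append(f"data_{block.name}")
        out.append("#")
        for cat in block.categories:
            _write_category(cat, out)
    return "\n".join(out) + ("\n" if out else "")


def _write_category(cat: CifCategory, out: list[str]) -> None:
    if len(cat.rows) == 1:
        width = max(len(f"_{cat.name}.{i}") for i in cat.item_names) + 2
        for item, val in zip(cat.item_names, cat.rows[0]):
            _emit(out, f"_{cat.name}.{item}".ljust(width), val)
    else:
        out.append("loop_")
        for item in cat.item_names:
            out.append(f"_{cat.name}.{item}")
        for row in cat.rows:
            parts: list[str] = []
            for val in row:
                rendered = format_value(val)
                if rendered.startswith("\n"):
                    if parts:
                        out.append(" ".join(parts))
                        parts = []
                    out.extend(rendered.strip("\n").split("\n"))
                else:
                    parts.append(rendered)
            if parts:
                out.append(" ".join(parts))
    out.append("#")


def _emit(out: list[str], prefix: str, val: CifValue) -> None:
    rendered = format_value(val)
    if rendered.startswith("\n"):
        out.append(prefix.rstrip())
        out.extend(rendered.strip("\n").split("\n"))
    else:
        out.append(prefix + rendered)


# ---------------------------------------------------------------------------
# Semantic equality


@dataclass
class EqualityResult:
    equal: bool
    difference: str = ""

    def __bool__(self) -> bool:
        return self.equal


def documents_equal(a: CifDocument, b: CifDocument) -> EqualityResult:
    """Style-insensitive comparison of two documents.

    Ignores quoting, whitespace, comments, item order within a category and
    category order within a block.  Respects block order, row order, and cell
    content including the unknown (?) vs inapplicable (.) distinction.
    """
    if len(a.blocks) != len(b.blocks):
        return EqualityResult(False, f"block count {len(a.blocks)} != {len(b.blocks)}")
    for ab, bb in zip(a.blocks, b.blocks):
        if ab.name != bb.name:
            return EqualityResult(False, f"block name {ab.name!r} != {bb.name!r}")
        a_names = set(ab.category_names())
        b_names = set(bb.category_names())
        if a_names != b_names:
            only = a_names.symmetric_difference(b_names)
            return EqualityResult(
                False, f"block {ab.name}: category set differs on {sorted(only)}"
            )
        for ac in ab.categories:
            bc = bb.find(ac.name)
            assert bc is not None
            res = _categories_equal(ab.name, ac, bc)
            if not res:
                return res
    return EqualityResult(True)


def _categories_equal(block: str, ac: CifCategory, bc: CifCategory) -> EqualityResult:
    where = f"block {block}, category {ac.name}"
    if set(ac.item_names) != set(bc.item_names):
        only = set(ac.item_names).symmetric_difference(bc.item_names)
        return EqualityResult(False, f"{where}: item set differs on {sorted(only)}")
    if len(ac.rows) != len(bc.rows):
        return EqualityResult(
            False, f"{where}: row count {len(ac.rows)} != {len(bc.rows)}"
        )
    order = [bc.item_names.index(i) for i in ac.item_names]
    for r, (arow, brow) in enumerate(zip(ac.rows, bc.rows)):
        for idx, item in enumerate(ac.item_names):
            av, bv = arow[idx], brow[order[idx]]
            if av != bv:
                return EqualityResult(
                    False,
                    f"{where}, item {item}, row {r}: "
                    f"{av!r} != {bv!r}",
                )
    return EqualityResult(True)
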