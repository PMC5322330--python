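"""Typed stream input/output: ARFF and CSV readers, schema handling, sliding windows.

A labeled tabular stream is a :class:`StreamSchema` plus an ordered sequence of
:class:`Instance` objects.  Streams are served to the learning pipeline through
:func:`sliding_windows`, which cuts the sequence into windows of length ``omega``
advanced by step ``m`` — the unit over which per-attribute quartile fences are
computed.

Supported formats are the standard ARFF dialect (``@relation`` / ``@attribute`` /
``@data``, ``?`` for missing, nominal domains in braces) and headered CSV with
inferred column types.  Sparse ARFF, compressed inputs and live sockets are out
of scope.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

__all__ = [
    "SchemaError",
    "RecordError",
    "ConfigError",
    "AttributeSpec",
    "StreamSchema",
    "Instance",
    "Window",
    "read_arff",
    "write_arff",
    "read_csv",
    "sliding_windows",
]


class SchemaError(ValueError):
    """Malformed or unsupported stream declaration (header-level problem)."""


class RecordError(ValueError):
    """A data row that violates the declared schema (row-level problem)."""


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad window size, missing column, ...)."""


NUMERIC = "numeric"
NOMINAL = "nominal"


@dataclass(frozen=True)
class AttributeSpec:
    """Declaration of a single stream attribute.

    ``kind`` is ``"numeric"`` or ``"nominal"``; nominal attributes carry a
    non-empty, duplicate-free tuple of category labels.
    """

    name: str
    kind: str
    categories: Optional[tuple] = None

    def __post_init__(self):
        if self.kind not in (NUMERIC, NOMINAL):
            raise SchemaError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == NOMINAL:
            if not self.categories:
                raise SchemaError(f"nominal attribute {self.name!r} has no categories")
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"nominal attribute {self.name!r} has duplicate categories")
            object.__setattr__(self, "categories", tuple(self.categories))
        elif self.categories is not None:
            raise SchemaError(f"numeric attribute {self.name!r} must not declare categories")

    @property
    def is_numeric(self) -> bool:
        return self.kind == NUMERIC


@dataclass(frozen=True)
class StreamSchema:
    """Ordered predictive attributes plus one nominal class attribute."""

    attributes: tuple
    class_attribute: AttributeSpec

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(self.attributes))
        names = [a.name for a in self.attributes] + [self.class_attribute.name]
        if len(set(names)) != len(names):
            raise SchemaError("attribute names are not unique")
        if self.class_attribute.kind != NOMINAL:
            raise SchemaError("class attribute must be nominal")

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def class_labels(self) -> tuple:
        return self.class_attribute.categories

    @property
    def numeric_indices(self) -> tuple:
        return tuple(i for i, a in enumerate(self.attributes) if a.is_numeric)

    def attribute_index(self, name: str) -> int:
        for i, a in enumerate(self.attributes):
            if a.name == name:
                return i
        raise KeyError(name)


@dataclass
class Instance:
    """One labeled record.

    ``values`` holds one entry per schema attribute (float for numeric, category
    label for nominal, ``None`` for missing).  ``index`` is the 0-based position
    in the stream.  ``truth_outlier`` / ``truth_group`` are ground-truth flags
    carried only by synthetic streams.
    """

    values: tuple
    label: str
    index: int = 0
    truth_outlier: Optional[bool] = None
    truth_group: Optional[bool] = None


@dataclass
class Window:
    """An ordered slice of the stream starting at ``start_index``.

    Normally ``len(instances) <= omega``; a trailing remainder shorter than four
    instances is merged into the last window, which may therefore exceed omega
    by up to three instances.
    """

    instances: list
    start_index: int

    @property
    def length(self) -> int:
        return len(self.instances)


# ---------------------------------------------------------------------------
# ARFF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(
    r"""^@attribute\s+('(?:[^'\\]|\\.)*'|"(?:[^"\\]|\\.)*"|\S+)\s+(.+)$""",
    re.IGNORECASE,
)
_NUMERIC_TYPES = {"numeric", "real", "integer"}


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def _parse_attribute_line(line: str, lineno: int) -> AttributeSpec:
    m = _ATTR_RE.match(line.strip())
    if m is None:
        raise SchemaError(f"line {lineno}: malformed @attribute declaration: {line.strip()!r}")
    name = _unquote(m.group(1))
    decl = m.group(2).strip()
    if decl.startswith("{"):
        if not decl.endswith("}"):
            raise SchemaError(f"line {lineno}: unterminated nominal domain for {name!r}")
        cats = [_unquote(c) for c in decl[1:-1].split(",")]
        cats = [c for c in (c.strip() for c in cats)]
        if not cats or any(c == "" for c in cats):
            raise SchemaError(f"line {lineno}: empty nominal domain for {name!r}")
        return AttributeSpec(name, NOMINAL, tuple(cats))
    if decl.lower() in _NUMERIC_TYPES:
        return AttributeSpec(name, NUMERIC)
    raise SchemaError(f"line {lineno}: unsupported attribute type {decl!r} for {name!r}")


def _parse_value(raw: str, spec: AttributeSpec, row: int):
    v = raw.strip()
    if v == "?" or v == "":
        return None
    if spec.is_numeric:
        try:
            return float(v)
        except ValueError:
            raise RecordError(
                f"row {row}: value {v!r} for numeric attribute {spec.name!r} is not a number"
            ) from None
    v = _unquote(v)
    if v not in spec.categories:
        raise RecordError(
            f"row {row}: value {v!r} outside nominal domain of {spec.name!r} "
            f"{spec.categories}"
        )
    return v


def read_arff(path, class_attribute: Optional[str] = None):
    """Read an ARFF file; return ``(schema, instances)`` with lazy instances.

    The class attribute defaults to the last declared attribute and must be
    nominal.  ``?`` parses as missing.  Header problems raise
    :class:`SchemaError` naming the offending line; bad data rows raise
    :class:`RecordError` naming the data-row number (1-based, counted from
    ``@data``).
    """
    specs = []
    data_start = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("%"):
            continue
        low = stripped.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            specs.append(_parse_attribute_line(stripped, lineno))
            continue
        if low.startswith("@data"):
            data_start = lineno
            break
        raise SchemaError(f"line {lineno}: unexpected content before @data: {stripped!r}")
    if data_start is None:
        raise SchemaError("no @data section found")
    if len(specs) < 2:
        raise SchemaError("ARFF header must declare at least one predictive attribute and a class")

    if class_attribute is None:
        class_idx = len(specs) - 1
    else:
        matches = [i for i, s in enumerate(specs) if s.name == class_attribute]
        if not matches:
            raise ConfigError(f"class attribute {class_attribute!r} not declared")
        class_idx = matches[0]
    class_spec = specs[class_idx]
    if class_spec.kind != NOMINAL:
        raise SchemaError(f"class attribute {class_spec.name!r} must be nominal")
    predictive = [s for i, s in enumerate(specs) if i != class_idx]
    schema = StreamSchema(tuple(predictive), class_spec)

    def _instances() -> Iterator[Instance]:
        row = 0
        idx = 0
        for line in lines[data_start:]:
            stripped = line.strip()
            if not stripped or stripped.startswith("%"):
                continue
            row += 1
            fields = next(csv.reader(io.StringIO(stripped)))
            if len(fields) != len(specs):
                raise RecordError(
                    f"row {row}: expected {len(specs)} values, got {len(fields)}"
                )
            raw_label = fields[class_idx]
            label = _parse_value(raw_label, class_spec, row)
            if label is None:
                raise RecordError(f"row {row}: missing class label")
            values = tuple(
                _parse_value(f, s, row)
                for i, (f, s) in enumerate(zip(fields, specs))
                if i != class_idx
            )
            yield Instance(values=values, label=label, index=idx)
            idx += 1

    return schema, _instances()


def write_arff(path, schema: StreamSchema, instances: Iterable[Instance],
               relation: str = "stream") -> int:
    """Write a stream back out as ARFF (class attribute last). Returns row count."""

    def _decl(spec: AttributeSpec) -> str:
        if spec.is_numeric:
            return f"@attribute {spec.name} numeric"
        return "@attribute %s {%s}" % (spec.name, ",".join(spec.categories))

    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@relation {relation}\n")
        for spec in schema.attributes:
            fh.write(_decl(spec) + "\n")
        fh.write(_decl(schema.class_attribute) + "\n")
        fh.write("@data\n")
        for inst in instances:
            fields = []
            for v, spec in zip(inst.values, schema.attributes):
                if v is None:
                    fields.append("?")
                elif spec.is_numeric:
                    fields.append(repr(float(v)))
                else:
                    fields.append(str(v))
            fields.append(str(inst.label))
            fh.write(",".join(fields) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _is_missing(v: str) -> bool:
    return v.strip() in ("", "?")


def read_csv(path, class_column: Union[str, int], delimiter: str = ","):
    """Read a headered CSV; return ``(schema, instances)``.

    Column types are inferred: a column is numeric iff every non-missing value
    parses as a number, otherwise nominal with categories in order of first
    appearance.  The class column (by name or 0-based index) is always treated
    as nominal.  Type inference requires a full pass, so the file is read
    eagerly; instances are still yielded lazily from memory.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: no header row") from None
        rows = []
        for rowno, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != len(header):
                raise RecordError(
                    f"row {rowno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise SchemaError("no data rows")

    if isinstance(class_column, int):
        if not 0 <= class_column < len(header):
            raise ConfigError(f"class column index {class_column} out of range")
        class_idx = class_column
    else:
        if class_column not in header:
            raise ConfigError(f"class column {class_column!r} not in header {header}")
        class_idx = header.index(class_column)

    def _infer(col: int) -> AttributeSpec:
        name = header[col]
        observed = [r[col] for r in rows if not _is_missing(r[col])]
        if col != class_idx and observed:
            try:
                for v in observed:
                    float(v)
            except ValueError:
                pass
            else:
                return AttributeSpec(name, NUMERIC)
        # nominal: categories in first-appearance order
        cats = []
        seen = set()
        for v in observed:
            v = v.strip()
            if v not in seen:
                seen.add(v)
                cats.append(v)
        if not cats:
            raise SchemaError(f"column {name!r} has no non-missing values")
        return AttributeSpec(name, NOMINAL, tuple(cats))

    specs = [_infer(c) for c in range(len(header))]
    class_spec = specs[class_idx]
    schema = StreamSchema(tuple(s for i, s in enumerate(specs) if i != class_idx), class_spec)

    def _instances() -> Iterator[Instance]:
        for idx, row in enumerate(rows):
            rowno = idx + 1
            raw_label = row[class_idx]
            if _is_missing(raw_label):
                raise RecordError(f"row {rowno}: missing class label")
            label = raw_label.strip()
            values = []
            for i, (v, spec) in enumerate(zip(row, specs)):
                if i == class_idx:
                    continue
                if _is_missing(v):
                    values.append(None)
                elif spec.is_numeric:
                    values.append(float(v))
                else:
                    values.append(v.strip())
            yield Instance(values=tuple(values), label=label, index=idx)

    return schema, _instances()


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def sliding_windows(stream: Iterable[Instance], omega: int, m: Optional[int] = None
                    ) -> Iterator[Window]:
    """Cut a stream into windows of length ``omega`` advanced by step ``m``.

    Window ``k`` covers stream positions ``[k*m, k*m + omega)``.  With
    ``m == omega`` (the default) the windows partition the stream.  At end of
    stream, a remainder contributing at least four new instances is emitted as
    a final short window; a shorter remainder is appended to the last emitted
    window.  Streams shorter than four instances yield nothing (with a warning).
    """
    if m is None:
        m = omega
    if omega < 4:
        raise ConfigError(f"window length omega={omega} must be >= 4 (quartiles need 4 points)")
    if not 1 <= m <= omega:
        raise ConfigError(f"window step m={m} must satisfy 1 <= m <= omega={omega}")

    buf: list = []
    start = 0
    pending: Optional[Window] = None
    for inst in stream:
        buf.append(inst)
        if len(buf) == omega:
            if pending is not None:
                yield pending
            pending = Window(list(buf), start)
            del buf[:m]
            start += m

    overlap = omega - m if pending is not None else 0
    n_new = len(buf) - overlap  # instances not covered by any emitted window
    if pending is None:
        if len(buf) >= 4:
            yield Window(buf, start)
        elif buf:
            warnings.warn(
                f"stream of {len(buf)} instances is shorter than 4; no windows emitted",
                stacklevel=2,
            )
        return
    if n_new <= 0:
        yield pending
        return
    if len(buf) >= 4:
        yield pending
        yield Window(buf, start)
    else:
        # short tail: merge the uncovered remainder into the previous window
        pending = Window(pending.instances + buf[overlap:], pending.start_index)
        yield pending
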