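"""Restricted-YAML metadata serialization.

Metadata (``exdir.yaml``) and attributes (``attributes.yaml``) are stored in a
strict subset of YAML 1.2: only Failsafe/JSON/Core schema types (map, sequence,
string, null, boolean, integer, float), block style only, string *values*
always quoted, no directives, node properties (tags/anchors/aliases), complex
mapping keys, empty keys, or block scalars. Keys are recommended to stay within
``[A-Za-z0-9_-]`` and unquoted.

Writing is strict: :func:`emit_restricted` only ever produces conforming text.
Reading is lenient: :func:`parse_lenient` accepts full YAML (delegating the
tokenizing/parsing to PyYAML's event stream) and reports subset violations as
warnings, never failures. Scalar resolution follows the YAML 1.2 Core schema
(PyYAML's native resolver is 1.1, so plain scalars are resolved here instead).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import yaml

from .exceptions import (
    InvalidDocumentError,
    UnsupportedValueError,
    YamlParseError,
)

__all__ = [
    "YamlViolation",
    "emit_restricted",
    "parse_lenient",
    "check_key_convention",
    "lint_text",
    "RULE_IDS",
]

# Restriction rule identifiers (subset rules), plus the two key-convention
# recommendations and a duplicate-key extension.
RULE_DISALLOWED_TYPE = "disallowed-type"
RULE_DIRECTIVES = "directives"
RULE_NODE_PROPERTIES = "node-properties"
RULE_COMPLEX_KEY = "complex-key"
RULE_PLAIN_STRING = "plain-string"
RULE_FLOW_STYLE = "flow-style"
RULE_EMPTY_KEY = "empty-key"
RULE_BLOCK_SCALAR = "block-scalar"
RULE_KEY_CHARSET = "key-charset"
RULE_QUOTED_KEY = "quoted-key"
RULE_DUPLICATE_KEY = "duplicate-key"

RULE_IDS = (
    RULE_DISALLOWED_TYPE,
    RULE_DIRECTIVES,
    RULE_NODE_PROPERTIES,
    RULE_COMPLEX_KEY,
    RULE_PLAIN_STRING,
    RULE_FLOW_STYLE,
    RULE_EMPTY_KEY,
    RULE_BLOCK_SCALAR,
    RULE_KEY_CHARSET,
    RULE_QUOTED_KEY,
    RULE_DUPLICATE_KEY,
)


@dataclass(frozen=True)
class YamlViolation:
    """A subset or key-convention violation found while reading or writing.

    Violations are always warnings: lenient reading still returns a document.
    """

    rule_id: str
    line: int
    message: str
    severity: str = "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: [{self.rule_id}] {self.message}"


_KEY_CONVENTION_RE = re.compile(r"^[A-Za-z0-9_-]+$")


def check_key_convention(key: str) -> bool:
    """True iff *key* is nonempty and only uses ASCII letters, digits, ``_``, ``-``."""
    return isinstance(key, str) and bool(_KEY_CONVENTION_RE.match(key))


# ---------------------------------------------------------------------------
# YAML 1.2 Core schema scalar resolution (for plain-style scalars).
# ---------------------------------------------------------------------------

_CORE_NULL_RE = re.compile(r"^(?:~|null|Null|NULL|)$")
_CORE_BOOL_RE = re.compile(r"^(?:true|True|TRUE|false|False|FALSE)$")
_CORE_INT_RE = re.compile(r"^(?:[-+]?[0-9]+|0o[0-7]+|0x[0-9a-fA-F]+)$")
_CORE_FLOAT_RE = re.compile(
    r"^(?:[-+]?(?:\.[0-9]+|[0-9]+(?:\.[0-9]*)?)(?:[eE][-+]?[0-9]+)?"
    r"|[-+]?\.(?:inf|Inf|INF)"
    r"|\.(?:nan|NaN|NAN))$"
)


def resolve_core_scalar(text: str) -> Any:
    """Resolve a plain-style scalar per the YAML 1.2 Core schema."""
    if _CORE_NULL_RE.match(text):
        return None
    if _CORE_BOOL_RE.match(text):
        return text.lower() == "true"
    if _CORE_INT_RE.match(text):
        if text.startswith("0o"):
            return int(text[2:], 8)
        if text.startswith("0x"):
            return int(text[2:], 16)
        return int(text)
    if _CORE_FLOAT_RE.match(text):
        lowered = text.lower()
        if lowered.endswith(".inf"):
            return -math.inf if lowered.startswith("-") else math.inf
        if lowered.endswith(".nan"):
            return math.nan
        return float(text)
    return text


# Tags PyYAML's resolver may attach that are fine (Failsafe/JSON/Core).
_CORE_TAGS = {
    "tag:yaml.org,2002:str",
    "tag:yaml.org,2002:int",
    "tag:yaml.org,2002:float",
    "tag:yaml.org,2002:bool",
    "tag:yaml.org,2002:null",
    "tag:yaml.org,2002:map",
    "tag:yaml.org,2002:seq",
}


# ---------------------------------------------------------------------------
# Emitter
# ---------------------------------------------------------------------------

def _coerce_scalar(value: Any) -> Any:
    """Normalize numpy scalar types to the corresponding Python kinds."""
    if isinstance(value, np.generic):
        return value.item()
    return value


def _is_scalar(value: Any) -> bool:
    value = _coerce_scalar(value)
    return value is None or isinstance(value, (str, bool, int, float))


def _format_float(x: float) -> str:
    if math.isnan(x):
        return ".nan"
    if math.isinf(x):
        return ".inf" if x > 0 else "-.inf"
    # repr gives the shortest round-trip decimal; it always contains '.' or
    # an exponent, so the Core schema re-reads it as a float (kind preserved).
    return repr(x)


def _format_scalar(value: Any) -> str:
    value = _coerce_scalar(value)
    if value is None:
        return "null"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return _format_float(value)
    if isinstance(value, str):
        # String values are always quoted (plain style is a violation).
        # JSON string escaping is a valid YAML double-quoted scalar.
        return json.dumps(value, ensure_ascii=False)
    raise UnsupportedValueError(
        f"value of type {type(value).__name__} is not representable "
        "in restricted YAML (allowed: map, sequence, string, null, "
        "boolean, integer, float)"
    )


def _format_key(key: Any, violations: list[YamlViolation] | None, line: int) -> str:
    if isinstance(key, np.str_):
        key = str(key)
    if not isinstance(key, str):
        raise UnsupportedValueError(
            f"mapping keys must be strings, got {type(key).__name__}"
        )
    if check_key_convention(key) and not _resolves_to_non_string(key):
        return key
    if violations is not None:
        violations.append(
            YamlViolation(
                RULE_KEY_CHARSET,
                line,
                f"key {key!r} uses characters outside [A-Za-z0-9_-]; "
                "emitted quoted",
            )
        )
    return json.dumps(key, ensure_ascii=False)


def _resolves_to_non_string(text: str) -> bool:
    """Keys whose plain form the Core schema would read as non-string."""
    return not isinstance(resolve_core_scalar(text), str)


def _emit_container(value: Any, indent: str, violations: list[YamlViolation] | None,
                    line_counter: list[int]) -> list[str]:
    lines: list[str] = []
    if isinstance(value, Mapping):
        if len(value) == 0:
            raise UnsupportedValueError(
                "empty maps are not representable in the restricted subset "
                "(flow style '{}' is forbidden)"
            )
        for k, v in value.items():
            line_counter[0] += 1
            key = _format_key(k, violations, line_counter[0])
            if _is_scalar(v):
                lines.append(f"{indent}{key}: {_format_scalar(v)}")
            else:
                _check_container(v)
                lines.append(f"{indent}{key}:")
                lines.extend(_emit_container(v, indent + "  ", violations, line_counter))
    elif isinstance(value, Sequence) and not isinstance(value, (str, bytes)):
        if len(value) == 0:
            raise UnsupportedValueError(
                "empty sequences are not representable in the restricted "
                "subset (flow style '[]' is forbidden)"
            )
        for item in value:
            line_counter[0] += 1
            if _is_scalar(item):
                lines.append(f"{indent}- {_format_scalar(item)}")
            else:
                _check_container(item)
                sub = _emit_container(item, "", violations, line_counter)
                lines.append(f"{indent}- {sub[0]}")
                lines.extend(f"{indent}  {s}" for s in sub[1:])
    else:
        raise UnsupportedValueError(
            f"cannot serialize value of type {type(value).__name__}"
        )
    return lines


def _check_container(value: Any) -> None:
    if isinstance(value, np.ndarray):
        raise UnsupportedValueError(
            "numpy arrays are not directly representable as attributes; "
            "convert to a list (or store as a dataset)"
        )
    if not isinstance(value, (Mapping, Sequence)) or isinstance(value, (str, bytes)):
        raise UnsupportedValueError(
            f"cannot serialize value of type {type(value).__name__}"
        )


def emit_restricted(document: Mapping[str, Any],
                    violations: list[YamlViolation] | None = None) -> str:
    """Serialize *document* to restricted-subset YAML text.

    The output is block style, values quoted where required, deterministic
    (insertion order of the document, 2-space indentation). Key-convention
    violations are appended to *violations* when given; they never fail the
    write. Raises :class:`UnsupportedValueError` for values outside the seven
    allowed kinds and for empty containers (not representable without flow
    style).
    """
    if not isinstance(document, Mapping):
        raise InvalidDocumentError("top-level attribute document must be a map")
    if len(document) == 0:
        return ""
    lines = _emit_container(document, "", violations, [0])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Lenient parser
# ---------------------------------------------------------------------------

def _iter_events(text: str) -> Iterator[yaml.Event]:
    return yaml.parse(text, Loader=yaml.SafeLoader)


class _EventStream:
    def __init__(self, events: Iterator[yaml.Event]):
        self._it = iter(events)

    def next(self) -> yaml.Event:
        return next(self._it)


def parse_lenient(text: str) -> tuple[dict[str, Any], list[YamlViolation]]:
    """Parse YAML *text* accepting the full language, collecting violations.

    Returns ``(document, violations)``. The document is a plain dict; plain
    scalars are resolved with the YAML 1.2 Core schema. Subset violations
    (flow style, plain-style strings, block scalars, node properties,
    directives, complex/empty keys, key-convention breaches, duplicate keys)
    are reported as warnings and never abort the read. Empty text yields an
    empty document. A non-map top level raises
    :class:`InvalidDocumentError`; malformed YAML raises
    :class:`YamlParseError` with line/column.
    """
    violations: list[YamlViolation] = []
    anchors: dict[str, Any] = {}

    try:
        events = list(_iter_events(text))
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        raise YamlParseError(
            str(exc),
            line=None if mark is None else mark.line + 1,
            column=None if mark is None else mark.column + 1,
        ) from exc
    except yaml.YAMLError as exc:  # pragma: no cover - unmarked errors are rare
        raise YamlParseError(str(exc)) from exc

    stream = _EventStream(iter(events))
    ev = stream.next()
    assert isinstance(ev, yaml.StreamStartEvent)
    ev = stream.next()
    if isinstance(ev, yaml.StreamEndEvent):
        return {}, violations
    assert isinstance(ev, yaml.DocumentStartEvent)
    if ev.version is not None or ev.tags:
        violations.append(
            YamlViolation(
                RULE_DIRECTIVES,
                ev.start_mark.line + 1,
                "directives (%YAML / %TAG) must not be used",
            )
        )

    ev = stream.next()
    if isinstance(ev, yaml.ScalarEvent) and ev.style is None and ev.value == "":
        # empty document body ("---" alone or whitespace)
        root: Any = {}
    else:
        root = _build_node(ev, stream, violations, anchors, is_key=False)

    # consume DocumentEnd / StreamEnd; more documents -> invalid
    ev = stream.next()
    assert isinstance(ev, yaml.DocumentEndEvent)
    ev = stream.next()
    if not isinstance(ev, yaml.StreamEndEvent):
        raise InvalidDocumentError("multiple YAML documents are not supported")

    if root is None:
        root = {}
    if not isinstance(root, dict):
        raise InvalidDocumentError(
            f"top-level value must be a map, got {type(root).__name__}"
        )
    return root, violations


def _check_node_properties(ev: yaml.Event, violations: list[YamlViolation]) -> None:
    line = ev.start_mark.line + 1
    anchor = getattr(ev, "anchor", None)
    tag = getattr(ev, "tag", None)
    if anchor is not None:
        violations.append(
            YamlViolation(RULE_NODE_PROPERTIES, line,
                          f"anchors must not be used (&{anchor})")
        )
    if tag is not None:
        violations.append(
            YamlViolation(RULE_NODE_PROPERTIES, line,
                          f"explicit tags must not be used ({tag})")
        )
        if tag not in _CORE_TAGS:
            violations.append(
                YamlViolation(RULE_DISALLOWED_TYPE, line,
                              f"tag outside the Failsafe/JSON/Core schemas: {tag}")
            )


def _build_node(ev: yaml.Event, stream: _EventStream,
                violations: list[YamlViolation], anchors: dict[str, Any],
                is_key: bool) -> Any:
    line = ev.start_mark.line + 1

    if isinstance(ev, yaml.AliasEvent):
        violations.append(
            YamlViolation(RULE_NODE_PROPERTIES, line,
                          f"aliases must not be used (*{ev.anchor})")
        )
        if ev.anchor in anchors:
            return anchors[ev.anchor]
        return None

    _check_node_properties(ev, violations)

    if isinstance(ev, yaml.ScalarEvent):
        value = _resolve_scalar_event(ev, violations, is_key=is_key)
        if ev.anchor:
            anchors[ev.anchor] = value
        return value

    if isinstance(ev, yaml.SequenceStartEvent):
        if ev.flow_style:
            violations.append(
                YamlViolation(RULE_FLOW_STYLE, line,
                              "flow style must not be used for sequences")
            )
        items = []
        nxt = stream.next()
        while not isinstance(nxt, yaml.SequenceEndEvent):
            items.append(_build_node(nxt, stream, violations, anchors, is_key=False))
            nxt = stream.next()
        if ev.anchor:
            anchors[ev.anchor] = items
        return items

    if isinstance(ev, yaml.MappingStartEvent):
        if ev.flow_style:
            violations.append(
                YamlViolation(RULE_FLOW_STYLE, line,
                              "flow style must not be used for maps")
            )
        mapping: dict[str, Any] = {}
        nxt = stream.next()
        while not isinstance(nxt, yaml.MappingEndEvent):
            key_line = nxt.start_mark.line + 1
            key = _build_node(nxt, stream, violations, anchors, is_key=True)
            if isinstance(nxt, (yaml.MappingStartEvent, yaml.SequenceStartEvent)):
                violations.append(
                    YamlViolation(RULE_COMPLEX_KEY, key_line,
                                  "complex mapping keys must not be used")
                )
                key = repr(key)
            if not isinstance(key, str):
                key = "null" if key is None else str(key)
            val_ev = stream.next()
            value = _build_node(val_ev, stream, violations, anchors, is_key=False)
            if key in mapping:
                violations.append(
                    YamlViolation(RULE_DUPLICATE_KEY, key_line,
                                  f"duplicate key {key!r}; last occurrence wins")
                )
            mapping[key] = value
            nxt = stream.next()
        if ev.anchor:
            anchors[ev.anchor] = mapping
        return mapping

    raise YamlParseError(f"unexpected YAML event {type(ev).__name__}")  # pragma: no cover


def _resolve_scalar_event(ev: yaml.ScalarEvent,
                          violations: list[YamlViolation], is_key: bool) -> Any:
    line = ev.start_mark.line + 1
    style = ev.style  # None plain, ' / " quoted, | / > block

    if style in ("|", ">"):
        violations.append(
            YamlViolation(RULE_BLOCK_SCALAR, line,
                          "block scalar styles must not be used")
        )
        return ev.value

    if style in ("'", '"'):
        if is_key and ev.value == "":
            violations.append(
                YamlViolation(RULE_EMPTY_KEY, line, "empty keys must not be used")
            )
        # quoting a key that breaks the charset recommendation is itself the
        # recommended practice, so only conventional keys warn when quoted
        elif is_key and check_key_convention(ev.value) \
                and not _resolves_to_non_string(ev.value):
            violations.append(
                YamlViolation(RULE_QUOTED_KEY, line,
                              f"key {ev.value!r} should not be quoted")
            )
        return ev.value

    # plain style; an explicit core tag (already reported as a node-property
    # violation) still decides the kind on this lenient read
    if ev.tag in _CORE_TAGS:
        kind = ev.tag.rsplit(":", 1)[1]
        if kind == "str":
            return ev.value
        if kind == "null":
            return None
        if kind == "bool":
            return ev.value.lower() in ("true", "yes", "on", "1")
        if kind == "int":
            return int(ev.value, 0)
        if kind == "float":
            return float(resolve_core_scalar(ev.value))
    resolved = resolve_core_scalar(ev.value)
    if is_key:
        if ev.value == "" or resolved is None:
            violations.append(
                YamlViolation(RULE_EMPTY_KEY, line, "empty keys must not be used")
            )
            return ""
        if not check_key_convention(ev.value):
            violations.append(
                YamlViolation(RULE_KEY_CHARSET, line,
                              f"key {ev.value!r} uses characters outside "
                              "[A-Za-z0-9_-]")
            )
        return ev.value  # keys keep their literal text
    if isinstance(resolved, str):
        violations.append(
            YamlViolation(RULE_PLAIN_STRING, line,
                          f"string value {ev.value!r} must be quoted")
        )
    return resolved


def lint_text(text: str) -> list[YamlViolation]:
    """Return the subset violations in *text* (parse errors are raised)."""
    _, violations = parse_lenient(text)
    return violations
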