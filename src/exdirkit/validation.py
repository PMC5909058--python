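"""Object-name acceptance policies.

Object names become directory names, so they must survive a move between
case-sensitive (Linux) and case-insensitive (Windows, macOS) file systems.
The default *thorough* policy rejects a new name that collides
case-insensitively with any existing sibling and restricts the character set;
the *minimal* policy (much faster on big directories) only rejects exact
collisions. A custom policy is any callable ``(parent_directory, name) ->
ValidationResult``.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

__all__ = [
    "ValidationResult",
    "thorough",
    "minimal",
    "resolve_policy",
    "RESERVED_NAMES",
]

#: File names reserved for the format's own bookkeeping.
RESERVED_NAMES = frozenset({"exdir.yaml", "attributes.yaml", "data.npy"})

ValidationPolicy = Callable[[Path, str], "ValidationResult"]


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


ACCEPT = ValidationResult(True)


def _reject(reason: str) -> ValidationResult:
    return ValidationResult(False, reason)


def _basic_reject(name: str) -> ValidationResult | None:
    """Checks every policy applies, even custom ones are wrapped with these."""
    if not isinstance(name, str) or name == "":
        return _reject("name must be a non-empty string")
    if "/" in name or "\x00" in name:
        return _reject("name must not contain '/' or NUL")
    if name in (".", ".."):
        return _reject("'.' and '..' are not valid object names")
    if name in RESERVED_NAMES:
        return _reject(f"{name!r} is a reserved file name")
    return None


_THOROUGH_CHARSET = re.compile(r"^[A-Za-z0-9_\- .]+$")


def thorough(parent_directory: Path | str, name: str) -> ValidationResult:
    """Default policy: charset restriction + case-insensitive uniqueness.

    Rejects a proposed name when any existing entry of the parent directory
    matches it case-insensitively (ASCII folding), so trees created on a
    case-sensitive file system cannot collide after transfer to a
    case-insensitive one.
    """
    basic = _basic_reject(name)
    if basic is not None:
        return basic
    if not _THOROUGH_CHARSET.match(name):
        return _reject(
            f"{name!r} contains characters outside [A-Za-z0-9_- .] "
            "(use minimal or a custom policy to allow them)"
        )
    if name[0] in " ." or name[-1] in " .":
        return _reject(f"{name!r} must not start or end with a space or dot")
    folded = name.lower()
    if folded in (r.lower() for r in RESERVED_NAMES):
        return _reject(f"{name!r} collides with a reserved file name")
    parent_directory = Path(parent_directory)
    for entry in os.listdir(parent_directory):
        if entry.lower() == folded:
            if entry == name:
                return _reject(f"an object named {name!r} already exists")
            return _reject(
                f"{name!r} differs from existing {entry!r} only by case"
            )
    return ACCEPT


def minimal(parent_directory: Path | str, name: str) -> ValidationResult:
    """Fast policy: exact-name collision and reserved names only."""
    basic = _basic_reject(name)
    if basic is not None:
        return basic
    if (Path(parent_directory) / name).exists():
        return _reject(f"an object named {name!r} already exists")
    return ACCEPT


def resolve_policy(spec: str | ValidationPolicy) -> ValidationPolicy:
    """Map ``'thorough'`` / ``'minimal'`` / callable to a policy callable.

    Custom callables are wrapped so the universal rejections (empty names,
    '/', NUL, reserved file names) always apply.
    """
    if spec == "thorough" or spec is thorough:
        return thorough
    if spec == "minimal" or spec is minimal:
        return minimal
    if callable(spec):
        def wrapped(parent_directory: Path | str, name: str) -> ValidationResult:
            basic = _basic_reject(name)
            if basic is not None:
                return basic
            result = spec(parent_directory, name)
            if isinstance(result, ValidationResult):
                return result
            return ACCEPT if result else _reject(f"{name!r} rejected by custom policy")

        return wrapped
    raise ValueError(
        f"name_validation must be 'thorough', 'minimal' or a callable, got {spec!r}"
    )
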