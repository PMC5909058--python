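"""Conformance linter.

Walks an on-disk tree and checks it against the format's structural rules:
the root must declare type ``file``; every group/dataset directory needs a
valid ``exdir.yaml``; datasets need a readable ``data.npy``; sibling names
must not collide case-insensitively; no nested ``file`` objects; no stray
special files. Restricted-YAML subset breaches are reported as warnings only
(lenient-read policy), structural breaches as errors.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

from . import npyio, yamlio
from .core import ATTRIBUTES_FILENAME, META_FILENAME, classify_directory
from .exceptions import (
    CorruptDatasetError,
    InvalidDocumentError,
    NotExdirDirectoryError,
    NotNpyError,
    YamlParseError,
)
from .validation import RESERVED_NAMES

__all__ = ["LintIssue", "LintReport", "lint_tree"]


@dataclass(frozen=True)
class LintIssue:
    path: str          # object path inside the tree ("/" for the root)
    code: str
    message: str
    severity: str      # "error" | "warning"

    def __str__(self) -> str:
        return f"{self.severity.upper():7s} {self.path}: [{self.code}] {self.message}"


@dataclass
class LintReport:
    root: Path
    issues: list[LintIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[LintIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[LintIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, path: str, code: str, message: str, severity: str) -> None:
        self.issues.append(LintIssue(path, code, message, severity))

    def render(self) -> str:
        lines = [str(i) for i in self.issues]
        lines.append(
            f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"
        )
        return "\n".join(lines)


def _lint_yaml_file(report: LintReport, obj_path: str, file_path: Path,
                    require_map: bool = True) -> dict | None:
    try:
        doc, violations = yamlio.parse_lenient(
            file_path.read_text(encoding="utf-8")
        )
    except YamlParseError as exc:
        report.add(obj_path, "yaml-malformed",
                   f"{file_path.name}: {exc}", "error")
        return None
    except InvalidDocumentError as exc:
        report.add(obj_path, "yaml-not-a-map",
                   f"{file_path.name}: {exc}", "error")
        return None
    for v in violations:
        report.add(obj_path, v.rule_id,
                   f"{file_path.name}: {v.message}", "warning")
    return doc


def _lint_meta(report: LintReport, obj_path: str, directory: Path,
               expect_root: bool) -> str | None:
    """Validate exdir.yaml; return the declared type (or None on failure)."""
    meta_path = directory / META_FILENAME
    if not meta_path.is_file():
        if expect_root:
            report.add(obj_path, "missing-meta",
                       f"root directory has no {META_FILENAME}", "error")
            return None
        return "raw"  # absence of exdir.yaml reads as a raw object
    doc = _lint_yaml_file(report, obj_path, meta_path)
    if doc is None:
        return None
    try:
        object_type = classify_directory(directory)
    except NotExdirDirectoryError as exc:
        report.add(obj_path, "bad-type-tag", str(exc), "error")
        return None
    section = doc.get("exdir", {})
    version = section.get("version") if isinstance(section, dict) else None
    if not isinstance(version, int) or version < 1:
        report.add(obj_path, "bad-version",
                   f"format version must be a positive integer, got {version!r}",
                   "error")
    for key in doc:
        if key not in ("exdir", "plugins"):
            report.add(obj_path, "unknown-meta-key",
                       f"unexpected top-level key {key!r} in {META_FILENAME}",
                       "warning")
    if expect_root and object_type != "file":
        report.add(obj_path, "root-not-file",
                   f"root declares type {object_type!r}, expected 'file'",
                   "error")
    elif not expect_root and object_type == "file":
        report.add(obj_path, "nested-file",
                   "a File cannot contain other File objects", "error")
    return object_type


def _lint_case_collisions(report: LintReport, obj_path: str,
                          directory: Path) -> None:
    seen: dict[str, str] = {}
    for entry in sorted(os.listdir(directory)):
        if entry in RESERVED_NAMES or not (directory / entry).is_dir():
            continue
        folded = entry.lower()
        if folded in seen:
            report.add(obj_path, "case-collision",
                       f"{seen[folded]!r} and {entry!r} differ only by case",
                       "error")
        else:
            seen[folded] = entry


def _lint_directory(report: LintReport, directory: Path, obj_path: str,
                    is_root: bool) -> None:
    object_type = _lint_meta(report, obj_path, directory, expect_root=is_root)
    if object_type is None:
        return

    attrs_path = directory / ATTRIBUTES_FILENAME
    if attrs_path.is_file():
        _lint_yaml_file(report, obj_path, attrs_path)

    if object_type in ("file", "group"):
        data_file = directory / npyio.DATA_FILENAME
        if data_file.exists():
            report.add(obj_path, "stray-data-file",
                       "data.npy inside a group directory", "error")
        _lint_case_collisions(report, obj_path, directory)
        for entry in sorted(os.listdir(directory)):
            child = directory / entry
            child_path = obj_path.rstrip("/") + "/" + entry
            if child.is_dir():
                _lint_directory(report, child, child_path, is_root=False)
            elif entry not in (META_FILENAME, ATTRIBUTES_FILENAME):
                report.add(obj_path, "stray-file",
                           f"unexpected file {entry!r} in a group directory",
                           "warning")
    elif object_type == "dataset":
        data_file = directory / npyio.DATA_FILENAME
        if not data_file.is_file():
            report.add(obj_path, "missing-data",
                       "dataset directory has no data.npy", "error")
        else:
            try:
                npyio.open_handle(data_file)
            except NotNpyError as exc:
                report.add(obj_path, "not-npy", str(exc), "error")
            except CorruptDatasetError as exc:
                report.add(obj_path, "corrupt-data", str(exc), "error")
        for entry in sorted(os.listdir(directory)):
            if entry in (META_FILENAME, ATTRIBUTES_FILENAME, npyio.DATA_FILENAME):
                continue
            report.add(obj_path, "stray-file",
                       f"unexpected entry {entry!r} in a dataset directory",
                       "warning")
    # raw: arbitrary content is the point; nothing to check beyond attributes


def lint_tree(root: str | os.PathLike) -> LintReport:
    """Lint the tree rooted at *root*; errors fail, subset breaches warn."""
    root = Path(root)
    report = LintReport(root=root)
    if not root.is_dir():
        report.add("/", "not-a-directory", f"{root} is not a directory", "error")
        return report
    _lint_directory(report, root, "/", is_root=True)
    return report
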