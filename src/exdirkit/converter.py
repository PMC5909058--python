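"""Bidirectional structural conversion between HDF5 files and directory trees.

Groups map to groups, datasets to datasets, attributes to attributes. Both
directions are schema-agnostic and never fail on an unconvertible object:
HDF5 features with no counterpart here (links, references, compound
attributes) are skipped with a reason, and features legal here but not in
HDF5 (nested map attributes, raw directories) are flattened or skipped with a
report entry.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np

from .core import Dataset, File, Group, Raw
from .exceptions import ObjectExistsError
from .validation import thorough

__all__ = ["ConversionReport", "hdf5_to_exdir", "exdir_to_hdf5",
           "flatten_attrs", "unflatten_attrs"]


@dataclass
class ConversionReport:
    """What a conversion did: per-type counts, skipped and lossy objects."""

    objects_converted: dict[str, int] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    lossy: list[tuple[str, str]] = field(default_factory=list)

    def count(self, object_type: str) -> None:
        self.objects_converted[object_type] = (
            self.objects_converted.get(object_type, 0) + 1
        )

    def skip(self, path: str, reason: str) -> None:
        self.skipped.append((path, reason))

    def note_lossy(self, path: str, description: str) -> None:
        self.lossy.append((path, description))

    def render(self) -> str:
        lines = [
            "converted: " + (", ".join(
                f"{n} {t}(s)" for t, n in sorted(self.objects_converted.items())
            ) or "nothing")
        ]
        for path, reason in self.skipped:
            lines.append(f"skipped {path}: {reason}")
        for path, desc in self.lossy:
            lines.append(f"lossy   {path}: {desc}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# attribute value mapping
# ---------------------------------------------------------------------------

def _h5_attr_to_document(value: Any) -> Any:
    """Map an HDF5 attribute value to the allowed attribute kinds."""
    if isinstance(value, bytes):
        return value.decode("utf-8", errors="surrogateescape")
    if isinstance(value, np.generic):
        return _h5_attr_to_document(value.item())
    if isinstance(value, np.ndarray):
        if value.dtype.kind in ("S", "O"):
            return [_h5_attr_to_document(v) for v in value.tolist()]
        return value.tolist()
    if isinstance(value, (bool, int, float, str)) or value is None:
        return value
    raise TypeError(f"unsupported attribute value type {type(value).__name__}")


def flatten_attrs(document: dict[str, Any], prefix: str = "") -> dict[str, Any]:
    """Flatten nested maps to dotted keys; literal dots are escaped as ``\\.``."""
    flat: dict[str, Any] = {}
    for key, value in document.items():
        escaped = key.replace("\\", "\\\\").replace(".", "\\.")
        full = f"{prefix}.{escaped}" if prefix else escaped
        if isinstance(value, dict):
            flat.update(flatten_attrs(value, full))
        else:
            flat[full] = value
    return flat


def _split_dotted(key: str) -> list[str]:
    parts: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(key):
        ch = key[i]
        if ch == "\\" and i + 1 < len(key):
            buf.append(key[i + 1])
            i += 2
        elif ch == ".":
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    parts.append("".join(buf))
    return parts


def unflatten_attrs(flat: dict[str, Any]) -> dict[str, Any]:
    """Inverse of :func:`flatten_attrs` (on keys it produced)."""
    out: dict[str, Any] = {}
    for key, value in flat.items():
        parts = _split_dotted(key)
        node = out
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return out


# ---------------------------------------------------------------------------
# HDF5 -> directory tree
# ---------------------------------------------------------------------------

def hdf5_to_exdir(source_hdf5: str | os.PathLike,
                  target_directory: str | os.PathLike,
                  overwrite: bool = False) -> ConversionReport:
    """Convert an HDF5 file to a directory tree.

    Group-for-group, dataset-for-dataset, attribute-for-attribute; payloads
    are preserved bitwise (same dtype and shape). Soft/external links and
    unconvertible dtypes are skipped with a reason. Names that would fail
    thorough validation are still converted (the target is opened with
    minimal validation) and recorded in the report.
    """
    target = Path(target_directory)
    if target.exists():
        if not overwrite:
            raise ObjectExistsError(f"{target}: already exists")
        mode = "w"
    else:
        mode = "w-"
    report = ConversionReport()
    with h5py.File(source_hdf5, "r") as h5:
        out = File(target, mode=mode, name_validation="minimal")
        report.count("file")
        _copy_attrs_h5_to_exdir(h5, out, "/", report)
        _convert_h5_group(h5, out, report)
    return report


def _copy_attrs_h5_to_exdir(h5obj, exobj, path: str,
                            report: ConversionReport) -> None:
    document: dict[str, Any] = {}
    for key in h5obj.attrs:
        try:
            document[key] = _h5_attr_to_document(h5obj.attrs[key])
        except TypeError as exc:
            report.skip(f"{path}@{key}", f"attribute not convertible: {exc}")
    if document:
        exobj.attrs.update(document)


def _convert_h5_group(h5group, exgroup: Group, report: ConversionReport) -> None:
    for name in h5group:
        h5path = f"{h5group.name.rstrip('/')}/{name}"
        link = h5group.get(name, getlink=True)
        if not isinstance(link, h5py.HardLink):
            report.skip(h5path, "links unsupported")
            continue
        if not thorough(exgroup.directory, name):
            report.note_lossy(
                h5path, "name fails thorough validation; converted as-is"
            )
        item = h5group[name]
        if isinstance(item, h5py.Group):
            child = exgroup.create_group(name)
            report.count("group")
            _copy_attrs_h5_to_exdir(item, child, h5path, report)
            _convert_h5_group(item, child, report)
        elif isinstance(item, h5py.Dataset):
            try:
                data = _h5_dataset_payload(item)
            except TypeError as exc:
                report.skip(h5path, str(exc))
                continue
            child = exgroup.create_dataset(name, data=data)
            report.count("dataset")
            if item.chunks is not None or item.compression is not None:
                report.note_lossy(h5path,
                                  "chunked/compressed layout materialized "
                                  "contiguously")
            _copy_attrs_h5_to_exdir(item, child, h5path, report)
        else:  # pragma: no cover - datatypes, references
            report.skip(h5path, f"unsupported object type {type(item).__name__}")


def _h5_dataset_payload(dataset: h5py.Dataset) -> np.ndarray:
    dtype = dataset.dtype
    if dtype.names is not None:
        raise TypeError("compound dtypes unsupported")
    if h5py.check_string_dtype(dtype):
        raw = dataset.asstr()[()]
        return np.asarray(raw, dtype=str)
    if dtype.kind == "O":
        raise TypeError(f"object dtype {dtype} unsupported")
    return dataset[()]


# ---------------------------------------------------------------------------
# directory tree -> HDF5
# ---------------------------------------------------------------------------

def exdir_to_hdf5(source_directory: str | os.PathLike,
                  target_hdf5: str | os.PathLike,
                  raw_mode: str = "skip",
                  overwrite: bool = False) -> ConversionReport:
    """Convert a directory tree to an HDF5 file.

    Nested map attributes (legal here, not in HDF5) are flattened to dotted
    keys with a report entry. Raw directories are skipped (``raw_mode='skip'``)
    or stored as groups of opaque uint8 datasets, one per file
    (``raw_mode='opaque'``).
    """
    if raw_mode not in ("skip", "opaque"):
        raise ValueError(f"raw_mode must be 'skip' or 'opaque', got {raw_mode!r}")
    target = Path(target_hdf5)
    if target.exists() and not overwrite:
        raise ObjectExistsError(f"{target}: already exists")
    report = ConversionReport()
    source = File(source_directory, mode="r")
    with h5py.File(target, "w") as h5:
        report.count("file")
        _copy_attrs_exdir_to_h5(source, h5, "/", report)
        _convert_exdir_group(source, h5, raw_mode, report)
    return report


def _attr_to_h5_value(value: Any):
    if value is None:
        raise TypeError("null attributes have no HDF5 counterpart")
    if isinstance(value, (bool, int, float, str)):
        return value
    if isinstance(value, list):
        if not value:
            raise TypeError("empty sequences have no HDF5 counterpart")
        if all(isinstance(v, bool) for v in value):
            return np.asarray(value, dtype=bool)
        if all(isinstance(v, (int, float)) and not isinstance(v, bool)
               for v in value):
            return np.asarray(value)
        if all(isinstance(v, str) for v in value):
            return np.asarray(value, dtype=object)
        raise TypeError("mixed or nested sequences have no HDF5 counterpart")
    raise TypeError(f"attribute type {type(value).__name__} not convertible")


def _copy_attrs_exdir_to_h5(exobj, h5obj, path: str,
                            report: ConversionReport) -> None:
    document = exobj.attrs.to_dict()
    if any(isinstance(v, dict) for v in document.values()):
        report.note_lossy(path, "nested attributes flattened to dotted keys")
        document = flatten_attrs(document)
    for key, value in document.items():
        try:
            h5obj.attrs[key] = _attr_to_h5_value(value)
        except TypeError as exc:
            report.skip(f"{path}@{key}", str(exc))


def _convert_exdir_group(exgroup: Group, h5group, raw_mode: str,
                         report: ConversionReport) -> None:
    for name in exgroup:
        child = exgroup[name]
        path = child.name
        if isinstance(child, Dataset):
            payload = child[...]
            if payload.dtype.kind == "U":
                h5group.create_dataset(name, data=payload.astype(object),
                                       dtype=h5py.string_dtype())
                report.note_lossy(path, "fixed-width unicode stored as "
                                        "variable-length HDF5 strings")
            else:
                h5group.create_dataset(name, data=payload)
            report.count("dataset")
            _copy_attrs_exdir_to_h5(child, h5group[name], path, report)
        elif isinstance(child, Raw):
            if raw_mode == "skip":
                report.skip(path, "raw directory (raw_mode=skip)")
                continue
            container = h5group.create_group(name)
            container.attrs["raw"] = True
            for filename in child.filenames():
                file_path = child.directory / filename
                if not file_path.is_file():
                    report.skip(f"{path}/{filename}",
                                "nested raw content not converted")
                    continue
                payload = np.frombuffer(file_path.read_bytes(), dtype=np.uint8)
                container.create_dataset(filename, data=payload)
            report.count("raw")
            report.note_lossy(path, "raw files stored as opaque uint8 datasets")
            _copy_attrs_exdir_to_h5(child, container, path, report)
        elif isinstance(child, Group):
            sub = h5group.create_group(name)
            report.count("group")
            _copy_attrs_exdir_to_h5(child, sub, path, report)
            _convert_exdir_group(child, sub, raw_mode, report)
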