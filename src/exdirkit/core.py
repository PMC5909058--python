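"""The four-object hierarchy: File, Group, Dataset, Raw.

Each object is a directory on disk. File/Group/Dataset directories carry an
``exdir.yaml`` declaring their type and format version; a directory without
one found inside a tree is read as Raw (foreign data dropped in place).
Dataset directories additionally hold the array payload in ``data.npy``, and
any object may carry user attributes in ``attributes.yaml``.

The API follows the h5py idiom: ``create_group`` / ``create_dataset``,
``f["path/to/child"]`` item retrieval with POSIX-style ``/`` separators,
dictionary-style iteration over groups, and an ``attrs`` mapping per object.
Names are case-preserving and lookups are case-exact; whether two names that
differ only by case may coexist is decided by the name-validation policy
fixed when the File is opened.
"""

from __future__ import annotations

import os
import shutil
import tempfile
import warnings
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

from . import npyio, yamlio
from .exceptions import (
    InvalidNameError,
    NotExdirDirectoryError,
    ObjectExistsError,
    ReadOnlyError,
    StaleHandleError,
    TypeMismatchError,
    UnsupportedValueError,
)
from .plugin_interface import (
    DatasetData,
    Handler,
    apply_attribute_read_chain,
    apply_attribute_write_chain,
    apply_read_chain,
    apply_write_chain,
)
from .validation import RESERVED_NAMES, resolve_policy

__all__ = ["File", "Group", "Dataset", "Raw", "Object", "Attribute",
           "META_FILENAME", "ATTRIBUTES_FILENAME", "FORMAT_VERSION"]

META_FILENAME = "exdir.yaml"
ATTRIBUTES_FILENAME = "attributes.yaml"
FORMAT_VERSION = 1

_TYPES = ("file", "group", "dataset", "raw")


# ---------------------------------------------------------------------------
# exdir.yaml helpers
# ---------------------------------------------------------------------------

def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(prefix=".meta-", suffix=".yaml.tmp", dir=path.parent)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as f:
            f.write(text)
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_object_meta(directory: Path, object_type: str,
                      meta_extra: Mapping[str, Any] | None = None) -> None:
    if object_type not in _TYPES:
        raise ValueError(f"unknown object type {object_type!r}")
    doc: dict[str, Any] = {"exdir": {"type": object_type, "version": FORMAT_VERSION}}
    if meta_extra:
        doc.update(meta_extra)
    _atomic_write_text(directory / META_FILENAME, yamlio.emit_restricted(doc))


def read_object_meta(directory: Path) -> dict[str, Any] | None:
    """Parsed ``exdir.yaml`` of *directory*, or None when absent."""
    meta_path = directory / META_FILENAME
    if not meta_path.is_file():
        return None
    text = meta_path.read_text(encoding="utf-8")
    doc, _ = yamlio.parse_lenient(text)
    return doc


def classify_directory(directory: Path) -> str:
    """Object type of *directory*: from its exdir.yaml, or 'raw' if absent."""
    meta = read_object_meta(directory)
    if meta is None:
        return "raw"
    section = meta.get("exdir")
    if not isinstance(section, dict) or "type" not in section:
        raise NotExdirDirectoryError(
            f"{directory}: exdir.yaml lacks an 'exdir: {{type, version}}' section"
        )
    object_type = section["type"]
    if object_type not in _TYPES:
        raise NotExdirDirectoryError(
            f"{directory}: unknown object type {object_type!r} in exdir.yaml"
        )
    return object_type


def _split_path(path: str) -> tuple[bool, list[str]]:
    """Split a POSIX-style object path; returns (absolute, components)."""
    if not isinstance(path, str):
        raise TypeError(f"object paths must be strings, got {type(path).__name__}")
    absolute = path.startswith("/")
    components = [c for c in path.split("/") if c != ""]
    for c in components:
        if c in (".", ".."):
            raise KeyError(f"path component {c!r} is not allowed")
    return absolute, components


# ---------------------------------------------------------------------------
# Attributes
# ---------------------------------------------------------------------------

def _validate_attr_value(value: Any) -> Any:
    """Coerce and check a value tree against the seven allowed kinds."""
    if isinstance(value, np.ndarray):
        if value.dtype.hasobject:
            raise UnsupportedValueError("object-dtype arrays cannot be attributes")
        return _validate_attr_value(value.tolist())
    if isinstance(value, np.generic):
        value = value.item()
    if value is None or isinstance(value, (bool, int, float, str)):
        return value
    if isinstance(value, Mapping):
        out = {}
        for k, v in value.items():
            if isinstance(k, np.str_):
                k = str(k)
            if not isinstance(k, str):
                raise UnsupportedValueError(
                    f"attribute keys must be strings, got {type(k).__name__}"
                )
            out[k] = _validate_attr_value(v)
        return out
    if isinstance(value, (list, tuple)):
        return [_validate_attr_value(v) for v in value]
    raise UnsupportedValueError(
        f"attribute value of type {type(value).__name__} is not supported "
        "(allowed: map, sequence, string, null, boolean, integer, float)"
    )


class Attribute:
    """Dictionary-style view of an object's ``attributes.yaml``.

    Every single-key assignment rewrites the whole file (atomically: the new
    document is serialized to a sibling temporary file and renamed over the
    old one). Assigning a whole dictionary to ``obj.attrs`` therefore batches
    many keys into one write.
    """

    def __init__(self, obj: "Object"):
        self._obj = obj

    @property
    def filename(self) -> Path:
        return self._obj.directory / ATTRIBUTES_FILENAME

    def _load_raw(self) -> dict[str, Any]:
        self._obj._require_live()
        path = self.filename
        if not path.is_file():
            return {}
        doc, violations = yamlio.parse_lenient(path.read_text(encoding="utf-8"))
        for v in violations:
            warnings.warn(f"{path}: {v}", stacklevel=3)
        return doc

    def _store_raw(self, document: dict[str, Any]) -> None:
        self._obj._require_writable()
        if not document:
            try:
                self.filename.unlink()
            except FileNotFoundError:
                pass
            return
        _atomic_write_text(self.filename, yamlio.emit_restricted(document))

    def _decode(self, document: dict[str, Any]) -> dict[str, Any]:
        return apply_attribute_read_chain(self._obj._handlers(), document)

    def to_dict(self) -> dict[str, Any]:
        return self._decode(self._load_raw())

    def __getitem__(self, key: str) -> Any:
        return self.to_dict()[key]

    def __setitem__(self, key: str, value: Any) -> None:
        doc = self._load_raw()
        doc[key] = value
        processed = apply_attribute_write_chain(self._obj._handlers(), doc)
        self._store_raw(_validate_attr_value(processed))

    def __delitem__(self, key: str) -> None:
        doc = self._load_raw()
        del doc[key]
        self._store_raw(doc)

    def update(self, other: Mapping[str, Any]) -> None:
        doc = self._load_raw()
        doc.update(other)
        processed = apply_attribute_write_chain(self._obj._handlers(), doc)
        self._store_raw(_validate_attr_value(processed))

    def replace(self, document: Mapping[str, Any]) -> None:
        """Replace the whole attribute document in a single write."""
        processed = apply_attribute_write_chain(self._obj._handlers(), dict(document))
        self._store_raw(_validate_attr_value(processed))

    def __contains__(self, key: str) -> bool:
        return key in self._load_raw()

    def __iter__(self) -> Iterator[str]:
        return iter(self._load_raw())

    def __len__(self) -> int:
        return len(self._load_raw())

    def keys(self):
        return self._load_raw().keys()

    def items(self):
        return self.to_dict().items()

    def values(self):
        return self.to_dict().values()

    def get(self, key: str, default: Any = None) -> Any:
        return self.to_dict().get(key, default)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Attribute):
            return self.to_dict() == other.to_dict()
        if isinstance(other, Mapping):
            return self.to_dict() == dict(other)
        return NotImplemented

    def __repr__(self) -> str:
        return f"Attribute of {self._obj.name!r}: {self.to_dict()!r}"


# ---------------------------------------------------------------------------
# Objects
# ---------------------------------------------------------------------------

class _FileContext:
    """Per-File state shared by every handle in the hierarchy."""

    def __init__(self, read_only: bool, policy, plugins: Sequence[Handler],
                 on_missing_plugin: str):
        self.read_only = read_only
        self.policy = policy
        self.plugins = list(plugins)
        self.on_missing_plugin = on_missing_plugin


class Object:
    """Handle to one directory of the hierarchy."""

    object_type = "object"

    def __init__(self, root_directory: Path, relative_components: tuple[str, ...],
                 context: _FileContext):
        self.root_directory = Path(root_directory)
        self.relative_components = tuple(relative_components)
        self._context = context

    # -- identity -----------------------------------------------------------

    @property
    def directory(self) -> Path:
        return self.root_directory.joinpath(*self.relative_components)

    @property
    def name(self) -> str:
        return "/" + "/".join(self.relative_components)

    @property
    def basename(self) -> str:
        return self.relative_components[-1] if self.relative_components else "/"

    @property
    def mode(self) -> str:
        return "read_only" if self._context.read_only else "read_write"

    @property
    def parent(self) -> "Group":
        if not self.relative_components:
            return self  # type: ignore[return-value]  # root is its own parent
        return _open_existing(self.root_directory,
                              self.relative_components[:-1], self._context)

    def _handlers(self) -> list[Handler]:
        return self._context.plugins

    # -- liveness / mode ----------------------------------------------------

    def _require_live(self) -> None:
        if not self.directory.is_dir():
            raise StaleHandleError(f"{self.name}: object no longer exists on disk")
        if self.object_type in ("file", "group", "dataset"):
            if not (self.directory / META_FILENAME).is_file():
                raise StaleHandleError(
                    f"{self.name}: {META_FILENAME} vanished; handle is stale"
                )

    def _require_writable(self) -> None:
        self._require_live()
        if self._context.read_only:
            raise ReadOnlyError(f"{self.name}: file opened read-only")

    # -- attributes ---------------------------------------------------------

    @property
    def attrs(self) -> Attribute:
        return Attribute(self)

    @attrs.setter
    def attrs(self, document: Mapping[str, Any]) -> None:
        Attribute(self).replace(document)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Object):
            return NotImplemented
        return (self.root_directory == other.root_directory
                and self.relative_components == other.relative_components)

    def __hash__(self) -> int:
        return hash((self.root_directory, self.relative_components))

    def __repr__(self) -> str:
        return (f"<{type(self).__name__} {self.name!r} "
                f"(root {str(self.root_directory)!r})>")


class Raw(Object):
    """A directory of arbitrary foreign files, annotated like any object."""

    object_type = "raw"

    def _require_live(self) -> None:
        if not self.directory.is_dir():
            raise StaleHandleError(f"{self.name}: object no longer exists on disk")

    def filenames(self) -> list[str]:
        """Names of the foreign files/directories inside this raw object."""
        self._require_live()
        return sorted(e for e in os.listdir(self.directory)
                      if e not in RESERVED_NAMES)


class Dataset(Object):
    """An n-dimensional array stored as ``data.npy``, sliced via memory map."""

    object_type = "dataset"

    def _require_live(self) -> None:
        super()._require_live()
        if not (self.directory / npyio.DATA_FILENAME).is_file():
            raise StaleHandleError(f"{self.name}: data.npy vanished; handle is stale")

    @property
    def data_path(self) -> Path:
        return self.directory / npyio.DATA_FILENAME

    def _handle(self, mode: str = "r") -> npyio.DatasetHandle:
        self._require_live()
        return npyio.open_handle(self.data_path, mode)

    @property
    def shape(self) -> tuple[int, ...]:
        return self._handle().shape

    @property
    def dtype(self) -> np.dtype:
        return self._handle().dtype

    @property
    def size(self) -> int:
        return self._handle().size

    def __len__(self) -> int:
        return len(self._handle())

    def __getitem__(self, selection: Any) -> np.ndarray:
        return self._handle().read_slice(selection)

    def __setitem__(self, selection: Any, values: Any) -> None:
        self._require_writable()
        self._handle("r+").write_slice(selection, values)

    def _plugin_meta(self) -> dict[str, Any]:
        meta = read_object_meta(self.directory) or {}
        return {k: v for k, v in meta.items() if k != "exdir"}

    @property
    def data(self) -> Any:
        """Full payload; plugin ``prepare_read`` hooks reconstruct rich values."""
        raw = self._handle().read_all()
        dd = DatasetData(data=raw, attrs=Attribute(self)._load_raw(),
                         meta=self._plugin_meta())
        return apply_read_chain(self._handlers(), dd,
                                on_missing=self._context.on_missing_plugin)

    @data.setter
    def data(self, value: Any) -> None:
        """Replace the payload entirely (shape/dtype may change)."""
        self._require_writable()
        dd = apply_write_chain(self._handlers(), value)
        npyio.write_array(self.data_path, dd.data)
        write_object_meta(self.directory, "dataset", meta_extra=dd.meta)
        if dd.attrs:
            Attribute(self).update(dd.attrs)


class Group(Object):
    """A container of Groups, Datasets and Raw objects."""

    object_type = "group"

    # -- creation -----------------------------------------------------------

    def _resolve_create_parent(self, name: str) -> tuple["Group", str]:
        """For a multi-component *name*, descend existing ancestors only."""
        absolute, components = _split_path(name)
        if absolute:
            raise InvalidNameError(
                f"creation names must be relative, got {name!r}"
            )
        if not components:
            raise InvalidNameError("empty object name")
        parent: Group = self
        for component in components[:-1]:
            child = parent[component]
            if not isinstance(child, Group):
                raise TypeMismatchError(
                    f"{child.name} is a {child.object_type}, not a group"
                )
            parent = child
        return parent, components[-1]

    def _validated_new_child(self, name: str) -> tuple["Group", Path]:
        self._require_writable()
        parent, leaf = self._resolve_create_parent(name)
        parent._require_writable()
        result = self._context.policy(parent.directory, leaf)
        if not result:
            if "exists" in result.reason or "case" in result.reason:
                raise ObjectExistsError(f"{parent.name}: {result.reason}")
            raise InvalidNameError(f"{parent.name}: {result.reason}")
        target = parent.directory / leaf
        if target.exists():
            raise ObjectExistsError(f"{parent.name}: {leaf!r} already exists")
        return parent, target

    def create_group(self, name: str) -> "Group":
        """Create a child group. Intermediate components must already exist."""
        parent, target = self._validated_new_child(name)
        target.mkdir()
        write_object_meta(target, "group")
        return Group(self.root_directory,
                     parent.relative_components + (target.name,), self._context)

    def require_group(self, name: str) -> "Group":
        """Return the named group, creating it if absent; never overwrites."""
        self._require_live()
        try:
            existing = self[name]
        except KeyError:
            return self.create_group(name)
        if not isinstance(existing, Group):
            raise TypeMismatchError(
                f"{existing.name} exists and is a {existing.object_type}, "
                "not a group"
            )
        return existing

    def create_dataset(self, name: str, shape: tuple[int, ...] | None = None,
                       dtype: Any = None, data: Any = None) -> Dataset:
        """Create a child dataset from ``data``, or zero-filled from ``shape``.

        Exactly one of the two must determine the array: passing both requires
        consistent extents, passing neither is an error. Plugin
        ``prepare_write`` hooks run on ``data`` first; attributes they produce
        are merged into the new object's ``attributes.yaml``.
        """
        if data is None and shape is None:
            raise TypeError(
                "create_dataset needs either data or a shape (+ optional dtype)"
            )
        if data is not None:
            dd = apply_write_chain(self._handlers(), data)
            arr = np.asarray(dd.data, dtype=dtype)
            if shape is not None and tuple(shape) != arr.shape:
                raise ValueError(
                    f"shape {tuple(shape)} is inconsistent with data shape "
                    f"{arr.shape}"
                )
        else:
            dd = DatasetData(data=None)
            arr = np.zeros(tuple(shape), dtype=dtype if dtype is not None
                           else np.float64)
        parent, target = self._validated_new_child(name)
        target.mkdir()
        write_object_meta(target, "dataset", meta_extra=dd.meta)
        npyio.write_array(target / npyio.DATA_FILENAME, arr)
        out = Dataset(self.root_directory,
                      parent.relative_components + (target.name,), self._context)
        if dd.attrs:
            Attribute(out).update(dd.attrs)
        return out

    def create_raw(self, name: str) -> Raw:
        """Create a raw directory for foreign-format files."""
        parent, target = self._validated_new_child(name)
        target.mkdir()
        write_object_meta(target, "raw")
        return Raw(self.root_directory,
                   parent.relative_components + (target.name,), self._context)

    def require_raw(self, name: str) -> Raw:
        self._require_live()
        try:
            existing = self[name]
        except KeyError:
            return self.create_raw(name)
        if not isinstance(existing, Raw):
            raise TypeMismatchError(
                f"{existing.name} exists and is a {existing.object_type}, not raw"
            )
        return existing

    # -- lookup / iteration -------------------------------------------------

    def __getitem__(self, path: str) -> Object:
        self._require_live()
        absolute, components = _split_path(path)
        current: Object
        if absolute:
            current = _open_existing(self.root_directory, (), self._context)
        else:
            current = self
        for component in components:
            if not isinstance(current, Group):
                raise TypeMismatchError(
                    f"{current.name} is a {current.object_type}, not a group; "
                    f"cannot descend into {component!r}"
                )
            child_dir = current.directory / component
            # case-exact lookup: the directory entry must match byte for byte
            if component in RESERVED_NAMES or not child_dir.is_dir() \
                    or component not in os.listdir(current.directory):
                raise KeyError(f"{current.name}: no object named {component!r}")
            current = _open_existing(
                self.root_directory,
                current.relative_components + (component,), self._context
            )
        return current

    def get(self, path: str, default: Any = None) -> Any:
        try:
            return self[path]
        except (KeyError, TypeMismatchError):
            return default

    def __contains__(self, path: str) -> bool:
        if path in ("/", ""):
            return True
        try:
            self[path]
            return True
        except (KeyError, TypeMismatchError, NotExdirDirectoryError):
            return False

    def _child_names(self) -> list[str]:
        self._require_live()
        return sorted(
            entry for entry in os.listdir(self.directory)
            if entry not in RESERVED_NAMES
            and (self.directory / entry).is_dir()
        )

    def __iter__(self) -> Iterator[str]:
        return iter(self._child_names())

    def __len__(self) -> int:
        return len(self._child_names())

    def keys(self) -> list[str]:
        return self._child_names()

    def values(self) -> Iterator[Object]:
        return (self[name] for name in self._child_names())

    def items(self) -> Iterator[tuple[str, Object]]:
        return ((name, self[name]) for name in self._child_names())

    # -- deletion -----------------------------------------------------------

    def __delitem__(self, path: str) -> None:
        """Remove the named child's whole subtree (frees disk space at once)."""
        self._require_writable()
        obj = self[path]  # raises KeyError when absent
        if not obj.relative_components:
            raise InvalidNameError("cannot delete the root object")
        shutil.rmtree(obj.directory)


def _open_existing(root_directory: Path, components: tuple[str, ...],
                   context: _FileContext) -> Object:
    directory = root_directory.joinpath(*components)
    object_type = classify_directory(directory)
    if object_type == "file":
        if components:
            raise TypeMismatchError(
                f"/{'/'.join(components)}: nested directory declares object "
                "type 'file'; a File cannot contain other Files"
            )
        return File._from_open(root_directory, context)
    cls = {"group": Group, "dataset": Dataset, "raw": Raw}[object_type]
    return cls(root_directory, components, context)


class File(Group):
    """Root object of a hierarchy; behaves as a Group in every group operation.

    Open modes follow the h5py convention:

    ====  =======================================================
    r     read-only, must exist
    r+    read-write, must exist
    w     create, truncating any existing tree at the location
    w-/x  create, fail if the location exists
    a     read-write, created if absent (default)
    ====  =======================================================

    ``name_validation`` fixes the naming policy (``"thorough"`` by default,
    ``"minimal"``, or a custom callable) for every object below this root;
    ``plugins`` is an ordered sequence of plugin handlers.
    """

    object_type = "file"

    def __init__(self, directory: str | os.PathLike, mode: str = "a",
                 name_validation: Any = "thorough",
                 plugins: Sequence[Handler] | None = None,
                 on_missing_plugin: str = "error"):
        directory = Path(directory).absolute()
        if mode not in ("r", "r+", "w", "w-", "x", "a"):
            raise ValueError(f"invalid mode {mode!r}")
        policy = resolve_policy(name_validation)
        flat_plugins: list[Handler] = []
        for p in plugins or ():
            if isinstance(p, Handler):
                flat_plugins.append(p)
            else:  # a plugin bundle (e.g. plugins.quantities())
                flat_plugins.extend(p)
        context = _FileContext(read_only=(mode == "r"), policy=policy,
                               plugins=flat_plugins,
                               on_missing_plugin=on_missing_plugin)
        super().__init__(directory, (), context)

        exists = directory.exists()
        if mode in ("r", "r+"):
            if not exists:
                raise FileNotFoundError(f"{directory}: no such directory")
            self._verify_is_file_object()
        elif mode in ("w-", "x"):
            if exists:
                raise ObjectExistsError(f"{directory}: already exists")
            self._create_root()
        elif mode == "w":
            if exists:
                self._verify_is_file_object()  # refuse to truncate foreign dirs
                shutil.rmtree(directory)
            self._create_root()
        else:  # a
            if exists:
                self._verify_is_file_object()
            else:
                self._create_root()

    def _create_root(self) -> None:
        if not self.root_directory.parent.is_dir():
            raise FileNotFoundError(
                f"{self.root_directory.parent}: parent directory does not exist"
            )
        self.root_directory.mkdir()
        write_object_meta(self.root_directory, "file")

    def _verify_is_file_object(self) -> None:
        if not self.root_directory.is_dir():
            raise NotExdirDirectoryError(
                f"{self.root_directory}: exists but is not a directory"
            )
        meta = read_object_meta(self.root_directory)
        if meta is None:
            raise NotExdirDirectoryError(
                f"{self.root_directory}: directory has no {META_FILENAME}; "
                "not an object of this format"
            )
        object_type = classify_directory(self.root_directory)
        if object_type != "file":
            raise TypeMismatchError(
                f"{self.root_directory}: exdir.yaml declares type "
                f"{object_type!r}, expected 'file'"
            )

    @classmethod
    def _from_open(cls, root_directory: Path, context: _FileContext) -> "File":
        obj = cls.__new__(cls)
        Group.__init__(obj, root_directory, (), context)
        return obj

    def close(self) -> None:
        """Provided for h5py parity; all writes are already flushed."""

    def __enter__(self) -> "File":
        return self

    def __exit__(self, *exc_info: Any) -> None:
        self.close()
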