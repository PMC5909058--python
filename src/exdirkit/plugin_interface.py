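"""Plugin hook pipeline.

Plugins transform values on the way to and from disk without changing the
on-disk layout: a dataset handler's ``prepare_write`` turns a rich in-memory
value into NPY-storable data plus extra attributes, and ``prepare_read``
reconstructs the value from what was stored. Handlers are pure — they never
touch the file system; the core does all I/O.

A handler that converts a value records itself in the ``meta`` bookkeeping
map (persisted under the reserved ``plugins`` key of the object's
``exdir.yaml``, keeping user attributes clean), so reading can match the
stored object back to the right handler. Handlers run in ascending
``order_index`` on write and descending on read.
"""

from __future__ import annotations

from typing import Any, Iterable, Sequence

import numpy as np

from .exceptions import MissingPluginError, UnsupportedValueError

__all__ = [
    "DatasetData",
    "Handler",
    "DatasetHandler",
    "AttributeHandler",
    "GroupHandler",
    "FileHandler",
    "apply_write_chain",
    "apply_read_chain",
    "apply_attribute_write_chain",
    "apply_attribute_read_chain",
]

META_PLUGINS_KEY = "plugins"


class DatasetData:
    """The payload a dataset handler sees: ``data``, ``attrs`` and ``meta``.

    ``data`` is the array-like payload, ``attrs`` an attribute-document
    fragment merged into ``attributes.yaml``, and ``meta`` plugin bookkeeping
    persisted in ``exdir.yaml``.
    """

    def __init__(self, data: Any = None, attrs: dict | None = None,
                 meta: dict | None = None):
        self.data = data
        self.attrs = attrs if attrs is not None else {}
        self.meta = meta if meta is not None else {}

    def mark(self, handler: "Handler") -> None:
        """Record that *handler* transformed this payload."""
        entries = self.meta.setdefault(META_PLUGINS_KEY, [])
        if not any(e.get("name") == handler.name for e in entries):
            entries.append({"name": handler.name, "version": handler.version})

    def marked_by(self, name: str) -> bool:
        return any(e.get("name") == name
                   for e in self.meta.get(META_PLUGINS_KEY, []))

    def plugin_names(self) -> list[str]:
        return [e.get("name", "") for e in self.meta.get(META_PLUGINS_KEY, [])]


class Handler:
    """Base plugin handler; subclass the target-specific classes below."""

    target: str = ""

    def __init__(self, name: str, version: int = 1, order_index: int = 0):
        self.name = name
        self.version = version
        self.order_index = order_index

    def prepare_write(self, dataset_data: DatasetData) -> DatasetData:
        return dataset_data

    def prepare_read(self, dataset_data: DatasetData) -> DatasetData:
        return dataset_data


class DatasetHandler(Handler):
    target = "dataset"


class AttributeHandler(Handler):
    """Runs on the whole attribute document per write (matching the
    whole-file rewrite semantics of ``attributes.yaml``)."""

    target = "attribute"


class GroupHandler(Handler):
    """Reserved for future creation hooks; the core currently calls none."""

    target = "group"


class FileHandler(Handler):
    """Reserved for future creation hooks; the core currently calls none."""

    target = "file"


def _select(handlers: Iterable[Handler], target: str, reverse: bool = False
            ) -> list[Handler]:
    chosen = [h for h in handlers if h.target == target]
    return sorted(chosen, key=lambda h: h.order_index, reverse=reverse)


def apply_write_chain(handlers: Sequence[Handler], value: Any) -> DatasetData:
    """Fold *value* through each dataset handler's ``prepare_write``.

    Handlers run in ascending ``order_index``. The terminal ``data`` must be
    NPY-storable; otherwise an :class:`UnsupportedValueError` names the last
    handler that ran.
    """
    dd = value if isinstance(value, DatasetData) else DatasetData(data=value)
    chain = _select(handlers, "dataset")
    last_name = None
    for handler in chain:
        out = handler.prepare_write(dd)
        if out is not None:
            dd = out
        last_name = handler.name
    try:
        arr = np.asarray(dd.data)
        has_object = arr.dtype.hasobject
    except Exception:
        has_object = True
    if has_object:
        where = f" (after plugin {last_name!r})" if last_name else ""
        raise UnsupportedValueError(
            f"dataset value of type {type(dd.data).__name__} is not "
            f"NPY-storable{where}"
        )
    return dd


def apply_read_chain(handlers: Sequence[Handler], dataset_data: DatasetData,
                     on_missing: str = "error") -> Any:
    """Inverse fold: run ``prepare_read`` of the handlers recorded in meta.

    Handlers run in descending ``order_index`` (the reverse of the write
    order). When meta names a plugin that is not registered, raise
    :class:`MissingPluginError` (or warn and return the raw data when
    ``on_missing='warn'``). Returns the final reconstructed ``data``.
    """
    registered = {h.name for h in handlers if h.target == "dataset"}
    missing = [n for n in dataset_data.plugin_names() if n not in registered]
    if missing:
        if on_missing == "warn":
            import warnings

            warnings.warn(
                f"dataset was written with unregistered plugin(s) {missing}; "
                "returning raw stored data",
                stacklevel=2,
            )
            return dataset_data.data
        raise MissingPluginError(
            f"dataset was written with plugin(s) {missing} that are not "
            "registered on this file"
        )
    dd = dataset_data
    for handler in _select(handlers, "dataset", reverse=True):
        out = handler.prepare_read(dd)
        if out is not None:
            dd = out
    return dd.data


def apply_attribute_write_chain(handlers: Sequence[Handler], document: dict) -> dict:
    """Run attribute handlers over the whole document before serialization."""
    dd = DatasetData(data=document)
    for handler in _select(handlers, "attribute"):
        out = handler.prepare_write(dd)
        if out is not None:
            dd = out
    return dd.data


def apply_attribute_read_chain(handlers: Sequence[Handler], document: dict) -> dict:
    dd = DatasetData(data=document)
    for handler in _select(handlers, "attribute", reverse=True):
        out = handler.prepare_read(dd)
        if out is not None:
            dd = out
    return dd.data
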