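"""Builtin plugins.

Currently one: experimental support for physical quantities. A
:class:`Quantity` is a bare magnitude plus a unit symbol (no dimensional
analysis). The dataset handler stores the magnitude in ``data.npy`` and the
unit string as a ``unit`` attribute; the attribute handler maps Quantity
attribute values to ``{unit, magnitude}`` maps and back, which keeps the
on-disk files plain restricted YAML.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .plugin_interface import AttributeHandler, DatasetData, DatasetHandler

__all__ = ["Quantity", "QuantityDatasetHandler", "QuantityAttributeHandler",
           "quantities"]

PLUGIN_NAME = "quantities"


class Quantity:
    """A magnitude with a unit symbol, e.g. ``Quantity(1.5, "s")``."""

    def __init__(self, magnitude: Any, unit: str):
        self.magnitude = magnitude
        self.unit = str(unit)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Quantity):
            return NotImplemented
        return self.unit == other.unit and np.array_equal(
            np.asarray(self.magnitude), np.asarray(other.magnitude)
        )

    def __repr__(self) -> str:
        return f"Quantity({self.magnitude!r}, {self.unit!r})"


class QuantityDatasetHandler(DatasetHandler):
    """Stores Quantity datasets as magnitude payload + ``unit`` attribute."""

    def __init__(self, order_index: int = 0):
        super().__init__(name=PLUGIN_NAME, version=1, order_index=order_index)

    def prepare_write(self, dataset_data: DatasetData) -> DatasetData:
        value = dataset_data.data
        if isinstance(value, Quantity):
            dataset_data.data = np.asarray(value.magnitude)
            dataset_data.attrs["unit"] = value.unit
            dataset_data.mark(self)
        return dataset_data

    def prepare_read(self, dataset_data: DatasetData) -> DatasetData:
        if dataset_data.marked_by(self.name) and "unit" in dataset_data.attrs:
            magnitude = np.asarray(dataset_data.data)
            if magnitude.ndim == 0:
                magnitude = magnitude.item()
            dataset_data.data = Quantity(magnitude, dataset_data.attrs["unit"])
        return dataset_data


class QuantityAttributeHandler(AttributeHandler):
    """Maps Quantity attribute values to ``{unit, magnitude}`` maps."""

    def __init__(self, order_index: int = 0):
        super().__init__(name=PLUGIN_NAME, version=1, order_index=order_index)

    def prepare_write(self, dataset_data: DatasetData) -> DatasetData:
        dataset_data.data = self._encode(dataset_data.data)
        return dataset_data

    def prepare_read(self, dataset_data: DatasetData) -> DatasetData:
        dataset_data.data = self._decode(dataset_data.data)
        return dataset_data

    def _encode(self, value: Any) -> Any:
        if isinstance(value, Quantity):
            mag = value.magnitude
            if isinstance(mag, np.ndarray):
                mag = mag.tolist()
            elif isinstance(mag, np.generic):
                mag = mag.item()
            return {"unit": value.unit, "magnitude": mag}
        if isinstance(value, dict):
            return {k: self._encode(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [self._encode(v) for v in value]
        return value

    def _decode(self, value: Any) -> Any:
        if isinstance(value, dict):
            if set(value) == {"unit", "magnitude"} and isinstance(value["unit"], str):
                return Quantity(value["magnitude"], value["unit"])
            return {k: self._decode(v) for k, v in value.items()}
        if isinstance(value, list):
            return [self._decode(v) for v in value]
        return value


def quantities(order_index: int = 0) -> list:
    """The builtin quantity plugin: pass to ``File(..., plugins=quantities())``."""
    return [QuantityDatasetHandler(order_index), QuantityAttributeHandler(order_index)]
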