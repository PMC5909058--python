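"""Dataset payload storage in the NPY binary array format.

Each dataset directory holds exactly one ``data.npy``. Files are written as
NPY version 1.0, C-contiguous, little-endian, so that any third-party NPY
reader (MATLAB, R, Rust, C++) can open them; version 2.0 is accepted on read.
Reads go through a memory map, so slicing a large dataset never loads the
whole payload, and reads always reflect the current on-disk bytes.
"""

from __future__ import annotations

import math
import os
import tempfile
import warnings
from pathlib import Path
from typing import Any

import numpy as np
from numpy.lib import format as npformat

from .exceptions import (
    CorruptDatasetError,
    NotNpyError,
    ReadOnlyError,
    UnsupportedDtypeError,
)

__all__ = ["write_array", "DatasetHandle", "open_handle", "DATA_FILENAME"]

DATA_FILENAME = "data.npy"


def _to_storable(array: Any) -> np.ndarray:
    arr = np.asarray(array)
    if arr.dtype.hasobject:
        raise UnsupportedDtypeError(
            f"object dtype {arr.dtype} cannot be stored in the NPY format"
        )
    if arr.dtype.names is not None:
        warnings.warn(
            "structured dtypes are outside the portable core of the format; "
            "third-party readers may not support them",
            stacklevel=3,
        )
    # deterministic byte layout: C order, little-endian where byte order
    # applies (ascontiguousarray would promote 0-d to 1-d, so guard it)
    if arr.ndim > 0 and not arr.flags.c_contiguous:
        arr = np.ascontiguousarray(arr)
    if arr.dtype.byteorder == ">" or (
        arr.dtype.byteorder == "=" and arr.dtype.itemsize > 1
        and not _is_little_endian_host()
    ):
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    return arr


def _is_little_endian_host() -> bool:
    import sys

    return sys.byteorder == "little"


def write_array(path: str | os.PathLike, array: Any) -> None:
    """Write *array* to *path* as an NPY v1.0 file, atomically.

    The file is serialized to a temporary sibling and renamed over the target,
    so a crash mid-write never leaves a half-written ``data.npy``.
    """
    path = Path(path)
    arr = _to_storable(array)
    fd, tmp = tempfile.mkstemp(prefix=".data-", suffix=".npy.tmp", dir=path.parent)
    try:
        with os.fdopen(fd, "wb") as f:
            npformat.write_array(f, arr, version=(1, 0), allow_pickle=False)
            f.flush()
            os.fsync(f.fileno())
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def _read_header(path: Path) -> tuple[tuple[int, ...], bool, np.dtype, int]:
    """Parse magic + header; return (shape, fortran_order, dtype, data offset)."""
    with open(path, "rb") as f:
        try:
            version = npformat.read_magic(f)
        except ValueError as exc:
            raise NotNpyError(f"{path}: not an NPY file ({exc})") from exc
        if version == (1, 0):
            shape, fortran, dtype = npformat.read_array_header_1_0(f)
        elif version == (2, 0):
            shape, fortran, dtype = npformat.read_array_header_2_0(f)
        else:
            raise NotNpyError(
                f"{path}: unsupported NPY version {version[0]}.{version[1]}"
            )
        offset = f.tell()
    return shape, fortran, dtype, offset


class DatasetHandle:
    """Shape/dtype view over a ``data.npy`` file with memory-mapped slicing.

    Opening parses only the header; payload bytes are touched lazily through
    the memory map, so opening a huge file is cheap. Writes through the handle
    (``mode='r+'``) are visible to any fresh handle on the same file.
    """

    def __init__(self, path: str | os.PathLike, mode: str = "r"):
        if mode not in ("r", "r+"):
            raise ValueError(f"mode must be 'r' or 'r+', got {mode!r}")
        self._path = Path(path)
        self._mode = mode
        shape, fortran, dtype, offset = _read_header(self._path)
        self._shape = tuple(int(s) for s in shape)
        self._dtype = dtype
        self._fortran = fortran
        self._offset = offset
        n_items = math.prod(self._shape)
        expected = offset + n_items * dtype.itemsize
        actual = self._path.stat().st_size
        if actual < expected:
            raise CorruptDatasetError(
                f"{self._path}: payload is {actual - offset} bytes but header "
                f"declares {expected - offset}"
            )
        if n_items == 0:
            # memory maps cannot have zero length; an empty array of the right
            # shape/dtype is indistinguishable from a mapped one
            self._mm: np.ndarray = np.empty(self._shape, dtype=dtype)
        else:
            self._mm = np.memmap(
                self._path,
                dtype=dtype,
                mode=mode,
                offset=offset,
                shape=self._shape,
                order="F" if fortran else "C",
            )

    @property
    def path(self) -> Path:
        return self._path

    @property
    def mode(self) -> str:
        return self._mode

    @property
    def shape(self) -> tuple[int, ...]:
        return self._shape

    @property
    def dtype(self) -> np.dtype:
        return self._dtype

    @property
    def size(self) -> int:
        return math.prod(self._shape)

    def __len__(self) -> int:
        if not self._shape:
            raise TypeError("len() of a 0-d dataset")
        return self._shape[0]

    def read_slice(self, selection: Any) -> np.ndarray:
        """Return a copy of the selected region (any numpy-style indexing)."""
        out = self._mm[selection]
        return np.array(out, copy=True)

    def read_all(self) -> np.ndarray:
        return np.array(self._mm, copy=True)

    def write_slice(self, selection: Any, values: Any) -> None:
        """Assign *values* (broadcast) to the selected region and flush."""
        if self._mode == "r":
            raise ReadOnlyError(f"{self._path}: dataset opened read-only")
        self._mm[selection] = values
        if isinstance(self._mm, np.memmap):
            self._mm.flush()

    __getitem__ = read_slice
    __setitem__ = write_slice


def open_handle(path: str | os.PathLike, mode: str = "r") -> DatasetHandle:
    """Open a ``data.npy`` file; parses the header only (no payload read)."""
    return DatasetHandle(path, mode)
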