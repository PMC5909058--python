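"""Shared test utilities: structural equality and an independent NPY reader."""

from __future__ import annotations

import ast
import struct
from pathlib import Path

import numpy as np


def structural_eq(a, b) -> bool:
    """Deep equality preserving kind (int vs float) and tolerating NaN."""
    if isinstance(a, float) and isinstance(b, float):
        return (a == b) or (np.isnan(a) and np.isnan(b))
    if isinstance(a, dict):
        return (isinstance(b, dict) and a.keys() == b.keys()
                and all(structural_eq(a[k], b[k]) for k in a))
    if isinstance(a, (list, tuple)):
        return (isinstance(b, (list, tuple)) and len(a) == len(b)
                and all(structural_eq(x, y) for x, y in zip(a, b)))
    return type(a) is type(b) and a == b


def read_npy_independent(path: Path) -> np.ndarray:
    """Minimal NPY reader written from the format description.

    Deliberately independent of ``numpy.lib.format`` (which the library
    delegates to), so conformance tests check the bytes against a second
    implementation: magic, one version byte pair, a little-endian header
    length, a Python-literal header dict, then the raw payload.
    """
    blob = Path(path).read_bytes()
    assert blob[:6] == b"\x93NUMPY", "bad magic"
    major, minor = blob[6], blob[7]
    if (major, minor) == (1, 0):
        (hlen,) = struct.unpack("<H", blob[8:10])
        header_end = 10 + hlen
    elif (major, minor) == (2, 0):
        (hlen,) = struct.unpack("<I", blob[8:12])
        header_end = 12 + hlen
    else:
        raise AssertionError(f"unsupported version {major}.{minor}")
    assert header_end % 64 == 0, "header not 64-byte aligned"
    header = ast.literal_eval(blob[10 if major == 1 else 12:header_end].decode("latin1"))
    dtype = np.dtype(header["descr"])
    shape = tuple(header["shape"])
    order = "F" if header["fortran_order"] else "C"
    count = int(np.prod(shape)) if shape else 1
    payload = blob[header_end:header_end + count * dtype.itemsize]
    assert len(payload) == count * dtype.itemsize, "payload truncated"
    return np.frombuffer(payload, dtype=dtype).reshape(shape, order=order)
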