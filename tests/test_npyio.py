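"""NPY payload conformance and memory-mapped slicing."""

import numpy as np
import pytest

from exdirkit import npyio
from exdirkit.exceptions import (
    CorruptDatasetError,
    NotNpyError,
    ReadOnlyError,
    UnsupportedDtypeError,
)

from helpers import read_npy_independent

DTYPES = ["int8", "int16", "int32", "int64",
          "uint8", "uint16", "uint32", "uint64",
          "float32", "float64", "bool"]
SHAPES = [(), (0,), (3,), (0, 3), (2, 3, 4)]


def _sample(rng, shape, dtype):
    dt = np.dtype(dtype)
    if dt.kind == "b":
        return rng.integers(0, 2, size=shape).astype(bool)
    if dt.kind in "iu":
        info = np.iinfo(dt)
        return rng.integers(info.min // 2 or 0, info.max // 2 + 1,
                            size=shape).astype(dt)
    return rng.standard_normal(size=shape).astype(dt)


class TestWriteArray:
    @pytest.mark.parametrize("dtype", DTYPES)
    @pytest.mark.parametrize("shape", SHAPES)
    def test_conformance_against_independent_reader(self, tmp_path, rng,
                                                    dtype, shape):
        """Every written file must be byte-readable by a second, independently
        written NPY implementation with identical shape/dtype/payload."""
        arr = _sample(rng, shape, dtype)
        path = tmp_path / "data.npy"
        npyio.write_array(path, arr)
        oracle = read_npy_independent(path)
        assert oracle.shape == arr.shape
        assert oracle.dtype == arr.dtype.newbyteorder("<") if arr.dtype.itemsize > 1 \
            else oracle.dtype == arr.dtype
        assert oracle.tobytes() == np.ascontiguousarray(arr).tobytes()
        # and numpy itself agrees
        assert np.array_equal(np.load(path), arr)

    def test_reads_file_written_by_reference_writer(self, tmp_path, rng):
        arr = rng.standard_normal((4, 5))
        np.save(tmp_path / "ref.npy", arr)
        handle = npyio.open_handle(tmp_path / "ref.npy")
        assert np.array_equal(handle.read_all(), arr)

    def test_fortran_input_stored_c_contiguous(self, tmp_path):
        arr = np.asfortranarray(np.arange(12).reshape(3, 4))
        npyio.write_array(tmp_path / "data.npy", arr)
        blob = (tmp_path / "data.npy").read_bytes()
        assert b"'fortran_order': False" in blob
        assert np.array_equal(np.load(tmp_path / "data.npy"), arr)

    def test_big_endian_input_stored_little_endian(self, tmp_path):
        arr = np.arange(5, dtype=">f8")
        npyio.write_array(tmp_path / "data.npy", arr)
        assert np.load(tmp_path / "data.npy").dtype.byteorder in ("<", "=")
        assert np.array_equal(np.load(tmp_path / "data.npy"), arr)

    def test_object_dtype_rejected(self, tmp_path):
        with pytest.raises(UnsupportedDtypeError):
            npyio.write_array(tmp_path / "data.npy", np.array([object()]))

    def test_rewrite_is_atomic_replacement(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.arange(10))
        npyio.write_array(path, np.arange(3.0))
        assert np.array_equal(np.load(path), np.arange(3.0))
        assert list(tmp_path.iterdir()) == [path]  # no temp litter


class TestOpenHandle:
    def test_header_only_metadata(self, tmp_path, rng):
        arr = _sample(rng, (7, 2), "int32")
        npyio.write_array(tmp_path / "data.npy", arr)
        handle = npyio.open_handle(tmp_path / "data.npy")
        assert handle.shape == (7, 2)
        assert handle.dtype == np.dtype("<i4")
        assert handle.size == 14 and len(handle) == 7

    def test_bad_magic(self, tmp_path):
        (tmp_path / "data.npy").write_bytes(b"NOTNPY" + b"\x00" * 64)
        with pytest.raises(NotNpyError):
            npyio.open_handle(tmp_path / "data.npy")

    def test_truncated_payload(self, tmp_path, rng):
        path = tmp_path / "data.npy"
        npyio.write_array(path, rng.standard_normal(100))
        blob = path.read_bytes()
        path.write_bytes(blob[:-40])
        with pytest.raises(CorruptDatasetError):
            npyio.open_handle(path)

    def test_read_only_handle_rejects_writes(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.arange(4))
        handle = npyio.open_handle(path, mode="r")
        with pytest.raises(ReadOnlyError):
            handle.write_slice(slice(0, 2), 0)

    def test_corruption_is_contained_to_one_file(self, tmp_path, rng):
        good, bad = tmp_path / "good.npy", tmp_path / "bad.npy"
        arr = rng.standard_normal(50)
        npyio.write_array(good, arr)
        npyio.write_array(bad, arr)
        blob = bytearray(bad.read_bytes())
        blob[0] ^= 0xFF  # flip a magic byte
        bad.write_bytes(bytes(blob))
        with pytest.raises(NotNpyError):
            npyio.open_handle(bad)
        assert np.array_equal(npyio.open_handle(good).read_all(), arr)


class TestSlicing:
    def test_half_open_slice(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.arange(10))
        assert np.array_equal(npyio.open_handle(path)[2:5], [2, 3, 4])

    def test_strided_write_then_full_read(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.arange(10.0))
        handle = npyio.open_handle(path, "r+")
        handle[::2] = 0
        expected = np.arange(10.0)
        expected[::2] = 0
        assert np.array_equal(npyio.open_handle(path).read_all(), expected)

    def test_random_selections_match_in_memory_oracle(self, tmp_path, rng):
        """Random slice/fancy expressions on the mapped handle equal the same
        expressions on a plain in-memory copy, interleaved with writes."""
        shape = (20, 30, 10)
        arr = rng.standard_normal(shape)
        path = tmp_path / "data.npy"
        npyio.write_array(path, arr)
        handle = npyio.open_handle(path, "r+")
        oracle = arr.copy()
        for step in range(80):
            selection = random_selection(rng, shape)
            assert np.array_equal(handle[selection], oracle[selection]), selection
            if step % 4 == 0:
                value = float(rng.standard_normal())
                handle[selection] = value
                oracle[selection] = value
        assert np.array_equal(npyio.open_handle(path).read_all(), oracle)

    def test_fresh_handle_sees_writes(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.zeros(5))
        npyio.open_handle(path, "r+")[1] = 7.0
        assert npyio.open_handle(path)[1] == 7.0

    def test_out_of_bounds_raises(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.arange(4))
        with pytest.raises(IndexError):
            npyio.open_handle(path)[10]

    def test_broadcast_error_propagates(self, tmp_path):
        path = tmp_path / "data.npy"
        npyio.write_array(path, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            npyio.open_handle(path, "r+")[0:2] = np.ones(5)


def random_selection(rng, shape):
    """One random indexing expression: ints, slices, full axes, fancy arrays.

    All index arrays in one expression share a length so they broadcast.
    """
    fancy_n = int(rng.integers(1, 5))
    selection = []
    for extent in shape:
        kind = rng.integers(4)
        if kind == 0:
            selection.append(int(rng.integers(extent)))
        elif kind == 1:
            a, b = sorted(rng.integers(0, extent + 1, size=2))
            step = int(rng.integers(1, 4))
            selection.append(slice(int(a), int(b), step))
        elif kind == 2:
            selection.append(slice(None))
        else:
            selection.append(rng.integers(0, extent, size=fancy_n))
    return tuple(selection)
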