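"""HDF5 <-> directory-tree conversion."""

import h5py
import numpy as np
import pytest

from exdirkit import File
from exdirkit.converter import (
    exdir_to_hdf5,
    flatten_attrs,
    hdf5_to_exdir,
    unflatten_attrs,
)
from exdirkit.exceptions import ObjectExistsError
from exdirkit.fixtures import TreeSpec, generate_hdf5_twin, generate_tree
from exdirkit.lint import lint_tree

from helpers import structural_eq


def _walk_h5(h5file):
    """Canonical {path: (kind, attrs, payload)} snapshot of an HDF5 file."""
    out = {}

    def visit(name, obj):
        attrs = {k: _canon(obj.attrs[k]) for k in obj.attrs}
        if isinstance(obj, h5py.Dataset):
            out["/" + name] = ("dataset", attrs,
                               (obj.shape, obj.dtype.str, obj[()].tobytes()))
        else:
            out["/" + name] = ("group", attrs, None)

    out["/"] = ("group", {k: _canon(h5file.attrs[k]) for k in h5file.attrs},
                None)
    h5file.visititems(visit)
    return out


def _canon(value):
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return tuple(_canon(v) for v in value.tolist())
    return value


class TestFlatten:
    def test_flatten_unflatten_inverse(self):
        document = {"daq": {"model": "NI", "cfg": {"rate": 30000}},
                    "plain": 1,
                    "has.dot": {"inner": True}}
        flat = flatten_attrs(document)
        assert flat == {"daq.model": "NI", "daq.cfg.rate": 30000,
                        "plain": 1, "has\\.dot.inner": True}
        assert unflatten_attrs(flat) == document


class TestHdf5ToExdir:
    def test_structural_identity(self, tmp_path, rng):
        src = tmp_path / "src.h5"
        with h5py.File(src, "w") as h5:
            h5.attrs["experimenter"] = "m. lab"
            g = h5.create_group("session1")
            g.attrs["rate_hz"] = 30000.0
            arr = rng.standard_normal((4, 5)).astype("float32")
            d = g.create_dataset("lfp", data=arr)
            d.attrs["channels"] = np.array([1, 2, 3])
        report = hdf5_to_exdir(src, tmp_path / "out.exdir")
        assert report.objects_converted == {"file": 1, "group": 1, "dataset": 1}
        assert report.skipped == []
        out = File(tmp_path / "out.exdir", "r")
        assert out.attrs["experimenter"] == "m. lab"
        assert out["session1"].attrs["rate_hz"] == 30000.0
        ds = out["session1/lfp"]
        assert ds.dtype == np.float32
        assert ds[...].tobytes() == arr.tobytes()
        assert ds.attrs["channels"] == [1, 2, 3]
        assert lint_tree(tmp_path / "out.exdir").ok

    def test_soft_link_skipped_with_reason(self, tmp_path):
        src = tmp_path / "src.h5"
        with h5py.File(src, "w") as h5:
            h5.create_dataset("real", data=np.arange(3))
            h5["alias"] = h5py.SoftLink("/real")
        report = hdf5_to_exdir(src, tmp_path / "out.exdir")
        assert ("/alias", "links unsupported") in report.skipped
        out = File(tmp_path / "out.exdir", "r")
        assert "alias" not in out and "real" in out

    def test_vlen_string_dataset(self, tmp_path):
        src = tmp_path / "src.h5"
        with h5py.File(src, "w") as h5:
            h5.create_dataset("labels", data=["alpha", "beta"],
                              dtype=h5py.string_dtype())
        hdf5_to_exdir(src, tmp_path / "out.exdir")
        out = File(tmp_path / "out.exdir", "r")
        assert out["labels"][...].tolist() == ["alpha", "beta"]

    def test_existing_target_requires_overwrite(self, tmp_path):
        with h5py.File(tmp_path / "src.h5", "w"):
            pass
        (tmp_path / "out.exdir").mkdir()
        with pytest.raises(ObjectExistsError):
            hdf5_to_exdir(tmp_path / "src.h5", tmp_path / "out.exdir")


class TestExdirToHdf5:
    def test_nested_attrs_flattened_and_reported(self, tmp_path):
        f = File(tmp_path / "t.exdir", "w")
        f.attrs = {"daq": {"model": "NI", "rate": 30000}}
        report = exdir_to_hdf5(tmp_path / "t.exdir", tmp_path / "out.h5")
        assert any("flattened" in d for _, d in report.lossy)
        with h5py.File(tmp_path / "out.h5", "r") as h5:
            assert _canon(h5.attrs["daq.model"]) == "NI"
            assert _canon(h5.attrs["daq.rate"]) == 30000

    def test_raw_skip_and_opaque(self, tmp_path):
        f = File(tmp_path / "t.exdir", "w")
        raw = f.create_raw("acq")
        (raw.directory / "frame.bin").write_bytes(b"\x01\x02\x03")
        report = exdir_to_hdf5(tmp_path / "t.exdir", tmp_path / "skip.h5")
        assert ("/acq", "raw directory (raw_mode=skip)") in report.skipped
        with h5py.File(tmp_path / "skip.h5", "r") as h5:
            assert "acq" not in h5
        report = exdir_to_hdf5(tmp_path / "t.exdir", tmp_path / "op.h5",
                               raw_mode="opaque")
        assert report.objects_converted.get("raw") == 1
        with h5py.File(tmp_path / "op.h5", "r") as h5:
            assert h5["acq/frame.bin"][()].tobytes() == b"\x01\x02\x03"

    def test_unicode_dataset_reported_lossy(self, tmp_path, rng):
        f = File(tmp_path / "t.exdir", "w")
        f.create_dataset("labels", data=np.array(["a", "bb"]))
        report = exdir_to_hdf5(tmp_path / "t.exdir", tmp_path / "out.h5")
        assert any("variable-length" in d for _, d in report.lossy)
        with h5py.File(tmp_path / "out.h5", "r") as h5:
            assert [v.decode() for v in h5["labels"][()]] == ["a", "bb"]

    def test_bad_raw_mode(self, tmp_path):
        File(tmp_path / "t.exdir", "w")
        with pytest.raises(ValueError):
            exdir_to_hdf5(tmp_path / "t.exdir", tmp_path / "o.h5",
                          raw_mode="banana")


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_hdf5_fixture_round_trips(self, tmp_path, seed):
        """h5 -> tree -> h5: the two HDF5 files have identical walks."""
        manifest = generate_tree(TreeSpec(seed=seed, max_depth=2),
                                 tmp_path / "scratch.exdir")
        generate_hdf5_twin(manifest, tmp_path / "a.h5")
        hdf5_to_exdir(tmp_path / "a.h5", tmp_path / "mid.exdir")
        exdir_to_hdf5(tmp_path / "mid.exdir", tmp_path / "b.h5")
        with h5py.File(tmp_path / "a.h5", "r") as ha, \
                h5py.File(tmp_path / "b.h5", "r") as hb:
            assert _walk_h5(ha) == _walk_h5(hb)

    def test_attr_values_survive_two_hops(self, tmp_path):
        src = tmp_path / "src.h5"
        document = {"rate": 30000.0, "id": 7, "ok": True, "note": "x y"}
        with h5py.File(src, "w") as h5:
            for k, v in document.items():
                h5.attrs[k] = v
        hdf5_to_exdir(src, tmp_path / "mid.exdir")
        mid = File(tmp_path / "mid.exdir", "r").attrs.to_dict()
        assert structural_eq(mid, document)
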