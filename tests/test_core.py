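"""File/Group/Dataset/Raw hierarchy semantics."""

import os

import numpy as np
import pytest

import exdirkit
from exdirkit import File
from exdirkit.exceptions import (
    InvalidNameError,
    NotExdirDirectoryError,
    ObjectExistsError,
    ReadOnlyError,
    StaleHandleError,
    TypeMismatchError,
)
from exdirkit.fixtures import (
    random_program,
    replay_in_memory,
    replay_on_disk,
    snapshot_tree,
)


class TestOpenModes:
    def test_create_writes_minimal_layout(self, tmp_path):
        f = File(tmp_path / "a.exdir", "w")
        assert f.object_type == "file" and f.name == "/"
        entries = sorted(os.listdir(tmp_path / "a.exdir"))
        assert entries == ["exdir.yaml"]

    def test_reopen_read_only(self, tmp_path):
        File(tmp_path / "a.exdir", "w")
        f = File(tmp_path / "a.exdir", "r")
        assert f.object_type == "file"
        with pytest.raises(ReadOnlyError):
            f.create_group("g")
        with pytest.raises(ReadOnlyError):
            f.attrs["k"] = 1

    def test_r_missing_location(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            File(tmp_path / "missing.exdir", "r")

    def test_w_minus_existing_location(self, tmp_path):
        File(tmp_path / "a.exdir", "w")
        with pytest.raises(ObjectExistsError):
            File(tmp_path / "a.exdir", "w-")

    def test_w_truncates(self, tmp_path):
        f = File(tmp_path / "a.exdir", "w")
        f.create_group("g")
        f2 = File(tmp_path / "a.exdir", "w")
        assert list(f2) == []

    def test_open_non_file_type_mismatch(self, tmp_path):
        f = File(tmp_path / "a.exdir", "w")
        d = f.create_dataset("d", data=np.arange(3))
        with pytest.raises(TypeMismatchError):
            File(d.directory, "r")

    def test_directory_without_meta_rejected(self, tmp_path):
        (tmp_path / "plain").mkdir()
        with pytest.raises(NotExdirDirectoryError):
            File(tmp_path / "plain", "r")
        # and 'w' refuses to truncate a directory it does not own
        with pytest.raises(NotExdirDirectoryError):
            File(tmp_path / "plain", "w")

    def test_append_mode_creates_then_reopens(self, tmp_path):
        File(tmp_path / "a.exdir", "a").create_group("g")
        assert "g" in File(tmp_path / "a.exdir", "a")


class TestGroups:
    def test_create_group_layout(self, root):
        g = root.create_group("session1")
        assert g.name == "/session1"
        assert (g.directory / "exdir.yaml").is_file()

    def test_case_conflict_under_thorough(self, root):
        root.create_group("name")
        with pytest.raises(ObjectExistsError):
            root.create_group("Name")

    def test_multicomponent_requires_existing_ancestors(self, root):
        with pytest.raises(KeyError):
            root.create_group("a/b")
        root.create_group("a")
        g = root.create_group("a/b")
        assert g.name == "/a/b"
        assert (root.directory / "a" / "b" / "exdir.yaml").is_file()

    def test_require_group_idempotent(self, root):
        g1 = root.require_group("g")
        g2 = root.require_group("g")
        assert g1 == g2
        assert sorted(os.listdir(g1.directory)) == ["exdir.yaml"]

    def test_require_group_type_mismatch(self, root):
        root.create_dataset("d", data=np.arange(2))
        with pytest.raises(TypeMismatchError):
            root.require_group("d")

    def test_interleaved_create_require_matches_set_union(self, root, rng):
        expected = set()
        for _ in range(20):
            name = f"grp_{int(rng.integers(8))}"
            if name in expected:
                root.require_group(name)
            else:
                (root.create_group if rng.random() < 0.5
                 else root.require_group)(name)
            expected.add(name)
        assert set(root.keys()) == expected

    def test_reserved_names_rejected(self, root):
        for reserved in ("exdir.yaml", "attributes.yaml", "data.npy"):
            with pytest.raises((InvalidNameError, ObjectExistsError)):
                root.create_group(reserved)


class TestDatasets:
    def test_shape_only_zero_fills(self, root):
        d = root.create_dataset("mydata", shape=(3,), dtype="int64")
        assert np.array_equal(d[...], [0, 0, 0])

    def test_data_round_trip_bitwise(self, root, rng):
        arr = rng.standard_normal(1000)
        d = root.create_dataset("a", data=arr)
        assert d[...].tobytes() == arr.tobytes()

    def test_inconsistent_shape_and_data(self, root):
        with pytest.raises(ValueError):
            root.create_dataset("d", shape=(2,), data=np.arange(3))

    def test_neither_shape_nor_data(self, root):
        with pytest.raises(TypeError):
            root.create_dataset("d")

    def test_slicing_and_assignment(self, root):
        d = root.create_dataset("d", data=np.arange(10.0))
        assert np.array_equal(d[2:5], [2, 3, 4])
        d[::2] = 0
        assert np.array_equal(d[...], [0, 1, 0, 3, 0, 5, 0, 7, 0, 9])

    def test_shape_dtype_properties(self, root):
        d = root.create_dataset("d", data=np.zeros((2, 3), dtype="float32"))
        assert d.shape == (2, 3) and d.dtype == np.float32 and d.size == 6

    def test_data_setter_replaces_payload(self, root):
        d = root.create_dataset("d", data=np.arange(4))
        d.data = np.zeros((2, 2), dtype="float32")
        assert d.shape == (2, 2) and d.dtype == np.float32


class TestRaw:
    def test_foreign_file_survives_reopen(self, root):
        raw = root.create_raw("acquisition")
        (raw.directory / "camera.avi").write_bytes(b"\x00" * 10)
        f = File(root.directory, "r")
        again = f["acquisition"]
        assert again.object_type == "raw"
        assert again.filenames() == ["camera.avi"]

    def test_external_directory_classified_raw(self, root):
        g = root.create_group("g")
        (g.directory / "external").mkdir()
        assert File(root.directory, "r")["g/external"].object_type == "raw"
        assert list(File(root.directory, "r")["g"]) == ["external"]

    def test_raw_attributes(self, root):
        raw = root.create_raw("r")
        raw.attrs["source"] = "amplifier"
        assert (raw.directory / "attributes.yaml").is_file()
        assert raw.attrs["source"] == "amplifier"


class TestLookup:
    def test_nested_retrieval(self, root):
        g = root.create_group("g")
        g.create_dataset("d", data=np.arange(3))
        assert root["g/d"].object_type == "dataset"
        assert root["g"]["d"].name == "/g/d"

    def test_lookup_is_case_exact(self, root):
        g = root.create_group("g")
        g.create_dataset("d", data=np.arange(3))
        with pytest.raises(KeyError):
            root["G/d"]
        with pytest.raises(KeyError):
            root["g/D"]

    def test_descending_through_dataset_fails(self, root):
        root.create_dataset("d", data=np.arange(3))
        with pytest.raises(TypeMismatchError):
            root["d/x"]

    def test_contains_and_get(self, root):
        g = root.create_group("g")
        g.create_dataset("d", data=np.arange(3))
        assert "g/d" in root and "g/x" not in root and "/" in root
        assert root.get("g/x") is None
        assert root.get("g/d").object_type == "dataset"

    def test_nested_file_meta_is_rejected(self, root):
        g = root.create_group("g")
        (g.directory / "exdir.yaml").write_text(
            'exdir:\n  type: "file"\n  version: 1\n', encoding="utf-8"
        )
        with pytest.raises(TypeMismatchError):
            root["g"]

    def test_iteration_is_sorted_and_case_preserving(self, tmp_path):
        f = File(tmp_path / "t.exdir", "w", name_validation="minimal")
        for name in ("b", "A", "c"):
            f.create_group(name)
        assert list(f) == sorted(["b", "A", "c"])
        assert f.keys() == ["A", "b", "c"]
        assert [o.name for o in f.values()] == ["/A", "/b", "/c"]
        assert dict(f.items()).keys() == {"A", "b", "c"}

    def test_iteration_skips_special_files(self, root):
        root.attrs["k"] = 1
        root.create_dataset("d", data=np.arange(2))
        assert list(root) == ["d"]
        assert list(root["d"]) if False else True  # datasets are not iterated


class TestDeletion:
    def test_dataset_deletion_frees_space(self, root):
        root.create_dataset("big", data=np.zeros(10_000))
        data_file = root.directory / "big" / "data.npy"
        assert data_file.is_file()
        del root["big"]
        assert not data_file.exists() and "big" not in root

    def test_group_deletion_removes_descendants(self, root):
        g = root.create_group("g")
        g.create_group("sub").create_dataset("d", data=np.arange(5))
        target = g.directory
        del root["g"]
        assert not target.exists()
        leftovers = [p for p in root.directory.rglob("*") if "g" in p.parts]
        assert leftovers == []

    def test_delete_missing_raises(self, root):
        with pytest.raises(KeyError):
            del root["nope"]

    def test_stale_handle_after_delete(self, root):
        g = root.create_group("g")
        d = g.create_dataset("d", data=np.arange(2))
        del root["g"]
        with pytest.raises(StaleHandleError):
            g.create_group("x")
        with pytest.raises(StaleHandleError):
            d[...]


class TestAttributes:
    def test_scalar_round_trip_preserves_kind(self, root):
        root.attrs["temperature"] = 32
        assert root.attrs["temperature"] == 32
        assert isinstance(root.attrs["temperature"], int)

    def test_nested_dictionary_attributes(self, root):
        document = {"daq": {"model": "NI-6343", "channels": [1, 2, 3]},
                    "depth_um": 800.5}
        root.attrs = document
        reread = File(root.directory, "r").attrs.to_dict()
        assert reread == document

    def test_incremental_equals_bulk_bytewise(self, tmp_path, rng):
        """N single-key writes and one bulk assignment of the same document
        must leave byte-identical attributes.yaml files."""
        doc = {f"key_{i:03d}": float(rng.standard_normal()) for i in range(200)}
        one = File(tmp_path / "one.exdir", "w")
        for k, v in doc.items():
            one.attrs[k] = v
        bulk = File(tmp_path / "bulk.exdir", "w")
        bulk.attrs = doc
        assert (one.directory / "attributes.yaml").read_bytes() == \
               (bulk.directory / "attributes.yaml").read_bytes()

    def test_absent_file_reads_empty(self, root):
        g = root.create_group("g")
        assert g.attrs.to_dict() == {}
        assert len(g.attrs) == 0

    def test_unsupported_value_rejected(self, root):
        with pytest.raises(exdirkit.exceptions.UnsupportedValueError):
            root.attrs["bad"] = {1, 2}

    def test_attribute_delete_and_update(self, root):
        root.attrs = {"a": 1, "b": 2}
        del root.attrs["a"]
        root.attrs.update({"c": 3})
        assert root.attrs.to_dict() == {"b": 2, "c": 3}


class TestNames:
    def test_root_name(self, root):
        assert root.name == "/"

    def test_nested_names(self, root):
        g = root.create_group("g")
        sub = g.create_group("sub")
        d = sub.create_dataset("d", data=np.arange(2))
        assert d.name == "/g/sub/d"
        assert d.parent.name == "/g/sub"
        assert root.parent.name == "/"

    def test_name_resolves_back_to_object(self, tmp_path):
        from exdirkit.fixtures import TreeSpec, generate_tree

        manifest = generate_tree(TreeSpec(seed=5), tmp_path / "t.exdir")
        f = File(tmp_path / "t.exdir", "r")
        for entry in manifest:
            if entry.path == "/":
                continue
            obj = f[entry.path.lstrip("/")]
            assert obj.name == entry.path
            assert obj.object_type == entry.object_type


class TestStructuralRoundTrip:
    @pytest.mark.parametrize("seed", range(25))
    def test_programs_match_in_memory_oracle(self, tmp_path, seed):
        """Random operation programs, replayed on disk and on a plain nested
        map, agree after close/reopen on (path, type, attrs, data)."""
        program = random_program(seed)
        f = File(tmp_path / "p.exdir", "w-")
        replay_on_disk(program, f)
        assert snapshot_tree(tmp_path / "p.exdir") == replay_in_memory(program)
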