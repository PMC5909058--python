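"""Seeded generator of valid (and deliberately broken) trees.

Every test input is generated, none downloaded. A :class:`TreeSpec` plus a
seed is a pure recipe: the same pair always produces the same manifest and the
same on-disk tree. Trees are written through the public API, so generating a
fixture is itself an integration exercise of the library; fault injections
(truncated payloads, bad type tags, case collisions, flow-style YAML, missing
metadata) bypass the API on purpose and write raw files directly.

Per-node random streams are derived by hashing ``(seed, path)``, so a
subtree's content does not depend on the order its siblings were generated in.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np

from .core import File, Group

__all__ = ["TreeSpec", "ManifestEntry", "generate_tree", "generate_hdf5_twin",
           "random_document", "node_rng", "FAULT_KINDS",
           "random_program", "replay_in_memory", "replay_on_disk",
           "snapshot_tree", "canonical_value"]

FAULT_KINDS = ("truncate_npy", "bad_type_tag", "case_collision",
               "flow_style_yaml", "missing_meta")

_WORDS = (
    "session", "trial", "probe", "stim", "lfp", "spikes", "epoch", "unit",
    "sweep", "channel", "frame", "motion", "events", "waveform", "position",
)


@dataclass(frozen=True)
class TreeSpec:
    """Recipe for a generated tree; with a seed it determines the tree fully."""

    seed: int = 0
    max_depth: int = 3
    children_per_node: tuple[int, int] = (2, 4)
    dataset_shapes: tuple[tuple[int, ...], ...] = (
        (), (3,), (0,), (2, 3), (4, 4), (0, 3), (10,),
    )
    dtypes: tuple[str, ...] = ("float64", "float32", "int64", "int32",
                               "uint8", "bool")
    attr_probability: float = 0.6
    fault_injections: frozenset = frozenset()
    name_validation: str = "thorough"


@dataclass
class ManifestEntry:
    """Oracle record of one generated object."""

    path: str
    object_type: str
    shape: tuple[int, ...] | None = None
    dtype: str | None = None
    attrs: dict[str, Any] = field(default_factory=dict)
    data: np.ndarray | None = None
    raw_files: dict[str, bytes] = field(default_factory=dict)


def node_rng(seed: int, path: str) -> np.random.Generator:
    """Independent random stream for one node, derived from (seed, path)."""
    digest = hashlib.sha256(f"{seed}:{path}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# random attribute documents
# ---------------------------------------------------------------------------

_SCALAR_KINDS = ("str", "int", "float", "bool", "null")


def _random_scalar(rng: np.random.Generator) -> Any:
    kind = _SCALAR_KINDS[rng.integers(len(_SCALAR_KINDS))]
    if kind == "str":
        n = int(rng.integers(0, 12))
        alphabet = "abc XYZ-_.:#{}[]'\"\\\nµΩ0123456789"
        return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))
    if kind == "int":
        return int(rng.integers(-(10 ** 9), 10 ** 9))
    if kind == "float":
        return float(rng.standard_normal() * 10.0 ** int(rng.integers(-8, 9)))
    if kind == "bool":
        return bool(rng.integers(2))
    return None


def _random_key(rng: np.random.Generator, odd: bool = False) -> str:
    base = _WORDS[rng.integers(len(_WORDS))] + "_" + str(int(rng.integers(100)))
    if odd and rng.random() < 0.3:
        return base + " #" + str(int(rng.integers(10)))  # breaks key convention
    return base


def _random_value(rng: np.random.Generator, depth: int) -> Any:
    roll = rng.random()
    if depth <= 0 or roll < 0.6:
        return _random_scalar(rng)
    if roll < 0.8:
        return [_random_value(rng, depth - 1)
                for _ in range(int(rng.integers(1, 4)))]
    return {
        _random_key(rng): _random_value(rng, depth - 1)
        for _ in range(int(rng.integers(1, 4)))
    }


def random_document(rng: np.random.Generator, max_depth: int = 4,
                    max_keys: int = 6, odd_keys: bool = False) -> dict[str, Any]:
    """A random attribute document over all seven value kinds.

    Containers are always non-empty (the restricted subset cannot represent
    empty maps/sequences without flow style).
    """
    doc: dict[str, Any] = {}
    for _ in range(int(rng.integers(1, max_keys + 1))):
        doc[_random_key(rng, odd=odd_keys)] = _random_value(rng, max_depth - 1)
    return doc


def _random_array(rng: np.random.Generator, shape: tuple[int, ...],
                  dtype: str) -> np.ndarray:
    if dtype == "bool":
        return rng.integers(0, 2, size=shape).astype(bool)
    dt = np.dtype(dtype)
    if dt.kind == "u":
        return rng.integers(0, np.iinfo(dt).max, size=shape).astype(dt)
    if dt.kind == "i":
        return rng.integers(np.iinfo(dt).min // 2, np.iinfo(dt).max // 2,
                            size=shape).astype(dt)
    return rng.standard_normal(size=shape).astype(dt)


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _unique_name(rng: np.random.Generator, taken_folded: set[str]) -> str:
    while True:
        word = _WORDS[rng.integers(len(_WORDS))]
        if rng.random() < 0.3:
            word = word.capitalize()
        name = f"{word}_{int(rng.integers(1000)):03d}"
        if name.lower() not in taken_folded:
            taken_folded.add(name.lower())
            return name


def _populate(group: Group, spec: TreeSpec, depth: int,
              manifest: list[ManifestEntry]) -> None:
    rng = node_rng(spec.seed, group.name)
    lo, hi = spec.children_per_node
    n_children = int(rng.integers(lo, hi + 1))
    taken: set[str] = set()
    for _ in range(n_children):
        name = _unique_name(rng, taken)
        if depth < spec.max_depth:
            kind = ("group", "dataset", "raw")[
                int(rng.choice(3, p=(0.45, 0.40, 0.15)))
            ]
        else:
            kind = ("dataset", "raw")[int(rng.choice(2, p=(0.8, 0.2)))]
        attrs = (random_document(rng, max_depth=3, max_keys=3)
                 if rng.random() < spec.attr_probability else {})
        if kind == "group":
            child = group.create_group(name)
            if attrs:
                child.attrs = attrs
            manifest.append(ManifestEntry(child.name, "group", attrs=attrs))
            _populate(child, spec, depth + 1, manifest)
        elif kind == "dataset":
            shape = spec.dataset_shapes[int(rng.integers(len(spec.dataset_shapes)))]
            dtype = spec.dtypes[int(rng.integers(len(spec.dtypes)))]
            data = _random_array(rng, shape, dtype)
            child = group.create_dataset(name, data=data)
            if attrs:
                child.attrs = attrs
            manifest.append(ManifestEntry(child.name, "dataset", shape=shape,
                                          dtype=dtype, attrs=attrs, data=data))
        else:
            raw = group.create_raw(name)
            files = {}
            for j in range(int(rng.integers(0, 3))):
                payload = rng.integers(0, 256, size=int(rng.integers(1, 64)),
                                       dtype=np.uint8).tobytes()
                filename = f"acquisition_{j}.bin"
                (raw.directory / filename).write_bytes(payload)
                files[filename] = payload
            if attrs:
                raw.attrs = attrs
            manifest.append(ManifestEntry(raw.name, "raw", attrs=attrs,
                                          raw_files=files))


def _inject_faults(root: Path, spec: TreeSpec) -> None:
    rng = node_rng(spec.seed, "::faults")
    faults = spec.fault_injections
    if "truncate_npy" in faults:
        victim = root / "fault_truncated"
        victim.mkdir()
        (victim / "exdir.yaml").write_text(
            "exdir:\n  type: dataset\n  version: 1\n", encoding="utf-8"
        )
        arr = rng.standard_normal(64)
        import io

        buf = io.BytesIO()
        np.lib.format.write_array(buf, arr, version=(1, 0))
        payload = buf.getvalue()
        (victim / "data.npy").write_bytes(payload[: len(payload) - 200])
    if "bad_type_tag" in faults:
        victim = root / "fault_bad_tag"
        victim.mkdir()
        (victim / "exdir.yaml").write_text(
            "exdir:\n  type: blob\n  version: 1\n", encoding="utf-8"
        )
    if "case_collision" in faults:
        for name in ("fault_case", "Fault_case"):
            d = root / name
            d.mkdir()
            (d / "exdir.yaml").write_text(
                "exdir:\n  type: group\n  version: 1\n", encoding="utf-8"
            )
    if "flow_style_yaml" in faults:
        victim = root / "fault_flow"
        victim.mkdir()
        (victim / "exdir.yaml").write_text(
            "exdir:\n  type: group\n  version: 1\n", encoding="utf-8"
        )
        (victim / "attributes.yaml").write_text(
            "channels: [1, 2, 3]\n", encoding="utf-8"
        )
    if "missing_meta" in faults:
        victim = root / "fault_no_meta"
        victim.mkdir()
        (victim / "notes.txt").write_text("foreign file\n", encoding="utf-8")


def generate_tree(spec: TreeSpec, target: str | os.PathLike
                  ) -> list[ManifestEntry]:
    """Write a tree described by *spec* at *target*; return its manifest.

    The manifest (ordered list of (path, type, shape/dtype, attrs, payload))
    is the oracle tests compare the on-disk tree against. Requires an empty or
    absent target.
    """
    unknown = set(spec.fault_injections) - set(FAULT_KINDS)
    if unknown:
        raise ValueError(f"unknown fault injections: {sorted(unknown)}")
    manifest: list[ManifestEntry] = []
    rng = node_rng(spec.seed, "/")
    root_attrs = (random_document(rng, max_depth=2, max_keys=3)
                  if rng.random() < spec.attr_probability else {})
    f = File(target, mode="w-", name_validation=spec.name_validation)
    if root_attrs:
        f.attrs = root_attrs
    manifest.append(ManifestEntry("/", "file", attrs=root_attrs))
    _populate(f, spec, depth=1, manifest=manifest)
    if spec.fault_injections:
        _inject_faults(Path(target), spec)
    return manifest


def generate_hdf5_twin(manifest: list[ManifestEntry],
                       target: str | os.PathLike) -> None:
    """Write an HDF5 file holding the manifest's common-subset content.

    Raw objects and attribute values HDF5 cannot hold (nested maps, nulls,
    heterogeneous sequences) are omitted; everything else maps one to one.
    Feeds the converter round-trip tests from the HDF5 side.
    """
    with h5py.File(target, "w") as h5:
        for entry in manifest:
            if entry.object_type == "raw":
                continue
            if entry.object_type == "file":
                node = h5
            elif entry.object_type == "group":
                node = h5.create_group(entry.path)
            else:
                node = h5.create_dataset(entry.path, data=entry.data)
            for key, value in entry.attrs.items():
                if isinstance(value, (bool, int, float, str)):
                    node.attrs[key] = value
                elif (isinstance(value, list) and value
                      and all(isinstance(v, (int, float)) and
                              not isinstance(v, bool) for v in value)):
                    node.attrs[key] = np.asarray(value)
                # nested maps / nulls / mixed sequences: no HDF5 counterpart


# ---------------------------------------------------------------------------
# random operation programs + in-memory oracle
# ---------------------------------------------------------------------------
# A "program" is a seeded list of create/require/attr/delete operations. It
# can be replayed twice: once through the library onto disk, and once onto a
# plain nested dict that knows nothing about the on-disk layout. Comparing
# the two snapshots is the structural round-trip check.

_OPS = ("create_group", "require_group", "create_dataset", "create_raw",
        "set_attr", "bulk_attrs", "delete")
_OP_WEIGHTS = (0.28, 0.10, 0.22, 0.08, 0.14, 0.08, 0.10)


def random_program(seed: int, max_ops: int = 50, max_depth: int = 4
                   ) -> list[tuple]:
    """A seeded random, always-valid operation program.

    Simulates the tree while generating, so every emitted operation succeeds:
    names are unique case-insensitively per parent (thorough-safe), deletes
    target existing children, datasets are created under existing groups.
    """
    rng = np.random.default_rng(seed)
    # simulated state: path -> type; children: path -> set of folded names
    nodes: dict[str, str] = {"/": "file"}
    children: dict[str, set[str]] = {"/": set()}
    program: list[tuple] = []

    def depth(path: str) -> int:
        return 0 if path == "/" else path.count("/")

    def groups() -> list[str]:
        return sorted(p for p, t in nodes.items() if t in ("file", "group"))

    def join(parent: str, name: str) -> str:
        return ("/" + name) if parent == "/" else f"{parent}/{name}"

    def remove_subtree(path: str) -> None:
        for p in [p for p in nodes if p == path or p.startswith(path + "/")]:
            nodes.pop(p)
            children.pop(p, None)

    n_ops = int(rng.integers(5, max_ops + 1))
    for _ in range(n_ops):
        op = _OPS[int(rng.choice(len(_OPS), p=_OP_WEIGHTS))]
        if op in ("create_group", "require_group", "create_dataset",
                  "create_raw"):
            candidates = [g for g in groups() if depth(g) < max_depth]
            if not candidates:
                continue
            parent = candidates[int(rng.integers(len(candidates)))]
            taken = children[parent]
            name = _unique_name(rng, set(taken))
            taken.add(name.lower())
            path = join(parent, name)
            if op == "create_dataset":
                shape = ((), (3,), (5,), (2, 3), (0,))[int(rng.integers(5))]
                dtype = ("float64", "int32", "bool")[int(rng.integers(3))]
                data = _random_array(rng, shape, dtype)
                program.append((op, path, data))
                nodes[path] = "dataset"
            else:
                program.append((op, path))
                if op == "create_raw":
                    nodes[path] = "raw"
                else:
                    nodes[path] = "group"
                    children[path] = set()
        elif op == "set_attr":
            paths = sorted(nodes)
            path = paths[int(rng.integers(len(paths)))]
            key = _random_key(rng)
            value = _random_value(rng, 2)
            program.append((op, path, key, value))
        elif op == "bulk_attrs":
            paths = sorted(nodes)
            path = paths[int(rng.integers(len(paths)))]
            program.append((op, path, random_document(rng, max_depth=2,
                                                      max_keys=4)))
        else:  # delete
            deletable = sorted(p for p in nodes if p != "/")
            if not deletable or rng.random() < 0.5:
                continue
            path = deletable[int(rng.integers(len(deletable)))]
            program.append((op, path))
            parent = path.rsplit("/", 1)[0] or "/"
            children[parent].discard(path.rsplit("/", 1)[1].lower())
            remove_subtree(path)
    return program


def canonical_value(value: Any) -> Any:
    """Hashable, comparison-stable form of an attribute value tree."""
    if isinstance(value, dict):
        return tuple(sorted((k, canonical_value(v)) for k, v in value.items()))
    if isinstance(value, (list, tuple)):
        return ("__seq__",) + tuple(canonical_value(v) for v in value)
    if isinstance(value, float) and np.isnan(value):
        return "__nan__"
    return (type(value).__name__, value)


def _canonical_data(array: np.ndarray | None):
    if array is None:
        return None
    arr = np.asarray(array)
    if arr.ndim > 0 and not arr.flags.c_contiguous:
        arr = np.ascontiguousarray(arr)
    if arr.dtype.byteorder == ">":
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    return (arr.shape, arr.dtype.str, arr.tobytes())


def replay_in_memory(program: list[tuple]) -> dict[str, tuple]:
    """Replay *program* on a plain nested map; return the canonical snapshot.

    This oracle knows nothing about directories, YAML or NPY: it is a dict of
    ``path -> (type, attrs, data)`` plus the subtree-delete rule.
    """
    nodes: dict[str, dict] = {"/": {"type": "file", "attrs": {}, "data": None}}
    for operation in program:
        op, path = operation[0], operation[1]
        if op in ("create_group", "require_group"):
            nodes.setdefault(path, {"type": "group", "attrs": {}, "data": None})
        elif op == "create_dataset":
            nodes[path] = {"type": "dataset", "attrs": {}, "data": operation[2]}
        elif op == "create_raw":
            nodes[path] = {"type": "raw", "attrs": {}, "data": None}
        elif op == "set_attr":
            nodes[path]["attrs"][operation[2]] = operation[3]
        elif op == "bulk_attrs":
            nodes[path]["attrs"] = dict(operation[2])
        elif op == "delete":
            for p in [p for p in nodes
                      if p == path or p.startswith(path + "/")]:
                del nodes[p]
    return {
        p: (n["type"], canonical_value(n["attrs"]), _canonical_data(n["data"]))
        for p, n in nodes.items()
    }


def replay_on_disk(program: list[tuple], group: Group) -> None:
    """Replay *program* through the public API rooted at *group*."""
    root = group
    for operation in program:
        op, path = operation[0], operation[1]
        relative = path.lstrip("/")
        if op == "create_group":
            root.create_group(relative)
        elif op == "require_group":
            root.require_group(relative)
        elif op == "create_dataset":
            root.create_dataset(relative, data=operation[2])
        elif op == "create_raw":
            root.create_raw(relative)
        elif op == "set_attr":
            obj = root if path == "/" else root[relative]
            obj.attrs[operation[2]] = operation[3]
        elif op == "bulk_attrs":
            obj = root if path == "/" else root[relative]
            obj.attrs = operation[2]
        elif op == "delete":
            parent_path, _, leaf = relative.rpartition("/")
            parent = root[parent_path] if parent_path else root
            del parent[leaf]


def snapshot_tree(root: str | os.PathLike) -> dict[str, tuple]:
    """Canonical ``path -> (type, attrs, data)`` snapshot of an on-disk tree."""
    f = File(root, mode="r")
    snapshot: dict[str, tuple] = {}

    def visit(obj) -> None:
        data = obj[...] if obj.object_type == "dataset" else None
        snapshot[obj.name if obj.relative_components else "/"] = (
            obj.object_type,
            canonical_value(obj.attrs.to_dict()),
            _canonical_data(data),
        )
        if obj.object_type in ("file", "group"):
            for name in obj:
                visit(obj[name])

    visit(f)
    return snapshot
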