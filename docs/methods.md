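# Methods

How the pieces of `exdirkit` are defined, what the defaults are, and what the
property suites check.

## Object model

Four object types map onto directories:

- **File** — the root; a specialization of Group. `exdir.yaml` declares
  `type: "file"`. A File may not contain another File: encountering a nested
  `file` type tag during lookup raises `TypeMismatchError`, and the linter
  reports it as the error `nested-file`.
- **Group** — directory with `exdir.yaml` (`type: "group"`), containing child
  object directories plus at most the two special files.
- **Dataset** — directory with `exdir.yaml` (`type: "dataset"`) and exactly
  one `data.npy` holding one n-dimensional array.
- **Raw** — directory of arbitrary foreign files. Its `exdir.yaml` is
  optional: a child directory with no `exdir.yaml` at all is classified as
  Raw on read, so external tools can drop directories into a tree without
  breaking it.

Reserved names (`exdir.yaml`, `attributes.yaml`, `data.npy`) are rejected as
object names. Open modes follow h5py: `r`, `r+`, `w` (truncate), `w-`/`x`
(create, fail if present), `a` (create or open). Mode `w` refuses to remove a
directory that is not itself a valid tree root, so a typo cannot delete an
unrelated directory.

Lookup is case-exact. Handles hold only (root, relative path); after their
directory is deleted they raise `StaleHandleError` rather than resurrecting
state. Deletion is `rmtree` — space returns to the OS immediately, which the
acceptance suite verifies by byte-counting the tree before and after deleting
an 8 MB dataset.

## Restricted YAML subset

Metadata files use YAML 1.2 restricted to what is needed for nested
key–value documents over seven value kinds: map, sequence, string, integer,
float, boolean, null.

Forbidden on write (and warned about on read): directives, anchors/aliases/
tags, complex (non-scalar) keys, plain-style *string values*, flow style,
empty keys, block scalars. Keys should match `[A-Za-z0-9_-]+`; keys outside
that set are emitted double-quoted with a warning. Empty maps and sequences
are not representable without flow style, so attempting to write one raises
`UnsupportedValueError`.

The **emitter** is deterministic: block style, two-space indent, insertion
order preserved, strings JSON-escaped in double quotes, floats via `repr`
(shortest round-trip form; `.nan`, `.inf`, `-.inf` for specials), booleans
`true`/`false`, null `null`. Keys that would re-read as a non-string scalar
(`true`, `32`, …) are quoted to preserve their kind. Determinism gives the
attribute batch-equivalence property: n single-key writes and one bulk
assignment of the same document produce byte-identical `attributes.yaml`.

The **parser** is built on PyYAML's event stream with Core-schema scalar
resolution implemented locally (PyYAML natively resolves YAML 1.1, which
differs on octals, `yes`/`no`, and sexagesimals). All subset violations are
collected as warnings with line numbers and rule ids; only malformed YAML or
a non-map top level is fatal. Duplicate keys keep the last value, with a
warning.

Closure property (checked at n=500): `parse_lenient(emit_restricted(d)) == d`
with zero warnings, and an independent general-purpose YAML parser
(`yaml.safe_load`) reads the emitted text to the same structure.

## Dataset storage

`data.npy` is written as NPY version 1.0, C-contiguous, little-endian,
regardless of the input array's layout, so any third-party NPY reader can
open it; version 2.0 is accepted on read. Writes are atomic: serialize to a
temporary sibling, fsync, rename. Object dtypes are rejected; structured
dtypes warn.

Reads are memory-mapped. Opening parses only the header (magic, dtype,
shape, order) and validates that the payload length matches; truncation
raises `CorruptDatasetError` at open time. Zero-size arrays are materialized
with `np.empty` since a zero-length mapping is impossible. Slicing, fancy
indexing and assignment delegate to the map, giving read-your-writes across
handles. `Dataset[...]`/`[slice]` reads raw stored values; `Dataset.data`
additionally runs the plugin read chain.

The test-suite oracle for conformance is a second NPY reader written
independently from the format description (struct-unpacked header length,
`ast.literal_eval` of the header dict, `np.frombuffer`), not
`numpy.lib.format`.

`create_dataset(name, shape=…, dtype=…, data=…)` requires `shape` or `data`;
with `shape` only, the dataset is zero-filled with default dtype `float64`.

## Name validation

- `thorough` (default): rejects names colliding case-insensitively with an
  existing sibling (ASCII folding), restricts characters to
  `[A-Za-z0-9_- .]`, and forbids leading/trailing spaces and dots — names
  that break on case-insensitive file systems (macOS, Windows) or in cloud
  sync.
- `minimal`: only exact-name existence and structural impossibilities
  (empty, `/`, NUL, `.`, `..`, reserved file names). Faster (no directory
  scan) and more permissive; portability is the user's problem.
- custom: any `callable(directory, name) -> bool`, wrapped so the structural
  checks always apply.

Soundness property (n=10,000 random creation sequences): any sequence of
names accepted by `thorough` case-folds to distinct names.

## Plugins

A plugin handler is pure: `prepare_write` maps a rich value to
(NPY-storable data, extra attributes, bookkeeping meta), `prepare_read`
inverts it. Handlers never touch the file system. Handlers run in ascending
`order_index` on write and descending on read, so chains invert correctly.
Handlers that transform a value record `{name, version}` under the reserved
`plugins` key of the object's `exdir.yaml` (keeping user attributes clean);
on read, a recorded plugin that is not registered raises
`MissingPluginError`, or warns and returns the raw stored data with
`on_missing_plugin="warn"`.

The bundled quantities plugin stores `Quantity(magnitude, unit)` as the
magnitude array plus a `unit` attribute (datasets) or a
`{"unit", "magnitude"}` map (attributes). A tree written with plugins enabled
is indistinguishable, to the linter and to plugin-unaware readers, from a
plain tree.

## Converter

`hdf5_to_exdir` / `exdir_to_hdf5` copy structure: group↔group,
dataset↔dataset, attribute↔attribute, payloads preserved bitwise (same shape
and dtype). Divergences are reported, never fatal:

- soft/external HDF5 links, compound and object dtypes → skipped with reason;
- nested map attributes (no HDF5 counterpart) → flattened to dotted keys
  (`daq.rate`; literal dots escaped `\.`), with `unflatten_attrs` as inverse;
- null / empty / mixed-kind sequence attributes → skipped;
- Raw objects → skipped (`raw_mode="skip"`, default) or stored as groups of
  opaque uint8 datasets (`raw_mode="opaque"`);
- fixed-width unicode datasets ↔ variable-length HDF5 strings, noted lossy;
- chunked/compressed HDF5 layouts materialized contiguously, noted lossy.

Round-trip property (n=50 seeded fixtures): HDF5 → tree → HDF5 gives
walk-identical files on links-free content.

## Linter

`lint_tree` walks a tree and separates **errors** (structural: bad or missing
type tags, nested files, missing/corrupt/non-NPY payloads, case collisions,
`data.npy` in a group, bad version) from **warnings** (YAML subset breaches,
stray files, unknown metadata keys) — mirroring strict-write/lenient-read.
A tree with warnings only is conformant.

## Fixture generator

All test inputs are generated, none downloaded. `TreeSpec(seed, …)` is a pure
recipe; per-node random streams are derived from `sha256(seed:path)`, so a
node's content does not depend on sibling generation order. Valid trees are
written through the public API; the five fault injections (truncated NPY, bad
type tag, case collision, flow-style YAML, missing metadata) bypass the API
deliberately. `random_program` emits always-valid operation sequences
(creates/attribute writes/deletes) that can be replayed both on disk and on a
plain nested dict, which serves as the structural round-trip oracle.

## Problem sizes in the test and acceptance suites

| Property | Size |
| --- | --- |
| structural round trip vs in-memory oracle | 500 programs, ≤ 50 ops, depth ≤ 4 |
| NPY conformance (independent reader) | 11 dtypes × 7 shapes incl. (100, 300, 100) |
| slicing equivalence with interleaved writes | 200 expressions per shape × 3 shapes |
| YAML closure + external parser | 500 random documents |
| case-rule soundness | 10,000 creation sequences |
| deletion reclaim | 10⁶ float64 (8 MB) |
| attribute batch equivalence | 200 keys |
| quantity plugin round trip | 100 values |
| converter round trip | 50 seeded HDF5 fixtures |

`scripts/acceptance.py --seed <int> --out <path>` recomputes all of these and
writes the rates/quantities as JSON.

## Limitations

- No file locking: concurrent writers to the same tree are undefined, as with
  most file-based formats.
- `thorough` case-folding is ASCII-only; full Unicode case rules are
  file-system-specific and out of scope.
- Attribute documents are rewritten whole per assignment; very large
  documents make single-key updates O(document).
- The converter ignores HDF5 chunking/compression settings (contents are
  preserved, layout is not).
- NPY structured dtypes are written with a warning but are outside the
  portable core.
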