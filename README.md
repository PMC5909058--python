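# exdirkit

A Python implementation of **Exdir** (Experimental Directory Structure): the
hierarchical data model of HDF5 — files, groups, datasets, attributes —
realized as ordinary file-system directories with human-readable YAML
metadata and NPY binary arrays.

## Why

Scientific pipelines need hierarchical storage with metadata, and HDF5's
abstract data model fits that need well. Its monolithic binary container is
the painful part: a localized corruption can take the whole file with it,
deleting a dataset does not reclaim space, nothing inside is visible without
special tools, and binary files defeat text-oriented infrastructure such as
version control, `diff` and `grep`.

Exdir keeps the model and drops the container. Every object is a directory:

```
experiment.exdir/            <- File (root)
├── exdir.yaml               <- object type + format version
├── attributes.yaml          <- optional user attributes (nested YAML)
└── session_001/             <- Group
    ├── exdir.yaml
    ├── attributes.yaml
    ├── lfp/                 <- Dataset
    │   ├── exdir.yaml
    │   └── data.npy         <- one n-dimensional array (NPY format)
    └── camera/              <- Raw: arbitrary foreign files
        ├── exdir.yaml
        └── frames.bin
```

Consequences fall out of the mapping for free: deletion is directory removal
(space returns to the OS immediately), corruption stays inside the one file
that was damaged, every piece of metadata is a text file you can read, edit
and version, and raw instrument output lives next to processed data inside
*Raw* objects without conversion.

The API follows h5py conventions (`create_group`, `create_dataset`, `attrs`,
`File(path, 'r'|'r+'|'w'|'w-'|'a')`, slicing), so moving code between the two
is mostly mechanical. Dataset access is memory-mapped: opening a dataset
parses a ~100-byte header, and slicing touches only the requested bytes.

## What is in the package

| Module | Role |
| --- | --- |
| `exdirkit.core` | `File` / `Group` / `Dataset` / `Raw` object model and attributes |
| `exdirkit.yamlio` | restricted-YAML emitter (strict) and parser (lenient) |
| `exdirkit.npyio` | NPY v1.0 writer, header parser, memory-mapped handles |
| `exdirkit.validation` | `thorough` / `minimal` / custom name-acceptance policies |
| `exdirkit.plugin_interface`, `exdirkit.plugins` | write/read transformation hooks; physical-quantity plugin |
| `exdirkit.converter` | bidirectional HDF5 ↔ Exdir structural converter |
| `exdirkit.lint` | conformance checker (structural errors, YAML-subset warnings) |
| `exdirkit.fixtures` | seeded generators of valid and deliberately broken trees |
| `exdirkit.cli` | `exdir` command: `ls`, `show`, `create`, `lint`, `convert`, `fixtures` |

## Worked example

```python
import numpy as np
from exdirkit import File

f = File("experiment.exdir", mode="w")
f.attrs["experimenter"] = "m. lab"

session = f.create_group("session_001")
session.attrs = {"probe": {"model": "A1x32", "channels": 32},
                 "depth_um": 800.0}

lfp = session.create_dataset("lfp", data=np.sin(np.linspace(0, 8, 1000)))
print(lfp.name, lfp.shape, lfp.dtype)
print(np.round(lfp[:5], 4))
print((session.directory / "attributes.yaml").read_text())
```

Output:

```
/session_001/lfp (1000,) float64
[0.    0.008 0.016 0.024 0.032]
probe:
  model: "A1x32"
  channels: 32
depth_um: 800.0
```

The `examples/` directory holds runnable narrative scripts: creating and
browsing a hierarchy, memory-mapped slicing of a 40 MB dataset, the
quantities plugin, and HDF5 conversion plus linting. Each prints the output
shown above when run directly.

The same operations are available from the shell; object paths are addressed
as `<root-directory>::<internal/path>`:

```bash
exdir ls experiment.exdir::session_001
exdir show experiment.exdir::session_001/lfp --limit 5
exdir lint experiment.exdir
exdir convert exdir2hdf experiment.exdir out.h5
```

## Design notes

- **Metadata** uses a restricted YAML 1.2 subset (block style only, quoted
  string values, Core-schema scalars, no anchors/tags/directives). Writing is
  strict and deterministic — the same document always produces the same bytes
  — while reading is lenient: hand-edited files that stray from the subset
  still parse, with warnings. `docs/methods.md` gives the precise rules.
- **Datasets** are NPY v1.0, C-contiguous, little-endian, so any third-party
  NPY reader can open them; writes are atomic (temp file + rename).
- **Name validation** defaults to `thorough` (case-insensitive uniqueness and
  a portable character set, so trees survive the trip between case-sensitive
  and case-insensitive file systems); `minimal` trades safety for speed.

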