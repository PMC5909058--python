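"""Convert an HDF5 file to a directory tree and back, then lint it.

The converter is structural: groups map to groups, datasets to datasets,
attributes to attributes, and anything without a counterpart is skipped or
flattened with an entry in the conversion report.
"""

import shutil
import tempfile
from pathlib import Path

import h5py
import numpy as np

from exdirkit.converter import exdir_to_hdf5, hdf5_to_exdir
from exdirkit.lint import lint_tree

workdir = Path(tempfile.mkdtemp(prefix="exdir-example-"))

# a small HDF5 source, including a soft link the tree format cannot hold
src = workdir / "source.h5"
with h5py.File(src, "w") as h5:
    h5.attrs["origin"] = "legacy pipeline"
    g = h5.create_group("session")
    g.create_dataset("spikes", data=np.random.default_rng(1).poisson(3, 50))
    h5["alias"] = h5py.SoftLink("/session/spikes")

report = hdf5_to_exdir(src, workdir / "converted.exdir")
print("-- hdf5 -> tree --")
print(report.render())

report = lint_tree(workdir / "converted.exdir")
print("\n-- lint --")
print(report.render())

back = workdir / "back.h5"
report = exdir_to_hdf5(workdir / "converted.exdir", back)
print("\n-- tree -> hdf5 --")
print(report.render())
with h5py.File(back, "r") as h5:
    print("payload intact:", h5["session/spikes"].shape)

shutil.rmtree(workdir)
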