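"""Slice a large dataset without loading it.

Dataset reads go through a memory map: opening parses only the NPY header,
and indexing touches only the requested bytes. Writes through a handle are
immediately visible to fresh handles on the same file.
"""

import shutil
import tempfile
from pathlib import Path

import numpy as np

from exdirkit import File

workdir = Path(tempfile.mkdtemp(prefix="exdir-example-"))
f = File(workdir / "big.exdir", mode="w")

# 100 channels x 100k samples of float32: ~40 MB on disk
data = np.random.default_rng(0).standard_normal((100, 100_000)).astype("float32")
d = f.create_dataset("recording", data=data)
print("stored:", d.shape, d.dtype)

# read a narrow window: only those bytes are touched
window = d[10:12, 5000:5010]
print("window:\n", np.round(window, 3))

# in-place edit of a single channel, then verify through a fresh file handle
d[7, :] = 0.0
fresh = File(workdir / "big.exdir", mode="r")
print("channel 7 zeroed:", bool(np.all(fresh["recording"][7, :5] == 0)))

# fancy indexing works the same as on an in-memory array
picks = d[np.array([3, 1, 4]), 0]
print("picked channels at t=0:", np.round(picks, 3))

shutil.rmtree(workdir)
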