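"""Create a small experiment hierarchy and browse it.

A File is a directory on disk; every group is a subdirectory, every dataset
a subdirectory holding one ``data.npy``, and attributes live in plain
``attributes.yaml`` files you can open in any text editor.
"""

import shutil
import tempfile
from pathlib import Path

import numpy as np

from exdirkit import File

workdir = Path(tempfile.mkdtemp(prefix="exdir-example-"))
root = workdir / "experiment.exdir"

# -- build -------------------------------------------------------------------
f = File(root, mode="w")
f.attrs["experimenter"] = "m. lab"
f.attrs["room_temperature_c"] = 21.5

session = f.create_group("session_001")
session.attrs = {"probe": {"model": "A1x32", "channels": 32},
                 "depth_um": 800.0}

lfp = session.create_dataset("lfp", data=np.sin(np.linspace(0, 8, 1000)))
lfp.attrs["sample_rate_hz"] = 30000.0

raw = session.create_raw("camera")
(raw.directory / "frames.bin").write_bytes(b"\x00" * 256)  # any foreign file

# -- browse ------------------------------------------------------------------
print("root attributes:", dict(f.attrs.to_dict()))
for name in f:
    print("child:", name, "->", f[name].object_type)

ds = f["session_001/lfp"]
print("dataset:", ds.name, ds.shape, ds.dtype)
print("first five samples:", np.round(ds[:5], 4))

# the metadata really is plain text:
print("\nsession_001/attributes.yaml:")
print((session.directory / "attributes.yaml").read_text(), end="")

shutil.rmtree(workdir)
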