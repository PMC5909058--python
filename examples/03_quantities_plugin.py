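"""Store values with physical units via the quantities plugin.

Plugins transform rich in-memory values into storable data plus attributes on
write, and reconstruct them on read — the on-disk layout stays plain NPY and
YAML, readable by any tool that knows nothing about the plugin.
"""

import shutil
import tempfile
from pathlib import Path

import numpy as np

from exdirkit import File
from exdirkit.plugins import Quantity, quantities

workdir = Path(tempfile.mkdtemp(prefix="exdir-example-"))
root = workdir / "units.exdir"

f = File(root, mode="w", plugins=quantities())
f.create_dataset("membrane_potential", data=Quantity(np.array([-65.0, -64.8, -70.1]), "mV"))
f.attrs["electrode_depth"] = Quantity(800.0, "um")

# reread with the plugin registered: full Quantity objects come back
out = File(root, mode="r", plugins=quantities())
v = out["membrane_potential"].data
print("value:", v.magnitude, v.unit)
print("depth:", out.attrs["electrode_depth"])

# without the plugin the stored form is still ordinary data + attributes
plain = File(root, mode="r", on_missing_plugin="warn")
print("plain unit attribute:", plain["membrane_potential"].attrs["unit"])

shutil.rmtree(workdir)
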