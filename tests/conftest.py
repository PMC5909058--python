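import numpy as np
import pytest

import exdirkit


@pytest.fixture
def root(tmp_path):
    """A fresh writable File root."""
    return exdirkit.File(tmp_path / "test.exdir", mode="w-")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
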