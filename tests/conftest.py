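import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_study  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def two_group_study(rng):
    """20 genes, 6+6 samples, first 5 genes shifted by +2 in the exposed group."""
    n_genes, n_per = 20, 6
    mat = rng.normal(7.0, 0.3, size=(n_genes, 2 * n_per))
    mat[:5, :n_per] += 2.0
    return make_study(mat, ["exposed"] * n_per + ["control"] * n_per)
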