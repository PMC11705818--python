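import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mycoscan import AbundanceTable

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_table():
    """4 samples x 3 taxa TPM table with known structure."""
    data = pd.DataFrame(
        {
            "tax1": [500_000.0, 400_000.0, 600_000.0, 550_000.0],
            "tax2": [300_000.0, 350_000.0, 250_000.0, 300_000.0],
            "tax3": [200_000.0, 250_000.0, 150_000.0, 150_000.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    kingdom = pd.Series(
        ["fungal", "fungal", "bacterial"], index=["tax1", "tax2", "tax3"]
    )
    return AbundanceTable(data, kingdom=kingdom)
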