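"""Small shared builders for test data."""

import pandas as pd

from mycoscan import AbundanceTable
from mycoscan.tables import TPM_SCALE


def random_tpm_table(rng, n_samples=20, n_taxa=10, zero_frac=0.0):
    """Random valid TPM table; optionally sparsified before closure."""
    x = rng.lognormal(0.0, 1.0, size=(n_samples, n_taxa))
    if zero_frac > 0:
        x[rng.random(x.shape) < zero_frac] = 0.0
    keep = x.sum(axis=1) > 0
    x = x[keep]
    x = x / x.sum(axis=1, keepdims=True) * TPM_SCALE
    return AbundanceTable(
        pd.DataFrame(
            x,
            index=[f"s{i}" for i in range(x.shape[0])],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )
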