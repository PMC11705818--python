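"""Core in-memory containers shared across the pipeline.

The central object is :class:`AbundanceTable`: a samples × taxa matrix on
the per-million (TPM) scale — every non-empty row sums to 1,000,000 — with
optional per-taxon kingdom labels and a taxonomy lineage table used for
rank roll-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TPM_SCALE = 1_000_000.0
RANKS = ("genus", "family", "order", "class", "subphylum")


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix on the TPM scale.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and taxon ids as columns.
        Rows are expected to sum to one million; rows with no assigned
        reads may be all-zero and are reported by :meth:`empty_samples`.
    kingdom:
        Optional per-taxon label, e.g. ``"fungal"`` / ``"bacterial"``.
    taxonomy:
        Optional lineage table indexed by taxon (species) id with columns
        from :data:`RANKS`.
    """

    data: pd.DataFrame
    kingdom: pd.Series | None = None
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.kingdom is not None:
            self.kingdom = self.kingdom.reindex(self.data.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def empty_samples(self) -> list[str]:
        """Samples with zero total abundance (no assigned reads)."""
        sums = self.row_sums()
        return list(sums.index[sums == 0])

    def to_fraction(self) -> pd.DataFrame:
        """Matrix rescaled from per-million to fractions summing to 1."""
        return self.data / TPM_SCALE

    def validate(self, tol: float = 1e-3) -> None:
        """Check the TPM closure invariant on every non-empty row."""
        sums = self.row_sums().to_numpy()
        nonempty = sums > 0
        if nonempty.any():
            dev = np.abs(sums[nonempty] - TPM_SCALE)
            if dev.max() > tol:
                bad = np.asarray(self.samples)[nonempty][dev > tol]
                raise ValueError(
                    f"rows do not sum to one million (tol {tol}): {list(bad[:5])}"
                )

    def subset_taxa(self, taxa) -> "AbundanceTable":
        taxa = [t for t in taxa if t in self.data.columns]
        return AbundanceTable(
            data=self.data[taxa].copy(),
            kingdom=None if self.kingdom is None else self.kingdom[taxa],
            taxonomy=self.taxonomy,
        )


@dataclass
class TaxonomyTable:
    """Species → lineage map with the five ranks used for roll-ups."""

    lineages: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise ValueError(f"taxonomy table missing ranks: {missing}")
        self.lineages = self.lineages.fillna("unclassified")

    def lineage_for(self, species: str, rank: str) -> str:
        return str(self.lineages.loc[species, rank])

    @property
    def species(self) -> list[str]:
        return list(self.lineages.index)
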