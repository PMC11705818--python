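"""Read decontamination, genome assignment, and TPM abundance profiles.

Reads surviving QC are screened against decoy references (host genome,
prokaryotic catalog, rRNA database — any FASTA set), the remainder is
assigned to catalog genomes by shared canonical k-mers, and per-genome
counts are normalized by genome size and closed to the per-million (TPM)
scale: r_g = c_g / L_g, TPM_g = 1e6 · r_g / Σ_h r_h. Genome-size
normalization is the step that converts read fractions (which scale with
genome length) into abundance fractions.

Precomputed alignments (SAM best hits or a TSV) can replace the internal
k-mer matcher via :func:`mycoscan.io_formats.read_best_hits`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._kmers import kmer_ints, kmer_set
from .io_formats import ReadAssignmentTable, ReadPair, SequenceSet
from .tables import RANKS, TPM_SCALE, AbundanceTable, TaxonomyTable

__all__ = [
    "AbundanceTable",
    "TaxonomyTable",
    "KmerIndex",
    "decontaminate_reads",
    "assign_reads",
    "normalize_tpm",
    "aggregate_taxa",
    "profile_samples",
]


@dataclass
class KmerIndex:
    """Canonical k-mer → genome bitmask index over a genome catalog."""

    k: int
    genome_ids: list[str]
    lookup: dict[int, int] = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, catalog_fasta: SequenceSet, k: int = 31) -> "KmerIndex":
        ids = catalog_fasta.ids
        lookup: dict[int, int] = {}
        for gi, (_, seq) in enumerate(catalog_fasta):
            bit = 1 << gi
            for km in np.unique(kmer_ints(seq, k)).tolist():
                lookup[km] = lookup.get(km, 0) | bit
        return cls(k=k, genome_ids=ids, lookup=lookup)

    def score_pair(self, pair: ReadPair) -> np.ndarray:
        """Per-genome count of shared distinct canonical k-mers over both
        mates."""
        kms = np.unique(
            np.concatenate(
                [kmer_ints(pair.seq1, self.k), kmer_ints(pair.seq2, self.k)]
            )
        )
        counts = np.zeros(len(self.genome_ids), dtype=np.int64)
        get = self.lookup.get
        for km in kms.tolist():
            mask = get(km, 0)
            while mask:
                low = mask & -mask
                counts[low.bit_length() - 1] += 1
                mask ^= low
        return counts


def decontaminate_reads(
    pairs: Iterable[ReadPair],
    decoys: SequenceSet | None,
    k: int = 31,
    hit_frac: float = 0.5,
) -> tuple[list[ReadPair], int]:
    """Remove pairs matching a decoy reference.

    A pair is removed when either mate has at least ``hit_frac`` of its
    canonical k-mers in the decoy index. An empty decoy set passes
    everything through with a warning.
    """
    pairs = list(pairs)
    if decoys is None or len(decoys) == 0:
        warnings.warn("empty decoy set: no reads removed", stacklevel=2)
        return pairs, 0
    index = kmer_set([s for _, s in decoys], k)
    retained: list[ReadPair] = []
    removed = 0
    for pair in pairs:
        hit = False
        for seq in (pair.seq1, pair.seq2):
            kms = np.unique(kmer_ints(seq, k))
            if kms.size == 0:
                continue
            n_hit = sum(1 for km in kms.tolist() if km in index)
            if n_hit / kms.size >= hit_frac:
                hit = True
                break
        if hit:
            removed += 1
        else:
            retained.append(pair)
    return retained, removed


def assign_reads(
    pairs: Iterable[ReadPair],
    catalog_fasta: SequenceSet | KmerIndex,
    k: int = 31,
) -> ReadAssignmentTable:
    """Assign each pair to the unique top-scoring catalog genome.

    The score is the number of distinct canonical k-mers the pair shares
    with each genome. Pairs with no hit at all, or whose top score is
    tied between genomes, are discarded (tallied as ambiguous), mirroring
    the best-hit tie rule for external alignments.
    """
    index = (
        catalog_fasta
        if isinstance(catalog_fasta, KmerIndex)
        else KmerIndex.build(catalog_fasta, k)
    )
    rows = []
    ambiguous = 0
    for pair in pairs:
        counts = index.score_pair(pair)
        top = counts.max() if counts.size else 0
        if top == 0:
            ambiguous += 1
            continue
        winners = np.flatnonzero(counts == top)
        if winners.size > 1:
            ambiguous += 1
            continue
        rows.append((pair.read_id, index.genome_ids[int(winners[0])], float(top)))
    df = pd.DataFrame(rows, columns=["read_id", "genome_id", "score"])
    return ReadAssignmentTable(df, n_ambiguous=ambiguous)


def normalize_tpm(
    counts: dict[str, float], genome_sizes: dict[str, float]
) -> dict[str, float]:
    """Genome-size-normalized TPM.

    Each count is divided by its genome size; the normalized counts are
    rescaled to sum to one million. All-zero input yields all-zero output
    (the caller flags such samples).
    """
    missing = [g for g in counts if g not in genome_sizes]
    if missing:
        raise KeyError(f"no genome size for: {missing}")
    rates = {g: c / genome_sizes[g] for g, c in counts.items()}
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in counts}
    return {g: TPM_SCALE * r / total for g, r in rates.items()}


def aggregate_taxa(
    table: AbundanceTable, taxonomy: TaxonomyTable, rank: str
) -> AbundanceTable:
    """Roll species-level abundances up to a higher rank by column sums.

    The abundance of a taxon is the sum of the abundances of all species
    assigned to it, so row sums are preserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    missing = [t for t in table.taxa if t not in taxonomy.lineages.index]
    if missing:
        raise KeyError(f"species without lineage rows: {missing}")
    mapping = {t: taxonomy.lineage_for(t, rank) for t in table.taxa}
    agg = table.data.T.groupby(table.data.columns.map(mapping)).sum().T
    agg.columns.name = None
    kingdom = None
    if table.kingdom is not None:
        kingdom = table.kingdom.groupby(table.data.columns.map(mapping)).first()
        kingdom = kingdom.reindex(agg.columns)
    return AbundanceTable(agg, kingdom=kingdom, taxonomy=table.taxonomy)


def profile_samples(
    samples: list[tuple[str, list[ReadPair]]],
    catalog: SequenceSet,
    genome_to_species: dict[str, str] | None = None,
    taxonomy: TaxonomyTable | None = None,
    decoys: SequenceSet | None = None,
    k: int = 31,
    qc: bool = True,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Full per-sample profiling: read QC → decoy removal → genome
    assignment → size-normalized TPM.

    ``samples`` holds (sample_id, read pairs). Genomes map to species
    via ``genome_to_species`` (identity when omitted). Returns the
    species-level table plus per-sample stage statistics; a sample that
    fails a stage is reported in the stats and its row left all-zero.
    """
    from .read_qc import filter_pairs

    sizes = {name: float(len(seq)) for name, seq in catalog}
    index = KmerIndex.build(catalog, k)
    g2s = genome_to_species or {name: name for name in catalog.ids}
    species = sorted(set(g2s.values()))

    rows = {}
    stats = []
    for sample_id, pairs in samples:
        stat = {"sample_id": sample_id}
        try:
            kept = list(pairs)
            stat["input_pairs"] = len(kept)
            if qc:
                kept, report = filter_pairs(kept)
                stat["qc_passed"] = report.passed_pairs
            if decoys is not None and len(decoys) > 0:
                kept, n_removed = decontaminate_reads(kept, decoys, k)
                stat["decoy_removed"] = n_removed
            assignments = assign_reads(kept, index, k)
            stat["assigned"] = len(assignments.df)
            stat["ambiguous"] = assignments.n_ambiguous
            counts = assignments.counts_per_genome().to_dict()
            tpm = normalize_tpm(
                {g: counts.get(g, 0) for g in catalog.ids}, sizes
            )
            by_species = {s: 0.0 for s in species}
            for g, v in tpm.items():
                by_species[g2s[g]] += v
            rows[sample_id] = by_species
            stat["status"] = "ok" if sum(by_species.values()) > 0 else "empty"
        except Exception as exc:  # keep profiling the remaining samples
            stat["status"] = f"failed: {exc}"
            rows[sample_id] = {s: 0.0 for s in species}
        stats.append(stat)

    data = pd.DataFrame.from_dict(rows, orient="index")[species]
    data.index.name = None
    table = AbundanceTable(
        data,
        kingdom=pd.Series("fungal", index=species),
        taxonomy=None if taxonomy is None else taxonomy.lineages,
    )
    return table, pd.DataFrame(stats)
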