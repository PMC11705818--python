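"""Non-redundant species-level genome catalog curation.

Assembly QC (N50 / scaffold-count filters), k-mer based bacterial
decontamination of scaffolds, MinHash ANI estimation, and greedy
representative-linkage clustering at the 95% ANI species boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import kmer_set, minhash_sketch
from .io_formats import SequenceSet


@dataclass
class GenomeRecord:
    """A named assembly: scaffold sequences plus derived QC statistics."""

    id: str
    scaffolds: list[str]
    total_len: int = 0
    n_scaffolds: int = 0
    n50: int = 0

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise ValueError(f"genome {self.id} has no scaffolds")
        self.total_len, self.n_scaffolds, self.n50 = assembly_stats_raw(self.scaffolds)

    @classmethod
    def from_sequence_set(cls, seqs: SequenceSet, genome_id: str) -> "GenomeRecord":
        return cls(id=genome_id, scaffolds=[s for _, s in seqs])

    def concatenated(self) -> str:
        return "".join(self.scaffolds)


@dataclass
class SpeciesCluster:
    representative: str
    members: list[str]
    rep_rule: str = "max_n50"

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its cluster")


def assembly_stats_raw(scaffolds: list[str]) -> tuple[int, int, int]:
    lengths = sorted((len(s) for s in scaffolds), reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= half:
            n50 = L
            break
    return total, len(lengths), n50


def assembly_stats(g: GenomeRecord) -> tuple[int, int, int]:
    """(total length, scaffold count, N50). N50 is the length of the
    scaffold at which the descending cumulative sum first reaches half of
    the total assembly length."""
    return assembly_stats_raw(g.scaffolds)


def qc_filter(
    genomes: list[GenomeRecord],
    min_n50: int = 2000,
    max_scaffolds: int = 10_000,
) -> tuple[list[GenomeRecord], list[tuple[GenomeRecord, list[str]]]]:
    """Drop extremely low-quality assemblies.

    A genome is removed iff N50 < ``min_n50`` OR scaffold count >
    ``max_scaffolds`` (both inequalities strict, so the boundary values
    2000 / 10000 are retained). Removed genomes carry their reason tags.
    """
    retained, removed = [], []
    for g in genomes:
        reasons = []
        if g.n50 < min_n50:
            reasons.append("n50")
        if g.n_scaffolds > max_scaffolds:
            reasons.append("scaffolds")
        if reasons:
            removed.append((g, reasons))
        else:
            retained.append(g)
    return retained, removed


def decontaminate_scaffolds(
    g: GenomeRecord,
    bacterial_ref: SequenceSet,
    k: int = 31,
    frac_threshold: float = 0.5,
    index: set[int] | None = None,
) -> GenomeRecord | None:
    """Drop scaffolds matching a bacterial reference.

    A scaffold is removed when at least ``frac_threshold`` of its
    canonical k-mers occur in the bacterial k-mer index. Returns a new
    record with recomputed stats, or ``None`` when every scaffold was
    bacterial (the genome leaves the catalog). A prebuilt ``index``
    (from :func:`mycoscan._kmers.kmer_set`) skips re-indexing across calls.
    """
    if index is None:
        index = kmer_set([s for _, s in bacterial_ref], k)
    kept = []
    for scaf in g.scaffolds:
        kmers = kmer_set(scaf, k)
        if not kmers:
            kept.append(scaf)
            continue
        frac = len(kmers & index) / len(kmers)
        if frac < frac_threshold:
            kept.append(scaf)
    if not kept:
        return None
    return GenomeRecord(id=g.id, scaffolds=kept)


def estimate_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 21,
    sketch: int = 2000,
) -> float:
    """Mash-style ANI from bottom-sketch MinHash Jaccard.

    j is estimated from the bottom-s sketch of the union; the Mash
    distance d = -(1/k)·ln(2j/(1+j)) is converted to ANI = 1 - d, clamped
    to [0, 1]. Symmetric by construction. j = 0 reports ANI 0.
    """
    sa = minhash_sketch(a.scaffolds, k, sketch)
    sb = minhash_sketch(b.scaffolds, k, sketch)
    merged = np.union1d(sa, sb)[:sketch]
    shared = np.intersect1d(sa, sb, assume_unique=True)
    inter = np.intersect1d(merged, shared, assume_unique=True).size
    if merged.size == 0 or inter == 0:
        return 0.0
    j = inter / merged.size
    d = -(1.0 / k) * np.log(2.0 * j / (1.0 + j))
    return float(min(1.0, max(0.0, 1.0 - d)))


def cluster_species(
    genomes: list[GenomeRecord],
    ani_threshold: float = 0.95,
    k: int = 21,
    sketch: int = 2000,
) -> list[SpeciesCluster]:
    """Greedy representative-linkage clustering (dRep-style).

    Genomes are visited by (N50 desc, total length desc, id asc) so the
    best assemblies found clusters; each genome joins the first cluster
    whose representative it matches at ANI ≥ threshold, else founds its
    own. The result partitions the input and is independent of input
    order (the sort key is total).
    """
    order = sorted(genomes, key=lambda g: (-g.n50, -g.total_len, g.id))
    clusters: list[SpeciesCluster] = []
    reps: dict[str, GenomeRecord] = {}
    for g in order:
        placed = False
        for c in clusters:
            if estimate_ani(g, reps[c.representative], k=k, sketch=sketch) >= ani_threshold:
                c.members.append(g.id)
                placed = True
                break
        if not placed:
            clusters.append(SpeciesCluster(representative=g.id, members=[g.id]))
            reps[g.id] = g
    return clusters


def catalog_table(clusters: list[SpeciesCluster], genomes: list[GenomeRecord]):
    """Flat per-genome catalog rows: (genome_id, cluster_id,
    representative_flag, n50, n_scaffolds, total_len)."""
    import pandas as pd

    by_id = {g.id: g for g in genomes}
    rows = []
    for ci, c in enumerate(clusters, start=1):
        for m in c.members:
            g = by_id[m]
            rows.append(
                (m, f"c{ci}", m == c.representative, g.n50, g.n_scaffolds, g.total_len)
            )
    return pd.DataFrame(
        rows,
        columns=["genome_id", "cluster_id", "representative_flag",
                 "n50", "n_scaffolds", "total_len"],
    )
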