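"""Readers and writers for every on-disk artifact the pipeline touches.

FASTA/FASTQ (Phred+33, gzip accepted by extension), SAM/TSV best-hit
tables, TSV abundance and taxonomy tables, and network export as an edge
list plus GraphML. All text I/O is UTF-8.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import networkx as nx
import pandas as pd
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .tables import RANKS, AbundanceTable, TaxonomyTable

_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message names the offending line/record."""


@dataclass
class SequenceSet:
    """Ordered collection of named DNA sequences with unique ids."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for name, seq in self.records:
            if name in seen:
                raise ValueError(f"duplicate sequence id: {name}")
            seen.add(name)
            if not seq:
                raise ValueError(f"empty sequence: {name}")
            extra = set(seq) - _ALPHABET
            if extra:
                raise ValueError(
                    f"sequence {name} contains non-ACGTN symbols: {sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.records]

    def get(self, name: str) -> str:
        for rid, seq in self.records:
            if rid == name:
                return seq
        raise KeyError(name)


class ReadPair(NamedTuple):
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class ReadAssignmentTable:
    """One best-hit genome per read; ambiguous reads are counted, not kept."""

    df: pd.DataFrame  # columns: read_id, genome_id, score
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if list(self.df.columns) != ["read_id", "genome_id", "score"]:
            raise ValueError("expected columns read_id, genome_id, score")
        if self.df["read_id"].duplicated().any():
            raise ValueError("more than one row per read_id")
        if (self.df["score"] < 0).any():
            raise ValueError("negative alignment score")

    def counts_per_genome(self) -> pd.Series:
        return self.df.groupby("genome_id").size()


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8" if "t" in mode else None)
    return open(path, mode, encoding="utf-8")


def read_fasta(path, on_invalid: str = "mask") -> SequenceSet:
    """Parse a FASTA file into a :class:`SequenceSet`.

    Sequence lines are concatenated and upper-cased. Symbols outside
    {A,C,G,T,N} are N-masked (``on_invalid="mask"``, default) or rejected
    (``on_invalid="error"``). Malformed headers and empty records raise
    :class:`ParseError` naming the line number.
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    name_line = 0

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"empty sequence: {name} (line {name_line})")
        extra = set(seq) - _ALPHABET
        if extra:
            if on_invalid == "error":
                raise ParseError(
                    f"record {name}: non-ACGTN symbols {sorted(extra)[:5]}"
                )
            seq = "".join(b if b in _ALPHABET else "N" for b in seq)
        records.append((name, seq))

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"malformed FASTA header at line {lineno}")
                name_line = lineno
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"sequence data before first header at line {lineno}"
                    )
                chunks.append(line)
        flush()
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _base_read_id(title: str) -> str:
    rid = title.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files matched by record order.

    Mate ids must agree after stripping a trailing ``/1`` / ``/2``;
    a mismatch, or trailing unpaired records in either file, raises
    :class:`ParseError`. Qualities are Phred+33 as stored.
    """
    with _open_text(path_r1) as fh1, _open_text(path_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        n = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                # count the stragglers in the longer file
                leftover = 1 + sum(1 for _ in (it1 if rec2 is None else it2))
                side = "R1" if rec2 is None else "R2"
                raise ParseError(
                    f"{leftover} unpaired trailing record(s) in {side} "
                    f"after {n} pairs"
                )
            n += 1
            id1, id2 = _base_read_id(rec1[0]), _base_read_id(rec2[0])
            if id1 != id2:
                raise ParseError(
                    f"mate id mismatch at pair {n}: {id1!r} vs {id2!r}"
                )
            for title, seq, qual in (rec1, rec2):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"sequence/quality length mismatch for {title}"
                    )
            yield ReadPair(id1, rec1[1].upper(), rec1[2], rec2[1].upper(), rec2[2])


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1, path_r2) -> None:
    with _open_text(path_r1, "wt") as f1, _open_text(path_r2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def phred_scores(qual: str) -> list[int]:
    """Phred+33 quality string to integer scores."""
    return [ord(c) - 33 for c in qual]


def _best_hits_from_frame(df: pd.DataFrame, prior_ambiguous: int = 0) -> ReadAssignmentTable:
    """Reduce a (read_id, genome_id, score) frame to unique best hits,
    discarding reads whose top score is tied between genomes."""
    rows = []
    ambiguous = prior_ambiguous
    for read_id, grp in df.groupby("read_id", sort=False):
        top = grp["score"].max()
        winners = grp[grp["score"] == top]
        if len(winners["genome_id"].unique()) > 1:
            ambiguous += 1
            continue
        rows.append((read_id, winners.iloc[0]["genome_id"], float(top)))
    out = pd.DataFrame(rows, columns=["read_id", "genome_id", "score"])
    return ReadAssignmentTable(out, n_ambiguous=ambiguous)


def read_best_hits(path, format: str = "tsv") -> ReadAssignmentTable:
    """Load read→genome assignments from a SAM file or a 3-column TSV.

    SAM records that are unmapped, secondary or supplementary are
    dropped; the alignment score is the ``AS`` tag when present, else
    MAPQ. Reads whose best score is tied between different genomes are
    discarded as ambiguous (conservative: non-specific mappings carry no
    abundance signal).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0)
        if list(df.columns[:3]) != ["read_id", "genome_id", "score"]:
            raise ParseError(
                "TSV must have header columns read_id, genome_id, score"
            )
        return _best_hits_from_frame(df[["read_id", "genome_id", "score"]])
    if format == "sam":
        rows = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                score = rec.get_tag("AS") if rec.has_tag("AS") else rec.mapping_quality
                rows.append((rec.query_name, rec.reference_name, float(score)))
        df = pd.DataFrame(rows, columns=["read_id", "genome_id", "score"])
        return _best_hits_from_frame(df)
    raise ValueError(f"unknown format: {format}")


# ---------------------------------------------------------------------------
# abundance / taxonomy / group tables

def _fmt6(x: float) -> str:
    if x == 0:
        return "0"
    return f"{x:.6g}"


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Samples as rows, taxa as columns, first column ``sample_id``;
    numbers serialized with 6 significant digits."""
    df = table.data.copy()
    df.insert(0, "sample_id", df.index)
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            cells = [str(row.iloc[0])] + [_fmt6(v) for v in row.iloc[1:]]
            fh.write("\t".join(cells) + "\n")


def read_abundance_table(path, kingdom: pd.Series | None = None,
                         taxonomy: TaxonomyTable | None = None) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", header=0)
    df = df.set_index("sample_id")
    df.index.name = None
    df.columns.name = None
    return AbundanceTable(
        df.astype(float),
        kingdom=kingdom,
        taxonomy=None if taxonomy is None else taxonomy.lineages,
    )


def read_taxonomy(path) -> TaxonomyTable:
    """TSV with columns species_id, genus, family, order, class, subphylum."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if "species_id" not in df.columns:
        raise ParseError("taxonomy TSV must have a species_id column")
    df = df.set_index("species_id")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ParseError(f"taxonomy TSV missing rank columns: {missing}")
    return TaxonomyTable(df)


def read_groups(path) -> pd.Series:
    """TSV with columns sample_id, group → Series mapping sample → group."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ParseError("groups TSV must have columns sample_id, group")
    return df.set_index("sample_id")["group"]


# ---------------------------------------------------------------------------
# network export

def write_network(net, path_edges, path_graphml) -> None:
    """Write a co-occurrence network as an edge-list TSV (source, target,
    weight, sign) and as GraphML with node attributes kingdom and degree."""
    with _open_text(path_edges, "wt") as fh:
        fh.write("source\ttarget\tweight\tsign\n")
        for i, j, w in net.edges:
            sign = "+" if w >= 0 else "-"
            fh.write(f"{i}\t{j}\t{w:.6g}\t{sign}\n")
    g = net.to_networkx()
    nx.write_graphml(g, str(path_graphml))


def read_network(path_graphml):
    """Round-trip companion of :func:`write_network` (GraphML side)."""
    from .conetwork import CoNetwork  # deferred: conetwork builds on tables only

    g = nx.read_graphml(str(path_graphml))
    nodes = {str(n): str(d.get("kingdom", "unknown")) for n, d in g.nodes(data=True)}
    edges = []
    for u, v, d in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        edges.append((a, b, float(d.get("weight", 0.0))))
    edges.sort()
    threshold = float(g.graph.get("threshold", 0.0))
    return CoNetwork(nodes=nodes, edges=edges, threshold=threshold)
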