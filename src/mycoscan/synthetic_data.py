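"""Synthetic genomes, reads and two-group abundance studies with ground truth.

Every generator is deterministic given its seed and returns, alongside the
data, a :class:`SyntheticTruth` recording the parameters that were planted
(composition, fold changes, correlation blocks, per-read origins), so every
downstream stage of the pipeline can be tested against a known answer
without downloading anything.

The abundance model is log-normal per taxon — the standard null for
relative-abundance microbiome data. Differential abundance is planted by
multiplying the enriched group's mean by a fold change; co-occurrence
structure is planted through one shared latent factor per block on the log
scale (rank-preserved through exponentiation), and rows are closed to the
per-million (TPM) scale at the end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import reverse_complement
from .io_formats import ReadPair, SequenceSet
from .tables import TPM_SCALE, AbundanceTable

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Ground-truth parameters emitted with every simulated dataset."""

    seed: int
    composition: dict[str, float] = field(default_factory=dict)
    planted_diff: dict[str, tuple[float, str]] = field(default_factory=dict)
    corr_blocks: list[tuple[list[str], float]] = field(default_factory=list)
    read_origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition sums to {total}, not 1")
            if any(not 0 <= f <= 1 for f in self.composition.values()):
                raise ValueError("composition fractions must lie in [0, 1]")
        for taxon, (fc, _grp) in self.planted_diff.items():
            if fc <= 0:
                raise ValueError(f"fold change for {taxon} must be positive")
        for members, corr in self.corr_blocks:
            if not -1 < corr < 1:
                raise ValueError("block correlation must lie in (-1, 1)")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "composition": self.composition,
            "planted_diff": {t: list(v) for t, v in self.planted_diff.items()},
            "corr_blocks": [[m, c] for m, c in self.corr_blocks],
            "read_origin": self.read_origin,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def simulate_genomes(n: int, length: int, gc: float = 0.45,
                     seed: int = 0, prefix: str = "g") -> SequenceSet:
    """``n`` i.i.d. random genomes of the given length and GC content."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i in range(n):
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        records.append((f"{prefix}{i + 1}", seq))
    return SequenceSet(records)


def mutate_to_ani(genome: str, target_ani: float, seed: int = 0) -> str:
    """Derive a mutant at a controlled nucleotide identity.

    Exactly ``round((1 - target_ani) * len)`` positions, chosen uniformly
    without replacement, are substituted with a different base, so the true
    identity of the output against the input equals the target to within
    rounding.
    """
    if not 0.80 <= target_ani < 1.0:
        raise ValueError("target_ani must lie in [0.80, 1.0)")
    rng = np.random.default_rng(seed)
    arr = np.array(list(genome))
    n_sub = int(round((1.0 - target_ani) * len(arr)))
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for i in pos:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _apply_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_reads(
    genomes: SequenceSet,
    composition: dict[str, float],
    n_pairs: int,
    read_len: int = 100,
    error_rate: float = 0.0,
    contaminants: SequenceSet | None = None,
    contaminant_frac: float = 0.0,
    insert_size: int = 350,
    quality: int = 30,
    seed: int = 0,
) -> tuple[list[ReadPair], SyntheticTruth]:
    """Paired-end reads from a known genome composition.

    Fragments start uniformly; the mate pair reads both fragment ends
    (mate 2 reverse-complemented), the whole fragment is flipped to the
    reverse strand with probability 0.5, substitution errors are applied
    per base, and qualities are a constant Phred ``quality``. A fraction
    ``contaminant_frac`` of pairs is drawn from ``contaminants`` instead;
    every read's true origin is recorded in the returned truth.
    """
    if not composition:
        raise ValueError("composition must not be empty")
    comp_ids = list(composition)
    comp_p = np.array([composition[g] for g in comp_ids], dtype=float)
    if abs(comp_p.sum() - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    seqs = {name: seq for name, seq in genomes}
    min_len = min(len(seqs[g]) for g in comp_ids)
    if read_len > min_len:
        raise ValueError("read_len exceeds the shortest genome")
    rng = np.random.default_rng(seed)
    qual = chr(quality + 33) * read_len
    truth = SyntheticTruth(seed=seed, composition=dict(composition))
    pairs: list[ReadPair] = []
    cont_seqs = list(contaminants) if contaminants is not None else []

    for i in range(n_pairs):
        rid = f"r{i + 1}"
        if cont_seqs and rng.random() < contaminant_frac:
            src_id, src = cont_seqs[rng.integers(len(cont_seqs))]
            origin = f"contaminant:{src_id}"
        else:
            src_id = comp_ids[rng.choice(len(comp_ids), p=comp_p)]
            src = seqs[src_id]
            origin = src_id
        frag_len = min(insert_size, len(src))
        start = int(rng.integers(0, len(src) - frag_len + 1))
        frag = src[start : start + frag_len]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        r1 = frag[:read_len]
        r2 = reverse_complement(frag[-read_len:])
        r1 = _apply_errors(r1, error_rate, rng)
        r2 = _apply_errors(r2, error_rate, rng)
        truth.read_origin[rid] = origin
        pairs.append(ReadPair(rid, r1, qual, r2, qual))
    return pairs, truth


def simulate_abundance_study(
    n_per_group: tuple[int, int],
    taxa: list,
    planted_diff: dict[str, tuple[float, str]] | None = None,
    corr_blocks: list[tuple[list[str], float]] | None = None,
    noise_sd_log: float = 0.5,
    base_mean: dict[str, float] | None = None,
    group_names: tuple[str, str] = ("A", "B"),
    seed: int = 0,
) -> tuple[AbundanceTable, pd.Series, SyntheticTruth]:
    """Two-group sample × taxon study with planted effects.

    ``taxa`` is a list of names or of ``(name, kingdom)`` tuples. Per
    taxon, log abundance = log(base mean) + log(fold change, in the
    enriched group only) + noise_sd_log·z, with z standard normal. For a
    taxon in a ``corr_blocks`` entry (members, loading), z is split into
    a latent factor f shared by the block and an idiosyncratic part:
    z = loading·f + sqrt(1 − loading²)·e. This keeps every taxon's
    marginal log-variance at noise_sd_log² (so planted blocks do not
    swing the community total and leak closure-induced correlations into
    unrelated taxa) while the within-block log-scale correlation equals
    loading². Base means default to a log-uniform draw over [1e-4, 1e-1],
    the span of typical detectable gut taxa. Rows are closed to the TPM
    scale.
    """
    nA, nB = n_per_group
    if nA < 3 or nB < 3:
        raise ValueError("each group needs at least 3 samples")
    planted_diff = dict(planted_diff or {})
    corr_blocks = list(corr_blocks or [])
    names, kingdoms = [], []
    for t in taxa:
        if isinstance(t, tuple):
            names.append(t[0])
            kingdoms.append(t[1])
        else:
            names.append(t)
            kingdoms.append("fungal")
    for t, (fc, grp) in planted_diff.items():
        if fc <= 0:
            raise ValueError(f"fold change for {t} must be positive")
        if grp not in group_names:
            raise ValueError(f"unknown enriched group {grp!r}")

    rng = np.random.default_rng(seed)
    n = nA + nB
    samples = [f"{group_names[0]}{i + 1}" for i in range(nA)] + [
        f"{group_names[1]}{i + 1}" for i in range(nB)
    ]
    labels = pd.Series(
        [group_names[0]] * nA + [group_names[1]] * nB, index=samples, name="group"
    )

    if base_mean is None:
        base = 10.0 ** rng.uniform(-4, -1, size=len(names))
        base_mean = dict(zip(names, base))
    mu = np.log(np.array([base_mean[t] for t in names]))  # (taxa,)

    z = rng.normal(0.0, 1.0, size=(n, len(names)))
    for members, loading in corr_blocks:
        if not 0 < abs(loading) < 1:
            raise ValueError("block loading must lie in (0, 1)")
        latent = rng.normal(0.0, 1.0, size=n)
        resid = np.sqrt(1.0 - loading * loading)
        for t in members:
            j = names.index(t)
            z[:, j] = loading * latent + resid * z[:, j]
    log_x = mu[None, :] + noise_sd_log * z
    for t, (fc, grp) in planted_diff.items():
        j = names.index(t)
        rows = np.array([g == grp for g in labels])
        log_x[rows, j] += np.log(fc)

    x = np.exp(log_x)
    x = x / x.sum(axis=1, keepdims=True) * TPM_SCALE

    table = AbundanceTable(
        pd.DataFrame(x, index=samples, columns=names),
        kingdom=pd.Series(kingdoms, index=names),
    )
    # induced within-block correlation on the log scale is loading²
    truth = SyntheticTruth(
        seed=seed,
        planted_diff=planted_diff,
        corr_blocks=[(list(m), float(l * l)) for m, l in corr_blocks],
    )
    return table, labels, truth
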