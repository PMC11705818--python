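"""Vectorized k-mer encoding, canonicalization and hashing.

Sequences are 2-bit encoded (A=0, C=1, G=2, T=3); any other symbol
invalidates every window that covers it. A k-mer and its reverse
complement are collapsed to the smaller of the two integer codes
("canonical" k-mer), so hits are strand-insensitive. Hashing uses the
splitmix64 finalizer, which is deterministic across runs and platforms.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def seq_to_codes(seq: str) -> np.ndarray:
    """2-bit codes for a DNA string; -1 marks non-ACGT symbols."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def _window_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all length-k windows plus a validity mask."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    vals = win.astype(np.uint64) @ weights
    bad = codes < 0
    # window is valid iff it covers no bad base
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return vals, valid


def kmer_ints(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Integer codes of every valid k-mer of ``seq`` (in order).

    With ``canonical=True`` each k-mer is replaced by min(k-mer,
    reverse-complement k-mer).
    """
    codes = seq_to_codes(seq)
    fwd, valid = _window_ints(codes, k)
    if not canonical:
        return fwd[valid]
    rc_codes = (3 - codes[::-1]).astype(np.int8)
    rc_codes[codes[::-1] < 0] = -1
    rev, _ = _window_ints(rc_codes, k)
    rev = rev[::-1]  # align window i of rc with window i of fwd
    return np.minimum(fwd, rev)[valid]


def kmer_set(seqs, k: int, canonical: bool = True) -> set[int]:
    """Set of canonical k-mer codes over one string or an iterable of strings."""
    if isinstance(seqs, str):
        seqs = [seqs]
    out: set[int] = set()
    for s in seqs:
        out.update(kmer_ints(s, k, canonical=canonical).tolist())
    return out


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit finalizer (vectorized)."""
    z = x.astype(np.uint64) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def minhash_sketch(seqs, k: int, sketch_size: int) -> np.ndarray:
    """Bottom-s MinHash sketch: the ``sketch_size`` smallest distinct
    hashes of the canonical k-mer set, sorted ascending."""
    if isinstance(seqs, str):
        seqs = [seqs]
    parts = [kmer_ints(s, k, canonical=True) for s in seqs]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    kmers = np.unique(np.concatenate(parts))
    hashes = np.unique(splitmix64(kmers))
    return np.sort(hashes)[:sketch_size]
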