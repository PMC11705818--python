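"""Read-level quality control for paired FASTQ input.

Five filters, applied per pair in a fixed order after polyG-tail
trimming: minimum length, mean Phred quality, fraction of low-quality
bases, sequence complexity, and pairing integrity. A pair is removed when
either mate fails any rule; the first failing rule (in order) is the
recorded reason, so the per-reason counts partition the input exactly.

Thresholds follow the convention that all comparisons are strict:
"shorter than 90 bp", mean quality "below 20", "more than 30%" low-quality
bases, complexity "under 30%".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .io_formats import ReadPair

#: order in which rules are evaluated; the first failure is the reason
RULE_ORDER = ("short", "mean_q", "frac_lowq", "low_complexity")


@dataclass
class QCReport:
    input_pairs: int = 0
    passed_pairs: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in (*RULE_ORDER, "unpaired")}
    )

    def check_conservation(self) -> None:
        total = self.passed_pairs + sum(self.removed.values())
        if total != self.input_pairs:
            raise AssertionError(
                f"QC accounting broken: {self.input_pairs} in, {total} accounted"
            )


def _scores(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


def mean_quality(qual: str) -> float:
    """Arithmetic mean of per-base Phred scores (Phred+33)."""
    if not qual:
        raise ValueError("empty quality string")
    return float(_scores(qual).mean())


def low_quality_fraction(qual: str, q_cut: int = 20) -> float:
    """Fraction of bases with Phred score strictly below ``q_cut``."""
    if not qual:
        raise ValueError("empty quality string")
    s = _scores(qual)
    return float((s < q_cut).mean())


def complexity(seq: str, k: int = 3) -> float:
    """Distinct k-mer fraction: |{k-mers}| / (len - k + 1).

    Repetitive sequences ("ATATATATAT" → 0.25) and homopolymers
    ("AAAAAAA" → 0.20) score low; random reads score near 1. Sequences
    shorter than k are defined to have complexity 0.
    """
    n = len(seq) - k + 1
    if n <= 0:
        return 0.0
    return len({seq[i : i + k] for i in range(n)}) / n


def trim_polyg(seq: str, qual: str, min_run: int = 10) -> tuple[str, str]:
    """Trim a trailing run of >= ``min_run`` G's (two-color chemistry
    artifact) and the matching quality tail."""
    n_g = len(seq) - len(seq.rstrip("G"))
    if n_g >= min_run:
        return seq[: len(seq) - n_g], qual[: len(seq) - n_g]
    return seq, qual


def _first_failure(
    seq: str,
    qual: str,
    min_len: int,
    min_mean_q: float,
    max_lowq_frac: float,
    min_complexity: float,
) -> dict[str, bool]:
    return {
        "short": len(seq) < min_len,
        "mean_q": mean_quality(qual) < min_mean_q if qual else True,
        "frac_lowq": low_quality_fraction(qual) > max_lowq_frac if qual else True,
        "low_complexity": complexity(seq) < min_complexity,
    }


def filter_pairs(
    pairs: Iterable[ReadPair],
    min_len: int = 90,
    min_mean_q: float = 20.0,
    max_lowq_frac: float = 0.30,
    min_complexity: float = 0.30,
    polyg_min_run: int = 10,
) -> tuple[list[ReadPair], QCReport]:
    """Apply the filter cascade to a stream of pairs.

    PolyG tails are trimmed first; then each rule is checked across both
    mates in :data:`RULE_ORDER`, and the pair is removed under the first
    rule either mate fails. Passing pairs are returned trimmed.
    """
    report = QCReport()
    passed: list[ReadPair] = []
    for pair in pairs:
        report.input_pairs += 1
        s1, q1 = trim_polyg(pair.seq1, pair.qual1, polyg_min_run)
        s2, q2 = trim_polyg(pair.seq2, pair.qual2, polyg_min_run)
        if not s1 or not s2:
            report.removed["short"] += 1
            continue
        f1 = _first_failure(s1, q1, min_len, min_mean_q, max_lowq_frac, min_complexity)
        f2 = _first_failure(s2, q2, min_len, min_mean_q, max_lowq_frac, min_complexity)
        reason = next((r for r in RULE_ORDER if f1[r] or f2[r]), None)
        if reason is not None:
            report.removed[reason] += 1
            continue
        report.passed_pairs += 1
        passed.append(ReadPair(pair.read_id, s1, q1, s2, q2))
    report.check_conservation()
    return passed, report


def filter_fastq_files(path_r1, path_r2, **kwargs) -> tuple[list[ReadPair], QCReport]:
    """Convenience wrapper: stream two FASTQ files through
    :func:`filter_pairs`, counting unmatched trailing records under the
    "unpaired" reason instead of raising."""
    from .io_formats import ParseError, read_fastq_pairs

    pairs: list[ReadPair] = []
    unpaired = 0
    try:
        for p in read_fastq_pairs(path_r1, path_r2):
            pairs.append(p)
    except ParseError as exc:
        m = re.match(r"(\d+) unpaired", str(exc))
        if not m:
            raise
        unpaired = int(m.group(1))
    passed, report = filter_pairs(pairs, **kwargs)
    report.removed["unpaired"] += unpaired
    report.input_pairs += unpaired
    report.check_conservation()
    return passed, report
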