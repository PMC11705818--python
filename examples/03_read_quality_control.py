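"""Apply the read-level quality filter cascade.

A small batch of read pairs exercises each removal rule: minimum length
(90 bp), mean Phred quality (20), fraction of low-quality bases (30%),
and sequence complexity (30%, the distinct 3-mer fraction that scores
homopolymers and dinucleotide repeats low). The report partitions the
input exactly.
"""

import numpy as np

from mycoscan import filter_pairs
from mycoscan.io_formats import ReadPair
from mycoscan.read_qc import complexity

rng = np.random.default_rng(4)
rand = lambda n: "".join(rng.choice(list("ACGT"), size=n))

q30, q10 = "?" * 100, "+" * 100
pairs = [
    ReadPair("ok", rand(100), q30, rand(100), q30),
    ReadPair("short", rand(80), "?" * 80, rand(100), q30),
    ReadPair("lowq", rand(100), q10, rand(100), q30),
    ReadPair("repeat", "AT" * 50, q30, rand(100), q30),
]
print(f"complexity of 'ATAT...' read: {complexity('AT' * 50):.3f} (< 0.30 fails)")

passed, report = filter_pairs(pairs)
print(f"input={report.input_pairs} passed={report.passed_pairs}")
for reason, count in report.removed.items():
    if count:
        print(f"removed[{reason}] = {count}")
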