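"""Clean-read filtering on a toy FASTQ batch with planted failures.

Builds 200 reads of which 12 contain an adapter, 8 exceed 10% unknown
bases, and 5 have more than half their bases at Phred quality <= 5, then
applies the clean-read rules and prints the per-category tally.
"""

from chillseq import QCParams, filter_fastq
from chillseq.simulate import generate_fastq

ADAPTER = "AGATCGGAAGAGC"

reads, labels = generate_fastq(
    n_reads=200,
    read_len=75,
    planted_fail_counts={"adapter": 12, "n_fraction": 8, "low_quality": 5},
    adapters=[ADAPTER],
    seed=11,
)
kept, report = filter_fastq(reads, QCParams(adapters=(ADAPTER,)))

print(f"input reads:            {report.n_input}")
print(f"kept (clean) reads:     {report.n_kept}")
print(f"dropped, adapter:       {report.n_dropped_adapter}")
print(f"dropped, >10% N:        {report.n_dropped_n_fraction}")
print(f"dropped, low quality:   {report.n_dropped_low_quality}")
print(
    "\nEvery read lands in exactly one category, so the dropped counts "
    "and the kept count always sum to the input count."
)
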