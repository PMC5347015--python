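"""Clean-read filtering of FASTQ input.

A read is removed (whole-read, never trimmed) when, in this order of
precedence, it (1) contains an adapter as an exact substring, (2) has more
than 10% unknown (N) bases, or (3) has more than 50% of bases at Phred
quality <= 5. The fraction thresholds are strict, so a read sitting exactly
at a boundary survives. Each read is tallied in exactly one report category.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import ChillseqError, FormatError, QCParams

__all__ = [
    "ReadRecord",
    "QCReport",
    "fraction_n",
    "fraction_low_quality",
    "contains_adapter",
    "filter_fastq",
    "read_fastq",
    "write_fastq",
    "write_qc_report",
]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    n_dropped_adapter: int
    n_dropped_n_fraction: int
    n_dropped_low_quality: int

    def __post_init__(self) -> None:
        dropped = (
            self.n_dropped_adapter
            + self.n_dropped_n_fraction
            + self.n_dropped_low_quality
        )
        if self.n_input != self.n_kept + dropped:
            raise ChillseqError("QC report categories must sum to n_input")


def fraction_n(sequence: str) -> float:
    """Fraction of unknown (N/n) bases in a non-empty sequence."""
    if not sequence:
        raise FormatError("empty sequence")
    return (sequence.count("N") + sequence.count("n")) / len(sequence)


def fraction_low_quality(
    quality: str, phred_offset: int = 33, low_quality_phred: int = 5
) -> float:
    """Fraction of bases with decoded Phred score <= low_quality_phred."""
    if not quality:
        raise FormatError("empty quality string")
    n_low = 0
    for ch in quality:
        score = ord(ch) - phred_offset
        if score < 0:
            raise FormatError(
                f"quality char {ch!r} decodes to negative Phred score "
                f"with offset {phred_offset}"
            )
        if score <= low_quality_phred:
            n_low += 1
    return n_low / len(quality)


def contains_adapter(sequence: str, adapters: Sequence[str]) -> bool:
    """True iff any adapter occurs as an exact contiguous substring."""
    return any(a and a in sequence for a in adapters)


def filter_fastq(
    reads: Iterable[ReadRecord], params: QCParams
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the clean-read rules; return kept reads (input order) + tally."""
    kept: list[ReadRecord] = []
    n_input = n_adapter = n_nfrac = n_lowq = 0
    for rec in reads:
        n_input += 1
        if contains_adapter(rec.sequence, params.adapters):
            n_adapter += 1
        elif fraction_n(rec.sequence) > params.max_n_fraction:
            n_nfrac += 1
        elif (
            fraction_low_quality(
                rec.quality, params.phred_offset, params.low_quality_phred
            )
            > params.max_low_quality_fraction
        ):
            n_lowq += 1
        else:
            kept.append(rec)
    report = QCReport(n_input, len(kept), n_adapter, n_nfrac, n_lowq)
    return kept, report


def _open_text(path: str | os.PathLike, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode + "t", encoding="utf-8")


def read_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Stream four-line FASTQ records (optionally gzip-compressed)."""
    with _open_text(path, "r") as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(title.split()[0], seq, qual)
        except ValueError as exc:  # malformed record
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with _open_text(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


def write_qc_report(report: QCReport, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "n_input\tn_kept\tn_dropped_adapter\t"
            "n_dropped_n_fraction\tn_dropped_low_quality\n"
        )
        fh.write(
            f"{report.n_input}\t{report.n_kept}\t{report.n_dropped_adapter}\t"
            f"{report.n_dropped_n_fraction}\t{report.n_dropped_low_quality}\n"
        )
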