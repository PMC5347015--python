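"""RPKM quantification and mapping-statistics arithmetic.

RPKM (reads per kilobase of gene model per million uniquely mapped reads)
for a gene with ``count`` uniquely mapped reads, model length ``length_bp``
and a library of ``total_unique`` uniquely mapped reads is

    RPKM = 1e9 * count / (length_bp * total_unique)

Mapping summaries render each tally as a percentage of total reads, rounded
half-away-from-zero to two decimals, the convention sequencing reports use.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ChillseqError, CountMatrix, GeneModel, SampleStats

__all__ = [
    "rpkm",
    "rpkm_matrix",
    "MappingSummary",
    "mapping_summary",
    "format_ratio_percent",
    "write_expression_matrix",
    "write_mapping_summary",
]

# SampleStats fields reported as a fraction of total reads; base pairs are
# on a different scale and are excluded.
_RATE_FIELDS = (
    "total_reads",
    "total_mapped",
    "perfect_match",
    "le2_mismatch",
    "unique_match",
    "multi_match",
    "unmapped",
)


def rpkm(count: int, length_bp: int, total_unique: int) -> float:
    """RPKM of one gene in one library."""
    if length_bp < 1:
        raise ChillseqError("length_bp must be >= 1")
    if total_unique < 1:
        raise ChillseqError("total_unique must be >= 1 (RPKM undefined)")
    if count < 0:
        raise ChillseqError("count must be non-negative")
    return 1e9 * count / (length_bp * total_unique)


def rpkm_matrix(
    counts: CountMatrix, lengths: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Elementwise RPKM with per-sample denominators from library_sizes.

    Returns a genes x samples DataFrame in the count-matrix row order.
    """
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ChillseqError(f"no gene length for: {missing}")
    length_vec = np.array(
        [lengths[g].length_bp for g in counts.gene_ids], dtype=np.float64
    )
    values = (
        1e9
        * counts.counts.astype(np.float64)
        / (length_vec[:, None] * counts.library_sizes.astype(np.float64)[None, :])
    )
    return pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids)


def format_ratio_percent(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Render 100*numerator/denominator as e.g. ``67.90%``.

    Exact integer arithmetic with ties rounded away from zero, so the
    rendering never inherits binary floating-point artefacts.
    """
    if denominator == 0:
        raise ChillseqError("denominator must be non-zero")
    scaled = Fraction(100 * numerator * 10**decimals, denominator)
    q, r = divmod(scaled.numerator, scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    sign = "-" if q < 0 else ""
    q = abs(q)
    whole, frac = divmod(q, 10**decimals)
    return f"{sign}{whole}.{frac:0{decimals}d}%"


@dataclass(frozen=True)
class MappingSummary:
    """Per-field rates (fractions of total reads) plus rendered percents."""

    rates: dict[str, float]
    rendered: dict[str, str]


def mapping_summary(stats: SampleStats) -> MappingSummary:
    """Rates of each mapping tally relative to total reads."""
    if stats.total_reads == 0:
        raise ChillseqError("total_reads must be positive")
    rates: dict[str, float] = {}
    rendered: dict[str, str] = {}
    for field in _RATE_FIELDS:
        v = getattr(stats, field)
        rates[field] = v / stats.total_reads
        rendered[field] = format_ratio_percent(v, stats.total_reads)
    return MappingSummary(rates, rendered)


def write_expression_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_mapping_summary(
    summaries: Mapping[str, tuple[SampleStats, MappingSummary]],
    path: str | os.PathLike,
) -> None:
    """TSV with raw integers and rendered percents, one row per field."""
    with open(path, "wt", encoding="utf-8") as fh:
        samples = list(summaries)
        fh.write("field\t" + "\t".join(samples) + "\n")
        for field in _RATE_FIELDS:
            cells = []
            for s in samples:
                stats, summ = summaries[s]
                cells.append(f"{getattr(stats, field)} ({summ.rendered[field]})")
            fh.write(field + "\t" + "\t".join(cells) + "\n")
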