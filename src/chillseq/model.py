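"""Domain types shared by every pipeline stage.

The experiment this package models has one sequencing library per condition
(an imbibed-seed control plus fast- and slow-cooled treatments), so the
central containers are deliberately simple: an integer count matrix with
per-sample library sizes, per-gene lengths for RPKM, a pathway membership
database, and small parameter bundles for QC, DEG calling and enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ChillseqError",
    "FormatError",
    "GeneModel",
    "CountMatrix",
    "SampleStats",
    "Pathway",
    "PathwayDB",
    "QCParams",
    "DEGThresholds",
    "EnrichmentParams",
]


class ChillseqError(Exception):
    """Base class for errors raised by this package."""


class FormatError(ChillseqError, ValueError):
    """A file or in-memory table violates its format contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene identifier with its model length in base pairs."""

    gene_id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise FormatError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )


class CountMatrix:
    """Per-gene unique-read counts for an ordered set of samples.

    ``library_sizes`` holds the per-sample total of uniquely mapped reads.
    It defaults to the column sums but may be declared larger (a count table
    need not list every gene the reads mapped to); it can never be smaller
    than the column sum.
    """

    def __init__(
        self,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        counts: np.ndarray,
        library_sizes: Iterable[int] | None = None,
    ) -> None:
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and (
            not np.issubdtype(counts.dtype, np.integer) or (counts < 0).any()
        ):
            raise FormatError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)

        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise FormatError(f"duplicate gene id {g!r}")
            seen.add(g)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")

        sums = self.counts.sum(axis=0) if self.counts.size else np.zeros(
            len(self.sample_ids), dtype=np.int64
        )
        if library_sizes is None:
            self.library_sizes = sums.copy()
        else:
            self.library_sizes = np.asarray(list(library_sizes), dtype=np.int64)
            if self.library_sizes.shape != (len(self.sample_ids),):
                raise FormatError("one library size per sample required")
            if (self.library_sizes < sums).any():
                bad = [
                    s
                    for s, ls, cs in zip(self.sample_ids, self.library_sizes, sums)
                    if ls < cs
                ]
                raise FormatError(
                    f"library size smaller than column sum for sample(s) {bad}"
                )
        if (self.library_sizes <= 0).any():
            raise FormatError("library sizes must be positive")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(
                f"unknown sample {sample_id!r}; have {self.sample_ids}"
            ) from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def library_size(self, sample_id: str) -> int:
        return int(self.library_sizes[self.sample_index(sample_id)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.library_sizes, other.library_sizes)
        )

    def __repr__(self) -> str:
        return (
            f"CountMatrix({self.n_genes} genes x {len(self.sample_ids)} samples, "
            f"library_sizes={self.library_sizes.tolist()})"
        )


@dataclass(frozen=True)
class SampleStats:
    """Read-mapping tallies for one library, as a mapping report prints them.

    Invariants: mapped + unmapped = total reads; perfect + <=2-mismatch =
    mapped; unique + multi-position = mapped.
    """

    total_reads: int
    total_base_pairs: int
    total_mapped: int
    perfect_match: int
    le2_mismatch: int
    unique_match: int
    multi_match: int
    unmapped: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise FormatError(f"SampleStats.{name} must be non-negative")
        if self.total_mapped + self.unmapped != self.total_reads:
            raise FormatError("mapped + unmapped must equal total_reads")
        if self.perfect_match + self.le2_mismatch != self.total_mapped:
            raise FormatError("perfect + <=2-mismatch must equal total_mapped")
        if self.unique_match + self.multi_match != self.total_mapped:
            raise FormatError("unique + multi-position must equal total_mapped")


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"pathway {self.pathway_id!r} has no members")


class PathwayDB:
    """Pathway id -> (name, member gene set); genes may belong to many."""

    def __init__(self, pathways: Iterable[Pathway]) -> None:
        self._pathways: dict[str, Pathway] = {}
        for pw in pathways:
            if pw.pathway_id in self._pathways:
                raise FormatError(f"duplicate pathway id {pw.pathway_id!r}")
            self._pathways[pw.pathway_id] = pw

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self):
        return iter(self._pathways.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._pathways[pathway_id]

    def ids(self) -> list[str]:
        return list(self._pathways)

    def annotated_genes(self) -> frozenset[str]:
        """Union of all member sets: the default enrichment background N."""
        out: set[str] = set()
        for pw in self._pathways.values():
            out |= pw.members
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return self._pathways == other._pathways


@dataclass(frozen=True)
class QCParams:
    """Clean-read filter settings.

    A read is discarded when it contains an adapter, when its fraction of
    unknown (N) bases exceeds ``max_n_fraction``, or when the fraction of
    bases at Phred quality <= ``low_quality_phred`` exceeds
    ``max_low_quality_fraction``. Both fraction thresholds are strict
    ("greater than"), so a read exactly at the boundary is kept.
    """

    adapters: tuple[str, ...] = ()
    max_n_fraction: float = 0.10
    low_quality_phred: int = 5
    max_low_quality_fraction: float = 0.50
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise FormatError("max_n_fraction must be in [0, 1]")
        if not 0.0 <= self.max_low_quality_fraction <= 1.0:
            raise FormatError("max_low_quality_fraction must be in [0, 1]")
        if self.phred_offset not in (33, 64):
            raise FormatError("phred_offset must be 33 or 64")


@dataclass(frozen=True)
class DEGThresholds:
    """DEG call: FDR <= max_fdr AND |log2 ratio| >= min_abs_log2_ratio."""

    max_fdr: float = 0.001
    min_abs_log2_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_fdr < 1.0:
            raise FormatError("max_fdr must be in (0, 1)")
        if self.min_abs_log2_ratio < 0:
            raise FormatError("min_abs_log2_ratio must be non-negative")


@dataclass(frozen=True)
class EnrichmentParams:
    """Over-representation significance settings (Bonferroni at 0.05)."""

    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise FormatError("alpha must be in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise FormatError("correction must be 'bonferroni' or 'none'")
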