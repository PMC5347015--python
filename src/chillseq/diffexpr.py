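"""Exact two-library differential expression without replicates.

The test is the Audic–Claverie comparison of a gene's tag counts between two
sequencing libraries. Conditional on observing ``x`` tags in library A (of
``N1`` total tags), the count ``y`` in library B (``N2`` total) under equal
expression follows

    p(y | x) = (N2/N1)**y * (x+y)! / ( x! * y! * (1 + N2/N1)**(x+y+1) )

which is evaluated in log space via log-gamma. A two-sided p-value is the
doubled smaller tail (both tails include the observed ``y``), capped at 1.
Genes are called differentially expressed when the Benjamini–Hochberg FDR
and the |log2 ratio| of normalized expression both pass their thresholds
(defaults FDR <= 0.001, |log2 ratio| >= 1).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .model import ChillseqError, CountMatrix, DEGThresholds

__all__ = [
    "GenePairObs",
    "GeneDEResult",
    "ContrastTable",
    "ac_log_pmf",
    "ac_two_sided_p",
    "log2_ratio",
    "bh_fdr",
    "run_contrast",
    "shared_degs",
    "opposite_direction",
    "VennCounts",
    "venn_counts",
    "write_contrast_table",
    "read_contrast_table",
]

# Relative cutoff for the geometric remainder bound that truncates the
# upper-tail summation.
_TAIL_RTOL = 1e-15


@dataclass(frozen=True)
class GenePairObs:
    """One gene's tag counts in a pair of libraries."""

    gene_id: str
    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ChillseqError(f"gene {self.gene_id!r}: negative count")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ChillseqError(f"gene {self.gene_id!r}: library totals must be positive")
        if self.x > self.n1 or self.y > self.n2:
            raise ChillseqError(
                f"gene {self.gene_id!r}: count exceeds library total"
            )


def ac_log_pmf(y, x, n1: int, n2: int):
    """log p(y | x) under equal expression; accepts scalars or arrays."""
    y_arr = np.asarray(y)
    x_arr = np.asarray(x)
    if (y_arr < 0).any() or (x_arr < 0).any():
        raise ChillseqError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ChillseqError("library totals must be positive")
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    out = (
        y_arr * log_r
        + gammaln(x_arr + y_arr + 1)
        - gammaln(x_arr + 1)
        - gammaln(y_arr + 1)
        - (x_arr + y_arr + 1) * log_1pr
    )
    if np.isscalar(y) and np.isscalar(x):
        return float(out)
    return out


def _log_upper_tail(x: int, y: int, n1: int, n2: int) -> float:
    """log P(Y >= y) by direct summation from y upward.

    Terms obey t_{k+1}/t_k = (x+y+k+1)/(y+k+1) * r/(1+r); once the ratio
    drops below 1 the remainder is bounded by a geometric series and the
    sum stops when that bound is below _TAIL_RTOL of the accumulated sum.
    """
    r_frac = (n2 / n1) / (1.0 + n2 / n1)  # r/(1+r) < 1
    log_t0 = ac_log_pmf(y, x, n1, n2)
    # Accumulate S = sum of term ratios relative to the first term; the
    # ratios are O(1) so S never overflows and P = exp(log_t0) * S.
    s = 1.0
    term = 1.0
    k = 0
    while True:
        ratio = (x + y + k + 1) / (y + k + 1) * r_frac
        term *= ratio
        s += term
        k += 1
        if ratio < 1.0:
            bound = term * ratio / (1.0 - ratio)
            if bound < _TAIL_RTOL * s:
                break
        if k > 10_000_000:  # defensive; unreachable for finite inputs
            raise ChillseqError("upper-tail summation failed to converge")
    return log_t0 + math.log(s)


def _log_lower_tail(x: int, y: int, n1: int, n2: int) -> float:
    """log P(Y <= y) by log-sum-exp over y' = 0..y."""
    ys = np.arange(y + 1)
    return float(logsumexp(ac_log_pmf(ys, x, n1, n2)))


def ac_two_sided_p(obs: GenePairObs) -> float:
    """Two-sided p = min(1, 2 * min(P(Y <= y), P(Y >= y))), both tails
    including the observed y."""
    x, y, n1, n2 = obs.x, obs.y, obs.n1, obs.n2
    log_lower = _log_lower_tail(x, y, n1, n2)
    if log_lower <= math.log(0.5):
        # lower + upper = 1 + pmf(y) > 1, so the lower tail is the smaller.
        p = 2.0 * math.exp(log_lower)
    else:
        log_upper = _log_upper_tail(x, y, n1, n2)
        p = 2.0 * math.exp(min(log_lower, log_upper))
    return min(1.0, p)


def log2_ratio(obs: GenePairObs) -> float:
    """log2 of normalized expression in B over A, with zero counts
    substituted by 1 (the gene-length factor cancels, so the RPKM ratio
    equals the normalized tag-count ratio)."""
    if obs.x == 0 and obs.y == 0:
        raise ChillseqError(
            f"gene {obs.gene_id!r}: log2 ratio undefined for double zero"
        )
    x_star = max(obs.x, 1)
    y_star = max(obs.y, 1)
    return math.log2((y_star / obs.n2) / (x_star / obs.n1))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    arr = np.asarray(list(p_values), dtype=np.float64)
    if arr.size == 0:
        return []
    if (arr < 0).any() or (arr > 1).any() or np.isnan(arr).any():
        raise ChillseqError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class GeneDEResult:
    gene_id: str
    x: int
    y: int
    log2_ratio: float
    p: float
    fdr: float
    direction: str  # up / down / flat, oriented B over A
    is_deg: bool


@dataclass
class ContrastTable:
    """Per-gene exact-test results for one pairwise comparison.

    ``name`` follows the ``<A>_vs_<B>`` convention with log2 ratios oriented
    B over A.
    """

    name: str
    sample_a: str
    sample_b: str
    n1: int
    n2: int
    results: list[GeneDEResult]

    def deg_ids(self) -> set[str]:
        return {r.gene_id for r in self.results if r.is_deg}

    def deg_ids_by_direction(self, direction: str) -> set[str]:
        return {
            r.gene_id
            for r in self.results
            if r.is_deg and r.direction == direction
        }

    def __getitem__(self, gene_id: str) -> GeneDEResult:
        for r in self.results:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.results],
                "x": [r.x for r in self.results],
                "y": [r.y for r in self.results],
                "N1": self.n1,
                "N2": self.n2,
                "log2_ratio": [r.log2_ratio for r in self.results],
                "p": [r.p for r in self.results],
                "fdr": [r.fdr for r in self.results],
                "direction": [r.direction for r in self.results],
                "is_deg": [r.is_deg for r in self.results],
            }
        )


def run_contrast(
    counts: CountMatrix,
    sample_a: str,
    sample_b: str,
    thresholds: DEGThresholds = DEGThresholds(),
    totals: tuple[int, int] | None = None,
) -> ContrastTable:
    """Test every gene of ``counts`` between two samples.

    N1/N2 default to the per-sample library sizes (uniquely mapped totals);
    ``totals`` overrides them, e.g. with total clean reads. Genes with zero
    counts in both samples are excluded from testing. FDR is computed across
    the tested genes of this contrast only.
    """
    xs = counts.column(sample_a)
    ys = counts.column(sample_b)
    if totals is None:
        n1 = counts.library_size(sample_a)
        n2 = counts.library_size(sample_b)
    else:
        n1, n2 = int(totals[0]), int(totals[1])
        if n1 <= 0 or n2 <= 0:
            raise ChillseqError("totals must be positive")

    tested: list[tuple[str, int, int]] = [
        (g, int(x), int(y))
        for g, x, y in zip(counts.gene_ids, xs, ys)
        if x > 0 or y > 0
    ]
    pvals = []
    ratios = []
    for g, x, y in tested:
        obs = GenePairObs(g, x, y, n1, n2)
        pvals.append(ac_two_sided_p(obs))
        ratios.append(log2_ratio(obs))
    fdrs = bh_fdr(pvals)

    results: list[GeneDEResult] = []
    for (g, x, y), p, q, lr in zip(tested, pvals, fdrs, ratios):
        is_deg = q <= thresholds.max_fdr and abs(lr) >= thresholds.min_abs_log2_ratio
        if is_deg:
            direction = "up" if lr > 0 else "down"
        else:
            direction = "up" if lr > 0 else ("down" if lr < 0 else "flat")
        results.append(GeneDEResult(g, x, y, lr, p, q, direction, is_deg))
    return ContrastTable(
        f"{sample_a}_vs_{sample_b}", sample_a, sample_b, n1, n2, results
    )


def shared_degs(a: ContrastTable, b: ContrastTable) -> set[str]:
    """Genes called DEG in both contrasts (e.g. the cold-responsive set
    shared by the two cooling rates against control)."""
    return a.deg_ids() & b.deg_ids()


def opposite_direction(
    a: ContrastTable, b: ContrastTable
) -> list[tuple[str, str, str]]:
    """DEGs of both contrasts whose direction differs between them,
    ordered as in table ``a``."""
    b_dir = {r.gene_id: r.direction for r in b.results if r.is_deg}
    out: list[tuple[str, str, str]] = []
    for r in a.results:
        if r.is_deg and r.gene_id in b_dir and r.direction != b_dir[r.gene_id]:
            out.append((r.gene_id, r.direction, b_dir[r.gene_id]))
    return out


@dataclass(frozen=True)
class VennCounts:
    """Per-contrast DEG tallies plus pairwise intersection sizes."""

    per_contrast: dict[str, tuple[int, int, int]]  # name -> (total, up, down)
    pairwise: dict[tuple[str, str], int]


def venn_counts(tables: Sequence[ContrastTable]) -> VennCounts:
    per_contrast: dict[str, tuple[int, int, int]] = {}
    for t in tables:
        up = len(t.deg_ids_by_direction("up"))
        down = len(t.deg_ids_by_direction("down"))
        per_contrast[t.name] = (up + down, up, down)
    pairwise: dict[tuple[str, str], int] = {}
    for i, a in enumerate(tables):
        for b in tables[i + 1 :]:
            pairwise[(a.name, b.name)] = len(a.deg_ids() & b.deg_ids())
    return VennCounts(per_contrast, pairwise)


def write_contrast_table(table: ContrastTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_contrast_table(path: str | os.PathLike, name: str | None = None) -> ContrastTable:
    df = pd.read_csv(path, sep="\t")
    inferred = name or os.path.splitext(os.path.basename(str(path)))[0]
    if "_vs_" in inferred:
        sample_a, sample_b = inferred.split("_vs_", 1)
    else:
        sample_a, sample_b = "A", "B"
    n1 = int(df["N1"].iloc[0]) if len(df) else 1
    n2 = int(df["N2"].iloc[0]) if len(df) else 1
    results = [
        GeneDEResult(
            str(r.gene_id),
            int(r.x),
            int(r.y),
            float(r.log2_ratio),
            float(r.p),
            float(r.fdr),
            str(r.direction),
            bool(r.is_deg),
        )
        for r in df.itertuples(index=False)
    ]
    return ContrastTable(inferred, sample_a, sample_b, n1, n2, results)
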