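"""Hypergeometric pathway over-representation and cross-contrast typing.

For a contrast with ``n`` pathway-annotatable DEGs out of ``N`` annotated
background genes, a pathway with ``M`` annotated members and ``m`` DEG
members is scored by the upper-tail hypergeometric probability
P(X >= m), X ~ Hypergeometric(N, M, n), with Bonferroni correction across
the pathways tested in that contrast.

Significant pathways are then classified across the three contrasts of the
cooling-rate design (fast/slow, control/fast, control/slow) into four
types: I significant only under slow cooling (vs control); II significant
under both cooling rates but more so under slow; III significant only (or
more) under fast; IV significant under both with no rate difference.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .expression import format_ratio_percent
from .model import ChillseqError, PathwayDB

__all__ = [
    "EnrichmentRow",
    "PathwayTypeCall",
    "hypergeom_upper_p",
    "enrich",
    "bonferroni_adjust",
    "classify_pathway_types",
    "more_significant_in_slow",
    "write_enrichment_table",
    "read_enrichment_table",
    "write_type_calls",
]


def hypergeom_upper_p(m: int, n: int, M: int, N: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n).

    m: DEGs in the pathway; n: annotatable DEGs; M: annotated genes in the
    pathway; N: all annotated genes.
    """
    if not (0 <= m <= min(n, M) and 0 <= n <= N and 0 <= M <= N):
        raise ChillseqError(
            f"invalid hypergeometric configuration m={m}, n={n}, M={M}, N={N}"
        )
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    name: str
    m: int
    n: int
    M: int
    N: int
    percent: float  # 100 * m / n
    percent_rendered: str
    p_raw: float
    p_adj: float


def bonferroni_adjust(p_raws: Sequence[float], k: int | None = None) -> list[float]:
    """min(1, p * k) with k defaulting to the number of tests supplied."""
    if k is None:
        k = len(p_raws)
    return [min(1.0, p * k) for p in p_raws]


def enrich(
    deg_ids: Iterable[str],
    db: PathwayDB,
    background: Iterable[str] | None = None,
) -> list[EnrichmentRow]:
    """Score every pathway for over-representation of DEGs.

    ``background`` defaults to all genes with at least one pathway
    membership; DEGs outside the background do not count toward ``n``.
    Rows are sorted by raw p ascending (pathway id breaks ties).
    """
    bg = frozenset(background) if background is not None else db.annotated_genes()
    degs = frozenset(deg_ids) & bg
    N = len(bg)
    n = len(degs)
    if n == 0:
        raise ChillseqError("no annotatable DEGs (n = 0)")

    rows: list[tuple[str, str, int, int]] = []
    for pw in db:
        members = pw.members & bg
        M = len(members)
        if M == 0:
            continue
        m = len(degs & members)
        rows.append((pw.pathway_id, pw.name, m, M))

    p_raws = [hypergeom_upper_p(m, n, M, N) for _, _, m, M in rows]
    p_adjs = bonferroni_adjust(p_raws)
    out = [
        EnrichmentRow(
            pid,
            name,
            m,
            n,
            M,
            N,
            100.0 * m / n,
            format_ratio_percent(m, n),
            p_raw,
            p_adj,
        )
        for (pid, name, m, M), p_raw, p_adj in zip(rows, p_raws, p_adjs)
    ]
    out.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return out


def more_significant_in_slow(
    p_fs: float | None, p_cf: float, p_cs: float, alpha: float
) -> bool:
    """Default rule separating type II from type IV when a pathway is
    significant under both cooling rates: the fast-vs-slow contrast is
    itself significant, or the control/slow p is smaller than the
    control/fast p."""
    return (p_fs is not None and p_fs <= alpha) or p_cs < p_cf


@dataclass(frozen=True)
class PathwayTypeCall:
    pathway_id: str
    p_fs: float | None
    p_cf: float | None
    p_cs: float | None
    type: str  # "I" | "II" | "III" | "IV" | "none"


def classify_pathway_types(
    fs: Mapping[str, float],
    cf: Mapping[str, float],
    cs: Mapping[str, float],
    alpha: float = 0.05,
    rate_difference_rule: Callable[
        [float | None, float, float, float], bool
    ] = more_significant_in_slow,
) -> list[PathwayTypeCall]:
    """Classify pathways by where they are significantly enriched.

    Inputs map pathway id -> raw p-value per contrast (fast/slow,
    control/fast, control/slow); a pathway absent from a mapping was not
    enriched there. Significance is p <= alpha on the raw p-values.
    """
    ids = sorted(set(fs) | set(cf) | set(cs))
    calls: list[PathwayTypeCall] = []
    for pid in ids:
        p_fs = fs.get(pid)
        p_cf = cf.get(pid)
        p_cs = cs.get(pid)
        sig_cf = p_cf is not None and p_cf <= alpha
        sig_cs = p_cs is not None and p_cs <= alpha
        if sig_cs and not sig_cf:
            t = "I"
        elif sig_cf and not sig_cs:
            t = "III"
        elif sig_cf and sig_cs:
            t = "II" if rate_difference_rule(p_fs, p_cf, p_cs, alpha) else "IV"
        else:
            t = "none"
        calls.append(PathwayTypeCall(pid, p_fs, p_cf, p_cs, t))
    return calls


def write_enrichment_table(
    rows: Sequence[EnrichmentRow], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "name": [r.name for r in rows],
            "m": [r.m for r in rows],
            "n": [r.n for r in rows],
            "M": [r.M for r in rows],
            "N": [r.N for r in rows],
            "percent": [r.percent for r in rows],
            "percent_rendered": [r.percent_rendered for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adj": [r.p_adj for r in rows],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_enrichment_table(path: str | os.PathLike) -> list[EnrichmentRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        EnrichmentRow(
            str(r.pathway_id),
            str(r.name),
            int(r.m),
            int(r.n),
            int(r.M),
            int(r.N),
            float(r.percent),
            str(r.percent_rendered),
            float(r.p_raw),
            float(r.p_adj),
        )
        for r in df.itertuples(index=False)
    ]


def write_type_calls(
    calls: Sequence[PathwayTypeCall], path: str | os.PathLike
) -> None:
    def fmt(p: float | None) -> str:
        return "" if p is None else f"{p:.8g}"

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("pathway_id\tp_fs\tp_cf\tp_cs\ttype\n")
        for c in calls:
            fh.write(
                f"{c.pathway_id}\t{fmt(c.p_fs)}\t{fmt(c.p_cf)}\t"
                f"{fmt(c.p_cs)}\t{c.type}\n"
            )
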