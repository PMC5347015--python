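"""End-to-end orchestration: QC -> RPKM -> contrasts -> sets -> enrichment.

Every stage reads and writes plain TSV/GMT/FASTQ files, so intermediate
files are the interchange contract and any stage can be re-run alone. A
manifest with content checksums is written last; identical inputs and
config give identical checksums.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import diffexpr, enrichment, expression, io, qc
from .model import (
    ChillseqError,
    DEGThresholds,
    EnrichmentParams,
    FormatError,
    QCParams,
)

__all__ = ["PipelineConfig", "Manifest", "load_config", "run_all"]

log = logging.getLogger("chillseq")


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for a full run.

    The three contrasts are fixed by the study design: control_vs_fast,
    control_vs_slow and fast_vs_slow, with log2 ratios oriented second
    sample over first.
    """

    counts: str
    outdir: str
    lengths: str | None = None
    pathways: str | None = None
    fastq: str | None = None
    sample_control: str = "control"
    sample_fast: str = "fast"
    sample_slow: str = "slow"
    adapters: tuple[str, ...] = ()
    max_n_fraction: float = 0.10
    low_quality_phred: int = 5
    max_low_quality_fraction: float = 0.50
    phred_offset: int = 33
    max_fdr: float = 0.001
    min_abs_log2_ratio: float = 1.0
    alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 0

    def qc_params(self) -> QCParams:
        return QCParams(
            adapters=tuple(self.adapters),
            max_n_fraction=self.max_n_fraction,
            low_quality_phred=self.low_quality_phred,
            max_low_quality_fraction=self.max_low_quality_fraction,
            phred_offset=self.phred_offset,
        )

    def thresholds(self) -> DEGThresholds:
        return DEGThresholds(self.max_fdr, self.min_abs_log2_ratio)

    def enrichment_params(self) -> EnrichmentParams:
        return EnrichmentParams(self.alpha, self.correction)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Read the flat key-value (YAML) config schema."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    if "adapters" in raw and isinstance(raw["adapters"], str):
        raw["adapters"] = tuple(
            a.strip() for a in raw["adapters"].split(",") if a.strip()
        )
    elif "adapters" in raw:
        raw["adapters"] = tuple(raw["adapters"])
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class Manifest:
    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries.append((str(path.relative_to(root)), digest))

    def write(self, path: Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("file\tsha256\n")
            for name, digest in self.entries:
                fh.write(f"{name}\t{digest}\n")


def _validate(config: PipelineConfig) -> None:
    for label, p in (
        ("counts", config.counts),
        ("lengths", config.lengths),
        ("pathways", config.pathways),
        ("fastq", config.fastq),
    ):
        if p is not None and not os.path.exists(p):
            raise FormatError(f"{label} file not found: {p}")
    counts = io.read_count_table(config.counts)
    for role, s in (
        ("control", config.sample_control),
        ("fast", config.sample_fast),
        ("slow", config.sample_slow),
    ):
        if s not in counts.sample_ids:
            raise FormatError(
                f"{role} sample {s!r} not in count table "
                f"(samples: {counts.sample_ids})"
            )


def run_all(config: PipelineConfig) -> Manifest:
    """Run every stage in order and return the artifact manifest.

    Any stage failure raises with the stage named; validation failures
    occur before any output is written.
    """
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()

    def emit(name: str) -> Path:
        return outdir / name

    def record(path: Path) -> None:
        manifest.add(path, outdir)

    # -- QC ---------------------------------------------------------------
    if config.fastq is not None:
        log.info("qc: filtering %s", config.fastq)
        kept, report = qc.filter_fastq(
            qc.read_fastq(config.fastq), config.qc_params()
        )
        qc.write_fastq(kept, emit("clean.fastq"))
        qc.write_qc_report(report, emit("qc_report.tsv"))
        record(emit("clean.fastq"))
        record(emit("qc_report.tsv"))
        log.info(
            "qc: %d/%d reads kept (adapter %d, N %d, low-quality %d)",
            report.n_kept,
            report.n_input,
            report.n_dropped_adapter,
            report.n_dropped_n_fraction,
            report.n_dropped_low_quality,
        )

    counts = io.read_count_table(config.counts)
    log.info(
        "counts: %d genes x %d samples", counts.n_genes, len(counts.sample_ids)
    )

    # -- Expression -------------------------------------------------------
    if config.lengths is not None:
        lengths = io.read_gene_lengths(config.lengths)
        expr = expression.rpkm_matrix(counts, lengths)
        expression.write_expression_matrix(expr, emit("expression_rpkm.tsv"))
        record(emit("expression_rpkm.tsv"))
        log.info("expression: RPKM for %d genes", len(expr))

    # -- Differential expression ------------------------------------------
    thresholds = config.thresholds()
    pairs = [
        (config.sample_control, config.sample_fast),
        (config.sample_control, config.sample_slow),
        (config.sample_fast, config.sample_slow),
    ]
    tables: list[diffexpr.ContrastTable] = []
    for a, b in pairs:
        table = diffexpr.run_contrast(counts, a, b, thresholds)
        tables.append(table)
        path = emit(f"contrast_{table.name}.tsv")
        diffexpr.write_contrast_table(table, path)
        record(path)
        log.info(
            "de: %s tested %d genes, %d DEGs",
            table.name,
            len(table.results),
            len(table.deg_ids()),
        )
    cf_table, cs_table, fs_table = tables

    # -- Cross-contrast sets ----------------------------------------------
    venn = diffexpr.venn_counts(tables)
    with open(emit("venn_counts.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("contrast\ttotal\tup\tdown\n")
        for name, (total, up, down) in venn.per_contrast.items():
            fh.write(f"{name}\t{total}\t{up}\t{down}\n")
        fh.write("pair\tshared\t\t\n")
        for (a, b), k in venn.pairwise.items():
            fh.write(f"{a}&{b}\t{k}\t\t\n")
    record(emit("venn_counts.tsv"))

    opposite = diffexpr.opposite_direction(cf_table, cs_table)
    with open(emit("opposite_direction.tsv"), "wt", encoding="utf-8") as fh:
        fh.write(
            "gene_id\tdirection_fast_vs_control\tdirection_slow_vs_control\n"
        )
        for gene_id, dir_f, dir_s in opposite:
            fh.write(f"{gene_id}\t{dir_f}\t{dir_s}\n")
    record(emit("opposite_direction.tsv"))
    log.info(
        "sets: %d shared DEGs, %d opposite-direction",
        venn.pairwise[(cf_table.name, cs_table.name)],
        len(opposite),
    )

    # -- Enrichment and typing --------------------------------------------
    if config.pathways is not None:
        db = io.read_pathway_db(config.pathways)
        background = db.annotated_genes()
        per_contrast_p: dict[str, dict[str, float]] = {}
        for table in tables:
            degs = table.deg_ids() & background
            path = emit(f"enrichment_{table.name}.tsv")
            if not degs:
                log.warning("enrich: %s has no annotatable DEGs", table.name)
                enrichment.write_enrichment_table([], path)
                per_contrast_p[table.name] = {}
            else:
                rows = enrichment.enrich(table.deg_ids(), db, background)
                enrichment.write_enrichment_table(rows, path)
                per_contrast_p[table.name] = {r.pathway_id: r.p_raw for r in rows}
                log.info(
                    "enrich: %s n=%d annotatable DEGs over %d pathways",
                    table.name,
                    len(degs),
                    len(rows),
                )
            record(path)
        calls = enrichment.classify_pathway_types(
            per_contrast_p[fs_table.name],
            per_contrast_p[cf_table.name],
            per_contrast_p[cs_table.name],
            alpha=config.alpha,
        )
        enrichment.write_type_calls(calls, emit("pathway_types.tsv"))
        record(emit("pathway_types.tsv"))
        log.info(
            "classify: %d pathways typed (%d significant somewhere)",
            len(calls),
            sum(1 for c in calls if c.type != "none"),
        )

    manifest.write(emit("manifest.tsv"))
    return manifest
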