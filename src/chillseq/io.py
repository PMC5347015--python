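"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular files are TSV with a header row. The count matrix may carry a
``#library_size`` comment line declaring per-sample totals of uniquely
mapped reads; without it, column sums are used. Pathway annotation is
accepted either as GMT (``pathway_id<TAB>name<TAB>gene...``) or as a
two-column ``gene<TAB>pathway`` TSV; the dialect is inferred from the
column count.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from .model import CountMatrix, FormatError, GeneModel, Pathway, PathwayDB

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_pathway_db",
    "write_pathway_gmt",
]


def read_count_table(path: str | os.PathLike) -> CountMatrix:
    """Read a TSV count matrix (``gene_id`` column + one column per sample).

    Comment lines start with ``#``; a ``#library_size`` line (values in
    sample order) overrides the column-sum default.
    """
    declared_sizes: list[int] | None = None
    header: list[str] | None = None
    gene_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.split("\t")
                if fields[0].strip("# ") == "library_size" or line.startswith(
                    "#library_size"
                ):
                    vals = line.split("\t")[1:] or line.split()[1:]
                    try:
                        declared_sizes = [int(v) for v in vals]
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}:{lineno}: non-integer library size"
                        ) from exc
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if len(header) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: header needs gene_id plus >=1 sample"
                    )
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row: list[int] = []
            for col, val in zip(header[1:], fields[1:]):
                try:
                    iv = int(val)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {val!r} "
                        f"in column {col!r}"
                    ) from exc
                if iv < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative count in column {col!r}"
                    )
                row.append(iv)
            rows.append(row)
    if header is None or not rows:
        raise FormatError(f"{path}: empty count table")
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise FormatError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    counts = np.asarray(rows, dtype=np.int64)
    return CountMatrix(gene_ids, header[1:], counts, declared_sizes)


def write_count_table(matrix: CountMatrix, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            "#library_size\t"
            + "\t".join(str(int(v)) for v in matrix.library_sizes)
            + "\n"
        )
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_gene_lengths(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read a two-column TSV of gene_id and model length in bp."""
    out: dict[str, GeneModel] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[1].lower() in ("length", "length_bp"):
                continue
            gene_id, length_s = fields
            try:
                length = int(length_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {length_s!r}"
                ) from exc
            if length <= 0:
                raise FormatError(
                    f"{path}:{lineno}: gene {gene_id!r} length must be positive"
                )
            if gene_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene_id!r}")
            out[gene_id] = GeneModel(gene_id, length)
    if not out:
        raise FormatError(f"{path}: no gene lengths found")
    return out


def write_gene_lengths(
    lengths: Mapping[str, GeneModel], path: str | os.PathLike
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tlength_bp\n")
        for gm in lengths.values():
            fh.write(f"{gm.gene_id}\t{gm.length_bp}\n")


def read_pathway_db(path: str | os.PathLike) -> PathwayDB:
    """Read pathway annotation in GMT or two-column gene->pathway TSV.

    If every non-comment line has exactly two columns the file is taken as
    gene->pathway pairs (pathway name = pathway id); otherwise it is GMT
    and a line with fewer than three columns is a zero-member error.
    """
    lines: list[tuple[int, list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            lines.append((lineno, line.split("\t")))
    if not lines:
        raise FormatError(f"{path}: empty pathway file")

    two_col = all(len(fields) == 2 for _, fields in lines)
    if two_col:
        members: dict[str, set[str]] = {}
        order: list[str] = []
        for lineno, (gene, pathway) in lines:
            if not gene or not pathway:
                raise FormatError(f"{path}:{lineno}: empty field")
            if pathway not in members:
                members[pathway] = set()
                order.append(pathway)
            members[pathway].add(gene)
        return PathwayDB(
            Pathway(pid, pid, frozenset(members[pid])) for pid in order
        )

    pathways: list[Pathway] = []
    for lineno, fields in lines:
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT pathway {fields[0]!r} has no members"
            )
        pid, name, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if not genes:
            raise FormatError(
                f"{path}:{lineno}: GMT pathway {pid!r} has no members"
            )
        pathways.append(Pathway(pid, name, frozenset(genes)))
    return PathwayDB(pathways)


def write_pathway_gmt(db: PathwayDB, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pw in db:
            fh.write(
                pw.pathway_id
                + "\t"
                + pw.name
                + "\t"
                + "\t".join(sorted(pw.members))
                + "\n"
            )
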