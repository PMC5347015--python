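"""Synthetic three-library experiments with known ground truth.

The generator emulates the structure of a no-replicate cooling-rate study:
a control library plus fast- and slow-cooled libraries, ~20k genes, planted
differential-expression classes (shared up/down across both cooling rates,
rate-specific, and opposite-direction genes), pathway annotation with
planted over-representation, and toy FASTQ with planted quality failures.
Counts are Poisson (or negative-binomial when ``dispersion`` > 0) draws
whose per-column expected sums equal the requested library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diffexpr import ContrastTable, opposite_direction
from .enrichment import EnrichmentRow
from .model import ChillseqError, CountMatrix, GeneModel, Pathway, PathwayDB
from .qc import ReadRecord

__all__ = [
    "PlantedPathway",
    "ExperimentSpec",
    "TruthBundle",
    "SimulatedExperiment",
    "generate_experiment",
    "generate_fastq",
    "RecoveryReport",
    "evaluate_recovery",
    "reference_scenario",
]

SAMPLES = ("control", "fast", "slow")

DEG_CLASSES = ("shared_up", "shared_down", "fast_only", "slow_only", "opposite")


@dataclass(frozen=True)
class PlantedPathway:
    """A pathway whose members are drawn preferentially from one DEG class.

    ``factor`` multiplies the class's background membership rate (capped at
    90% of the pathway), planting over-representation of that class.
    ``deg_class`` may be any DEG class name or ``shared`` (the union of
    shared_up, shared_down and opposite).
    """

    pathway_id: str
    deg_class: str
    factor: float


@dataclass(frozen=True)
class ExperimentSpec:
    """Conditions of a simulated experiment.

    Defaults mirror the scale of the study design this package targets:
    three libraries of ~1e7 uniquely mapped reads over ~20k genes, with
    planted DEG classes sized like the reported contrast structure
    (570 shared cold-responsive genes of which 12 flip direction between
    cooling rates, plus rate-specific responders).
    """

    n_genes: int = 20_000
    library_sizes: tuple[int, int, int] = (10_000_000, 10_000_000, 10_000_000)
    baseline_mean: float = 50.0
    baseline_sigma: float = 0.5
    dispersion: float = 0.0
    gene_length_range: tuple[int, int] = (200, 5000)
    planted: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "shared_up": (279, 4.0),
            "shared_down": (279, 4.0),
            "fast_only": (1151, 4.0),
            "slow_only": (1417, 4.0),
            "opposite": (12, 4.0),
        }
    )
    n_pathways: int = 120
    pathway_size_range: tuple[int, int] = (10, 100)
    planted_enriched: tuple[PlantedPathway, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ChillseqError("n_genes must be positive")
        if len(self.library_sizes) != 3 or any(s <= 0 for s in self.library_sizes):
            raise ChillseqError("three positive library sizes required")
        if self.baseline_mean <= 0:
            raise ChillseqError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ChillseqError("dispersion must be non-negative")
        total_planted = 0
        for cls, (count, fold) in self.planted.items():
            if cls not in DEG_CLASSES:
                raise ChillseqError(f"unknown DEG class {cls!r}")
            if count < 0:
                raise ChillseqError(f"negative planted count for {cls!r}")
            if fold < 1.0:
                raise ChillseqError(
                    f"planted fold for {cls!r} must be >= 1 (got {fold})"
                )
            total_planted += count
        if total_planted > self.n_genes:
            raise ChillseqError(
                f"planted genes ({total_planted}) exceed n_genes ({self.n_genes})"
            )
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ChillseqError("invalid gene_length_range")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ChillseqError("invalid pathway_size_range")


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth of a simulated experiment.

    ``fold_fast``/``fold_slow`` are the planted mean ratios of each gene
    relative to control (1.0 for null genes); ``planted_pathways`` maps
    pathway id to the planting description.
    """

    gene_class: dict[str, str]
    fold_fast: dict[str, float]
    fold_slow: dict[str, float]
    planted_pathways: dict[str, PlantedPathway]

    def genes_of_class(self, deg_class: str) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == deg_class}


@dataclass(frozen=True)
class SimulatedExperiment:
    counts: CountMatrix
    lengths: dict[str, GeneModel]
    pathways: PathwayDB
    truth: TruthBundle
    spec: ExperimentSpec


def _pathway_ids(n: int) -> list[str]:
    return [f"pw{i + 1:04d}" for i in range(n)]


def generate_experiment(spec: ExperimentSpec) -> SimulatedExperiment:
    """Draw one experiment; identical spec + seed gives identical output."""
    root = np.random.SeedSequence(spec.seed)
    ss_len, ss_mean, ss_assign, ss_counts, ss_pw = root.spawn(5)

    width = max(5, len(str(spec.n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]

    rng_len = np.random.default_rng(ss_len)
    lo, hi = spec.gene_length_range
    length_vals = rng_len.integers(lo, hi + 1, size=spec.n_genes)
    lengths = {
        g: GeneModel(g, int(L)) for g, L in zip(gene_ids, length_vals)
    }

    rng_mean = np.random.default_rng(ss_mean)
    sigma = spec.baseline_sigma
    z = rng_mean.standard_normal(spec.n_genes)
    base_mean = spec.baseline_mean * np.exp(sigma * z - 0.5 * sigma * sigma)

    # Assign planted classes from a seeded permutation of the gene indices.
    rng_assign = np.random.default_rng(ss_assign)
    order = rng_assign.permutation(spec.n_genes)
    fold_fast = np.ones(spec.n_genes)
    fold_slow = np.ones(spec.n_genes)
    gene_class = {g: "null" for g in gene_ids}
    pos = 0
    for cls in DEG_CLASSES:
        count, fold = spec.planted.get(cls, (0, 1.0))
        idx = order[pos : pos + count]
        pos += count
        for rank, i in enumerate(idx):
            gene_class[gene_ids[i]] = cls
            if cls == "shared_up":
                fold_fast[i] = fold_slow[i] = fold
            elif cls == "shared_down":
                fold_fast[i] = fold_slow[i] = 1.0 / fold
            elif cls == "fast_only":
                fold_fast[i] = fold if rank % 2 == 0 else 1.0 / fold
            elif cls == "slow_only":
                fold_slow[i] = fold if rank % 2 == 0 else 1.0 / fold
            elif cls == "opposite":
                # Up under fast cooling, down under slow, relative to control.
                fold_fast[i] = fold
                fold_slow[i] = 1.0 / fold

    means = np.column_stack(
        [base_mean, base_mean * fold_fast, base_mean * fold_slow]
    )
    # Scale each column so the expected column sum equals the library size.
    lam = means * (np.asarray(spec.library_sizes, dtype=float) / means.sum(axis=0))

    rng_counts = np.random.default_rng(ss_counts)
    if spec.dispersion == 0.0:
        counts = rng_counts.poisson(lam)
    else:
        n_param = 1.0 / spec.dispersion
        p_param = n_param / (n_param + lam)
        counts = rng_counts.negative_binomial(n_param, p_param)
    matrix = CountMatrix(gene_ids, list(SAMPLES), counts.astype(np.int64))

    # Pathway annotation with optional planted over-representation.
    rng_pw = np.random.default_rng(ss_pw)
    pw_ids = _pathway_ids(spec.n_pathways)
    planted_by_id = {p.pathway_id: p for p in spec.planted_enriched}
    unknown = set(planted_by_id) - set(pw_ids)
    if unknown:
        raise ChillseqError(f"planted pathway ids not generated: {sorted(unknown)}")
    lo, hi = spec.pathway_size_range
    class_pools = {
        cls: [i for i, g in enumerate(gene_ids) if gene_class[g] == cls]
        for cls in DEG_CLASSES
    }
    class_pools["shared"] = (
        class_pools["shared_up"]
        + class_pools["shared_down"]
        + class_pools["opposite"]
    )
    pathways: list[Pathway] = []
    for pid in pw_ids:
        size = int(rng_pw.integers(lo, hi + 1))
        if pid in planted_by_id:
            plant = planted_by_id[pid]
            if plant.deg_class not in class_pools:
                raise ChillseqError(f"unknown planted DEG class {plant.deg_class!r}")
            pool = class_pools[plant.deg_class]
            if not pool:
                raise ChillseqError(
                    f"planted class {plant.deg_class!r} has no genes"
                )
            rate = min(0.9, plant.factor * len(pool) / spec.n_genes)
            k = min(len(pool), size, int(round(rate * size)))
            inside = rng_pw.choice(pool, size=k, replace=False)
            outside_pool = np.setdiff1d(
                np.arange(spec.n_genes), np.asarray(pool), assume_unique=False
            )
            outside = rng_pw.choice(outside_pool, size=size - k, replace=False)
            member_idx = np.concatenate([inside, outside])
        else:
            member_idx = rng_pw.choice(spec.n_genes, size=size, replace=False)
        members = frozenset(gene_ids[int(i)] for i in member_idx)
        pathways.append(Pathway(pid, f"synthetic pathway {pid}", members))
    db = PathwayDB(pathways)

    truth = TruthBundle(
        gene_class=gene_class,
        fold_fast={g: float(f) for g, f in zip(gene_ids, fold_fast)},
        fold_slow={g: float(f) for g, f in zip(gene_ids, fold_slow)},
        planted_pathways=planted_by_id,
    )
    return SimulatedExperiment(matrix, lengths, db, truth, spec)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _high_quality(rng: np.random.Generator, length: int, offset: int = 33) -> str:
    return "".join(chr(offset + int(q)) for q in rng.integers(30, 41, size=length))


def generate_fastq(
    n_reads: int,
    read_len: int,
    planted_fail_counts: Mapping[str, int],
    adapters: Sequence[str],
    seed: int,
) -> tuple[list[ReadRecord], list[str]]:
    """Reads with exactly the planted number of failures per QC category.

    ``planted_fail_counts`` keys: ``adapter``, ``n_fraction``,
    ``low_quality``. Failure categories are mutually exclusive by
    construction: adapter reads are otherwise clean, N-heavy reads carry 20%
    N with high quality, low-quality reads have 60% of bases at Phred 2.
    Returns the reads plus per-read truth labels (``ok`` or the category).
    """
    counts = {
        k: int(planted_fail_counts.get(k, 0))
        for k in ("adapter", "n_fraction", "low_quality")
    }
    extra = set(planted_fail_counts) - set(counts)
    if extra:
        raise ChillseqError(f"unknown QC categories: {sorted(extra)}")
    if any(v < 0 for v in counts.values()):
        raise ChillseqError("planted fail counts must be non-negative")
    if sum(counts.values()) > n_reads:
        raise ChillseqError("planted failures exceed n_reads")
    if counts["adapter"] > 0:
        if not adapters:
            raise ChillseqError("adapter failures planted but no adapters given")
        if min(len(a) for a in adapters) > read_len:
            raise ChillseqError("adapter longer than read length")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels_pool = (
        ["adapter"] * counts["adapter"]
        + ["n_fraction"] * counts["n_fraction"]
        + ["low_quality"] * counts["low_quality"]
        + ["ok"] * (n_reads - sum(counts.values()))
    )
    labels = [labels_pool[i] for i in rng.permutation(n_reads)]

    def clean_seq() -> str:
        while True:
            seq = _random_seq(rng, read_len)
            if not any(a in seq for a in adapters):
                return seq

    reads: list[ReadRecord] = []
    n_low = int(np.floor(0.6 * read_len))
    n_n = int(np.ceil(0.2 * read_len))
    for i, label in enumerate(labels):
        rid = f"read{i + 1:06d}"
        if label == "adapter":
            ad = adapters[int(rng.integers(0, len(adapters)))]
            pos = int(rng.integers(0, read_len - len(ad) + 1))
            seq = clean_seq()
            seq = seq[:pos] + ad + seq[pos + len(ad) :]
            reads.append(ReadRecord(rid, seq, _high_quality(rng, read_len)))
        elif label == "n_fraction":
            seq_arr = np.array(list(clean_seq()))
            n_pos = rng.choice(read_len, size=n_n, replace=False)
            seq_arr[n_pos] = "N"
            reads.append(
                ReadRecord(rid, "".join(seq_arr), _high_quality(rng, read_len))
            )
        elif label == "low_quality":
            qual_arr = np.array(list(_high_quality(rng, read_len)))
            low_pos = rng.choice(read_len, size=n_low, replace=False)
            qual_arr[low_pos] = chr(33 + 2)
            reads.append(ReadRecord(rid, clean_seq(), "".join(qual_arr)))
        else:
            reads.append(
                ReadRecord(rid, clean_seq(), _high_quality(rng, read_len))
            )
    return reads, labels


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered the planted truth."""

    sensitivity: dict[str, float]  # per planted DEG class
    observed_fdr: dict[str, float]  # per contrast (fast, slow)
    n_opposite_planted: int
    n_opposite_recovered: int
    pathway_ranks: dict[str, int]  # planted pathway -> 1-based rank by p_raw


def evaluate_recovery(
    fast_table: ContrastTable,
    slow_table: ContrastTable,
    truth: TruthBundle,
    enrichment_rows: Sequence[EnrichmentRow] | None = None,
) -> RecoveryReport:
    """Sensitivity per planted class, observed FDR per contrast, recovery
    of opposite-direction genes, and rank of planted pathways.

    A planted gene counts as recovered when it is called a DEG with the
    planted direction in every contrast where an effect was planted; a DEG
    call is false in a contrast when the gene's planted fold there is 1.
    Empty ratios use the convention 0/0 := 0.
    """
    known = set(truth.gene_class)
    for table in (fast_table, slow_table):
        stray = {r.gene_id for r in table.results} - known
        if stray:
            raise ChillseqError(
                f"contrast {table.name!r} contains genes absent from the "
                f"truth: {sorted(stray)[:5]}..."
            )

    fast_dir = {r.gene_id: r.direction for r in fast_table.results if r.is_deg}
    slow_dir = {r.gene_id: r.direction for r in slow_table.results if r.is_deg}

    def expected_dir(fold: float) -> str:
        return "up" if fold > 1.0 else "down"

    sensitivity: dict[str, float] = {}
    for cls in DEG_CLASSES:
        genes = truth.genes_of_class(cls)
        if not genes:
            continue
        hit = 0
        for g in genes:
            ok = True
            if truth.fold_fast[g] != 1.0:
                ok = ok and fast_dir.get(g) == expected_dir(truth.fold_fast[g])
            if truth.fold_slow[g] != 1.0:
                ok = ok and slow_dir.get(g) == expected_dir(truth.fold_slow[g])
            hit += ok
        sensitivity[cls] = hit / len(genes)

    observed_fdr: dict[str, float] = {}
    for label, table, folds in (
        ("fast", fast_table, truth.fold_fast),
        ("slow", slow_table, truth.fold_slow),
    ):
        called = [r.gene_id for r in table.results if r.is_deg]
        false = sum(1 for g in called if folds[g] == 1.0)
        observed_fdr[label] = false / len(called) if called else 0.0

    opposite_planted = truth.genes_of_class("opposite")
    flagged = {g for g, _, _ in opposite_direction(fast_table, slow_table)}
    n_recovered = len(flagged & opposite_planted)

    pathway_ranks: dict[str, int] = {}
    if enrichment_rows is not None:
        ranked = sorted(enrichment_rows, key=lambda r: (r.p_raw, r.pathway_id))
        for rank, row in enumerate(ranked, start=1):
            if row.pathway_id in truth.planted_pathways:
                pathway_ranks[row.pathway_id] = rank

    return RecoveryReport(
        sensitivity=sensitivity,
        observed_fdr=observed_fdr,
        n_opposite_planted=len(opposite_planted),
        n_opposite_recovered=n_recovered,
        pathway_ranks=pathway_ranks,
    )


def reference_scenario(seed: int = 1) -> ExperimentSpec:
    """The benchmark recovery scenario: 5,000 genes, three 1e6-read
    libraries, Poisson noise around a baseline mean of 50, 100 shared-up and
    100 shared-down genes at fold 4, 20 opposite-direction genes at fold 4,
    and one pathway (of 50) planted at 10x over-representation of the
    shared-up class."""
    return ExperimentSpec(
        n_genes=5000,
        library_sizes=(1_000_000, 1_000_000, 1_000_000),
        baseline_mean=50.0,
        dispersion=0.0,
        planted={
            "shared_up": (100, 4.0),
            "shared_down": (100, 4.0),
            "opposite": (20, 4.0),
        },
        n_pathways=50,
        pathway_size_range=(10, 60),
        planted_enriched=(PlantedPathway("pw0001", "shared_up", 10.0),),
        seed=seed,
    )
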