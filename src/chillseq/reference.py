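"""Published summary tables of the motivating experiment.

The pipeline was built around a three-library comparison of imbibed lettuce
seeds: an unfrozen control and seeds cooled to -20 °C fast (60 °C/h) or
slow (3 °C/h). The raw reads were never deposited, but the study's printed
summaries are recomputable arithmetic and serve as reference inputs: the
per-library read-mapping statistics, the reported DEG tallies per contrast,
the twelve genes that flipped direction between cooling rates, and the
significantly enriched KEGG pathways with their per-contrast p-values and
type labels.

Contrast key: ``fs`` = fast vs slow cooling, ``cf`` = control vs fast,
``cs`` = control vs slow.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import SampleStats

__all__ = [
    "MAPPING_STATS",
    "MAPPING_PERCENTS",
    "DEG_TALLIES",
    "SHARED_DEG_COUNT",
    "OPPOSITE_GENES",
    "ANNOTATABLE_DEGS",
    "PathwayCell",
    "PathwayRecord",
    "ENRICHED_PATHWAYS",
]

# Read-mapping statistics per library.
MAPPING_STATS: dict[str, SampleStats] = {
    "control": SampleStats(
        total_reads=12_413_353,
        total_base_pairs=608_254_297,
        total_mapped=8_429_247,
        perfect_match=6_873_209,
        le2_mismatch=1_556_038,
        unique_match=8_350_513,
        multi_match=78_734,
        unmapped=3_984_106,
    ),
    "fast": SampleStats(
        total_reads=11_702_598,
        total_base_pairs=573_427_302,
        total_mapped=7_730_392,
        perfect_match=6_296_355,
        le2_mismatch=1_434_037,
        unique_match=7_651_551,
        multi_match=78_841,
        unmapped=3_972_206,
    ),
    "slow": SampleStats(
        total_reads=11_527_110,
        total_base_pairs=564_828_390,
        total_mapped=7_579_398,
        perfect_match=6_051_017,
        le2_mismatch=1_528_381,
        unique_match=7_505_842,
        multi_match=73_556,
        unmapped=3_947_712,
    ),
}

# The percentages the mapping report prints (2-decimal rendering of each
# tally over total reads).
MAPPING_PERCENTS: dict[str, dict[str, str]] = {
    "control": {
        "total_reads": "100.00%",
        "total_mapped": "67.90%",
        "perfect_match": "55.37%",
        "le2_mismatch": "12.54%",
        "unique_match": "67.27%",
        "multi_match": "0.63%",
        "unmapped": "32.10%",
    },
    "fast": {
        "total_reads": "100.00%",
        "total_mapped": "66.06%",
        "perfect_match": "53.80%",
        "le2_mismatch": "12.25%",
        "unique_match": "65.38%",
        "multi_match": "0.67%",
        "unmapped": "33.94%",
    },
    "slow": {
        "total_reads": "100.00%",
        "total_mapped": "65.75%",
        "perfect_match": "52.49%",
        "le2_mismatch": "13.26%",
        "unique_match": "65.11%",
        "multi_match": "0.64%",
        "unmapped": "34.25%",
    },
}

# Reported DEG tallies per contrast: (up, down) at FDR <= 0.001 and
# |log2 ratio| >= 1.
DEG_TALLIES: dict[str, tuple[int, int]] = {
    "control_vs_fast": (968, 753),
    "control_vs_slow": (1089, 898),
    "fast_vs_slow": (780, 955),
}

# DEGs shared by the two cooling rates against control.
SHARED_DEG_COUNT = 570

# The twelve shared DEGs regulated in opposite directions between cooling
# rates: (gene_id, log2 ratio fast/control, FDR, log2 ratio slow/control,
# FDR).
OPPOSITE_GENES: list[tuple[str, float, float, float, float]] = [
    ("gi|90503171", -1.12, 3.45e-6, 1.05, 5.43e-11),
    ("gi|22259961", 1.65, 4.53e-11, -2.01, 1.16e-4),
    ("gi|22250752", 1.49, 6.90e-57, -2.33, 2.18e-35),
    ("gi|22225830", 1.44, 2.04e-17, -1.69, 6.08e-8),
    ("gi|22250698", 1.41, 3.40e-28, -1.66, 5.37e-13),
    ("gi|22240524", 1.36, 1.15e-13, -1.04, 9.88e-4),
    ("gi|22265151", 1.33, 2.23e-18, -1.13, 9.17e-6),
    ("gi|22253147", 1.32, 1.08e-28, -1.12, 1.35e-8),
    ("gi|22242137", 1.16, 6.30e-13, -1.27, 1.14e-6),
    ("gi|22254644", 1.10, 4.62e-8, -1.34, 3.78e-5),
    ("gi|90517427", 1.06, 9.68e-31, -1.40, 7.55e-22),
    ("gi|83979007", 1.04, 5.75e-18, -1.03, 2.19e-8),
]

# Number of pathway-annotatable DEGs (n of the hypergeometric test) per
# contrast.
ANNOTATABLE_DEGS: dict[str, int] = {"fs": 789, "cf": 904, "cs": 1027}


@dataclass(frozen=True)
class PathwayCell:
    """One contrast's entry for an enriched pathway: DEG count in the
    pathway, the printed percent of annotatable DEGs (None where the
    printed cell is absent or inconsistent), and the raw p-value."""

    m: int | None
    percent: float | None
    p: float


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    name: str
    type: str  # I / II / III / IV
    fs: PathwayCell | None
    cf: PathwayCell | None
    cs: PathwayCell | None


# The significantly enriched pathways and their cross-contrast
# classification. The percent of the RNA transport cs cell is printed
# inconsistently with its own m and n (0.38 vs 39/1027) and is left None;
# its fs cell prints a p-value with no DEG count.
ENRICHED_PATHWAYS: list[PathwayRecord] = [
    PathwayRecord(
        "ko03013", "RNA transport", "I",
        PathwayCell(None, None, 2.95e-5), None, PathwayCell(39, None, 0.001),
    ),
    PathwayRecord(
        "ko03040", "Spliceosome", "I",
        PathwayCell(29, 3.68, 0.001), None, PathwayCell(32, 3.12, 0.008),
    ),
    PathwayRecord(
        "ko04075", "Plant hormone signal transduction", "I",
        PathwayCell(44, 5.58, 0.001), None, PathwayCell(55, 5.36, 7.79e-4),
    ),
    PathwayRecord(
        "ko04144", "Endocytosis", "I",
        PathwayCell(15, 1.9, 0.032), None, PathwayCell(18, 1.75, 0.040),
    ),
    PathwayRecord(
        "ko00240", "Pyrimidine metabolism", "I",
        PathwayCell(16, 2.03, 0.041), None, PathwayCell(20, 1.95, 0.035),
    ),
    PathwayRecord(
        "ko03420", "Nucleotide excision repair", "I",
        PathwayCell(8, 1.01, 0.055), None, PathwayCell(14, 1.36, 0.001),
    ),
    PathwayRecord(
        "ko03440", "Homologous recombination", "II",
        PathwayCell(6, 0.76, 0.006),
        PathwayCell(6, 0.66, 0.011),
        PathwayCell(6, 0.58, 0.019),
    ),
    PathwayRecord(
        "ko03030", "DNA replication", "II",
        PathwayCell(7, 0.89, 0.013),
        PathwayCell(7, 0.77, 0.026),
        PathwayCell(14, 1.36, 5.53e-6),
    ),
    PathwayRecord(
        "ko04120", "Ubiquitin mediated proteolysis", "II",
        PathwayCell(18, 2.28, 0.064),
        PathwayCell(23, 2.54, 0.014),
        PathwayCell(29, 2.82, 0.001),
    ),
    PathwayRecord(
        "ko00250", "Alanine, aspartate and glutamate metabolism", "III",
        PathwayCell(15, 1.9, 0.004),
        PathwayCell(14, 1.55, 0.025),
        PathwayCell(14, 1.36, 0.061),
    ),
    PathwayRecord(
        "ko00062", "Fatty acid elongation", "III",
        PathwayCell(6, 0.76, 0.063), PathwayCell(8, 0.88, 0.016), None,
    ),
    PathwayRecord(
        "ko04141", "Protein processing in endoplasmic reticulum", "IV",
        None, PathwayCell(41, 4.54, 0.002), PathwayCell(40, 3.89, 0.021),
    ),
    PathwayRecord(
        "ko04712", "Circadian rhythm - plant", "IV",
        None, PathwayCell(12, 1.33, 0.021), PathwayCell(13, 1.27, 0.024),
    ),
]
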