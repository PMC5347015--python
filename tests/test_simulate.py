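"""Synthetic-experiment generator: determinism, planted truth, recovery."""

from __future__ import annotations

import numpy as np
import pytest

from chillseq.diffexpr import run_contrast
from chillseq.io import write_count_table, write_pathway_gmt
from chillseq.model import ChillseqError
from chillseq.simulate import (
    ExperimentSpec,
    PlantedPathway,
    evaluate_recovery,
    generate_experiment,
    generate_fastq,
    reference_scenario,
)


def _small_spec(**overrides) -> ExperimentSpec:
    base = dict(
        n_genes=400,
        library_sizes=(50_000, 50_000, 50_000),
        baseline_mean=50.0,
        dispersion=0.0,
        planted={"shared_up": (20, 4.0), "opposite": (5, 4.0)},
        n_pathways=10,
        pathway_size_range=(5, 15),
        seed=9,
    )
    base.update(overrides)
    return ExperimentSpec(**base)


class TestGenerateExperiment:
    def test_zero_planted_means_all_null(self):
        sim = generate_experiment(_small_spec(planted={}))
        assert set(sim.truth.gene_class.values()) == {"null"}
        assert all(f == 1.0 for f in sim.truth.fold_fast.values())

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            sim = generate_experiment(_small_spec())
            write_count_table(sim.counts, tmp_path / f"counts_{run}.tsv")
            write_pathway_gmt(sim.pathways, tmp_path / f"pw_{run}.gmt")
        assert (tmp_path / "counts_a.tsv").read_bytes() == (
            tmp_path / "counts_b.tsv"
        ).read_bytes()
        assert (tmp_path / "pw_a.gmt").read_bytes() == (
            tmp_path / "pw_b.gmt"
        ).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_experiment(_small_spec(seed=1))
        b = generate_experiment(_small_spec(seed=2))
        assert not np.array_equal(a.counts.counts, b.counts.counts)

    def test_column_sums_near_declared_library_sizes(self):
        spec = _small_spec(library_sizes=(200_000, 200_000, 200_000))
        sim = generate_experiment(spec)
        sums = sim.counts.counts.sum(axis=0)
        np.testing.assert_allclose(sums, spec.library_sizes, rtol=0.05)

    def test_planted_fold_recovered_in_column_means(self):
        spec = ExperimentSpec(
            n_genes=5000,
            library_sizes=(1_000_000,) * 3,
            baseline_mean=100.0,
            planted={"shared_up": (100, 4.0)},
            n_pathways=5,
            pathway_size_range=(5, 20),
            seed=21,
        )
        sim = generate_experiment(spec)
        up = sim.truth.genes_of_class("shared_up")
        idx = [sim.counts.gene_ids.index(g) for g in up]
        control = sim.counts.counts[idx, 0].astype(float)
        fast = sim.counts.counts[idx, 1].astype(float)
        assert fast.mean() / control.mean() == pytest.approx(4.0, rel=0.10)

    def test_opposite_genes_flip_between_contrasts(self):
        sim = generate_experiment(_small_spec())
        for g in sim.truth.genes_of_class("opposite"):
            assert sim.truth.fold_fast[g] > 1.0
            assert sim.truth.fold_slow[g] < 1.0

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ChillseqError, match="exceed"):
            _small_spec(planted={"shared_up": (500, 4.0)})
        with pytest.raises(ChillseqError, match="fold"):
            _small_spec(planted={"shared_up": (5, 0.5)})

    def test_negative_binomial_counts_overdispersed(self):
        poisson = generate_experiment(_small_spec(planted={}, dispersion=0.0))
        nb = generate_experiment(_small_spec(planted={}, dispersion=0.5))
        # variance/mean across genes: ~1 for Poisson, >> 1 for NB
        v_p = poisson.counts.counts[:, 0].var() / poisson.counts.counts[:, 0].mean()
        v_nb = nb.counts.counts[:, 0].var() / nb.counts.counts[:, 0].mean()
        assert v_nb > 3 * v_p

    def test_planted_pathway_overrepresents_class(self):
        spec = _small_spec(
            planted={"shared_up": (40, 4.0)},
            planted_enriched=(PlantedPathway("pw0001", "shared_up", 8.0),),
        )
        sim = generate_experiment(spec)
        up = sim.truth.genes_of_class("shared_up")
        planted = sim.pathways["pw0001"]
        rate_in = len(planted.members & up) / len(planted.members)
        rate_bg = len(up) / spec.n_genes
        assert rate_in > 3 * rate_bg


class TestGenerateFastq:
    def test_exact_planted_failure_counts(self):
        reads, labels = generate_fastq(
            50, 40, {"adapter": 4, "n_fraction": 3, "low_quality": 2}, ["ACGTACGTACGT"], 5
        )
        assert len(reads) == 50
        assert labels.count("adapter") == 4
        assert labels.count("n_fraction") == 3
        assert labels.count("low_quality") == 2

    def test_zero_failures_all_clean(self):
        reads, labels = generate_fastq(20, 30, {}, [], seed=1)
        assert set(labels) == {"ok"}
        assert all("N" not in r.sequence for r in reads)

    def test_same_seed_identical(self):
        a, _ = generate_fastq(30, 25, {"adapter": 3}, ["ACGTACGT"], seed=4)
        b, _ = generate_fastq(30, 25, {"adapter": 3}, ["ACGTACGT"], seed=4)
        assert a == b

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ChillseqError):
            generate_fastq(5, 30, {"adapter": 10}, ["ACGT"], seed=0)
        with pytest.raises(ChillseqError):
            generate_fastq(5, 30, {"adapter": 1}, [], seed=0)


class TestEvaluateRecovery:
    @pytest.fixture(scope="class")
    @staticmethod
    def sim_and_tables():
        spec = ExperimentSpec(
            n_genes=800,
            library_sizes=(300_000,) * 3,
            baseline_mean=60.0,
            planted={
                "shared_up": (30, 4.0),
                "shared_down": (30, 4.0),
                "opposite": (8, 4.0),
            },
            n_pathways=12,
            pathway_size_range=(8, 30),
            planted_enriched=(PlantedPathway("pw0001", "shared_up", 8.0),),
            seed=3,
        )
        sim = generate_experiment(spec)
        cf = run_contrast(sim.counts, "control", "fast")
        cs = run_contrast(sim.counts, "control", "slow")
        return sim, cf, cs

    def test_strong_planting_is_recovered(self, sim_and_tables):
        sim, cf, cs = sim_and_tables
        report = evaluate_recovery(cf, cs, sim.truth)
        assert report.sensitivity["shared_up"] >= 0.9
        assert report.sensitivity["shared_down"] >= 0.9
        assert report.observed_fdr["fast"] <= 0.05
        assert report.observed_fdr["slow"] <= 0.05

    def test_no_calls_yields_zero_by_convention(self, sim_and_tables):
        sim, cf, cs = sim_and_tables
        # strip every DEG call: sensitivity and FDR fall back to 0/0 := 0
        import dataclasses

        def uncall(table):
            table = dataclasses.replace(
                table,
                results=[
                    dataclasses.replace(r, is_deg=False) for r in table.results
                ],
            )
            return table

        report = evaluate_recovery(uncall(cf), uncall(cs), sim.truth)
        assert all(v == 0.0 for v in report.sensitivity.values())
        assert all(v == 0.0 for v in report.observed_fdr.values())

    def test_gene_id_mismatch_detected(self, sim_and_tables):
        sim, cf, cs = sim_and_tables
        import dataclasses

        bad = dataclasses.replace(
            cf,
            results=[dataclasses.replace(cf.results[0], gene_id="alien")]
            + cf.results[1:],
        )
        with pytest.raises(ChillseqError, match="alien"):
            evaluate_recovery(bad, cs, sim.truth)


def test_reference_scenario_is_fixed():
    spec = reference_scenario(seed=1)
    assert spec.n_genes == 5000
    assert spec.library_sizes == (1_000_000,) * 3
    assert spec.planted["opposite"] == (20, 4.0)
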