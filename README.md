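# chillseq

Differential-expression and pathway analysis for no-replicate, three-sample
RNA-seq designs — specifically the control / fast-cooled / slow-cooled
comparison used to study freezing tolerance of imbibed seeds, where each
condition is sequenced as a single library and classical replicate-based
models do not apply.

The package implements the full computational chain of such a study as a
tested, reusable library:

- **Clean-read filtering** of FASTQ input: whole-read removal of reads
  containing an adapter, reads with more than 10% unknown (N) bases, or
  reads with more than 50% of bases at Phred quality ≤ 5.
- **RPKM quantification**: `RPKM = 10⁹ · C / (L · N)` for a gene with `C`
  uniquely mapped reads and model length `L` bp in a library of `N`
  uniquely mapped reads, plus mapping-report percentage arithmetic.
- **Exact two-library differential expression** (the Audic–Claverie test).
  Conditional on count `x` in library A (size `N1`), the count `y` in
  library B (size `N2`) under equal expression follows

  ```
  p(y|x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1 + N2/N1)^(x+y+1) )
  ```

  evaluated in log-gamma space; the two-sided p-value is the doubled
  smaller tail (both tails including the observation), capped at 1.
  Benjamini–Hochberg FDR is applied per contrast, and a gene is a DEG when
  `FDR ≤ 0.001` and `|log2 ratio| ≥ 1` (both thresholds configurable).
- **Cross-contrast set analysis**: per-contrast up/down tallies, pairwise
  DEG intersections, and genes regulated in *opposite* directions between
  the two cooling rates.
- **Pathway over-representation**: upper-tail hypergeometric test
  `P(X ≥ m)` for a pathway with `M` annotated genes, `m` of the contrast's
  `n` annotatable DEGs, and `N` annotated genes overall, with Bonferroni
  correction at α = 0.05, followed by a four-type classification of
  significant pathways across the three contrasts (I: slow-cooling only;
  II: both rates, more significant under slow; III: fast-cooling only/more;
  IV: both rates, no rate difference).
- **Synthetic data with planted truth**: a generator for three-library
  count experiments (Poisson or negative-binomial noise, planted shared,
  rate-specific, and opposite-direction DEG classes, planted pathway
  enrichment) and toy FASTQ with planted QC failures, so every stage is
  verifiable without any external download.

## Worked example

`examples/exact_test_basics.py` runs the exact test on four hand-sized
observations:

```
            gene     x     y  log2_ratio            p
          steady   100   103       0.043    8.884e-01
      induced_4x    50   200       2.000    1.978e-22
  depth_artifact    50   100       0.000    9.694e-01
        silenced    40     0      -5.322    9.095e-13
```

`steady` (100 vs 103 reads at equal depth) and `depth_artifact` (50 vs 100
reads, but library B is twice as deep) are consistent with equal
expression; `induced_4x` and `silenced` clear both DEG thresholds. The
other examples simulate a full experiment and recover its planted truth:

```bash
python examples/simulate_and_call_degs.py    # DEG calling + opposite-direction genes
python examples/pathway_enrichment_types.py  # enrichment + type I-IV classification
python examples/qc_filtering.py              # clean-read filtering tally
```

For shell use, the same stages are exposed as a thin CLI:

```bash
chillseq simulate --outdir sim --n-genes 2000 --library-size 500000 --seed 7
chillseq de sim/counts.tsv --sample-a control --sample-b fast --out cf.tsv
chillseq all config.yaml    # every stage + checksummed artifact manifest
```

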