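# Methods

## The statistical setting

The design this package targets has one sequencing library per condition:
imbibed-seed control, fast cooling (60 °C/h to −20 °C) and slow cooling
(3 °C/h). With no replicates, between-gene dispersion cannot be estimated,
so differential expression rests on the exact two-library (Audic–Claverie)
test: under equal expression and Poisson sampling of tags, the count `y`
of a gene in library B, conditional on its count `x` in library A and the
library totals `N1`, `N2`, is distributed as

    p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1,

which is the negative binomial NB(x+1, 1/(1+r)). The test is exact but
inherits the Poisson assumption: biological over-dispersion (which the
design cannot see) makes it anti-conservative. The synthetic generator's
`dispersion` parameter exists precisely to document this limit — with
`dispersion > 0` counts are drawn negative-binomially (variance
μ + d·μ²) and null p-values become too small, which is a property of the
no-replicate design, not a bug in the implementation.

## Numerical choices

- The pmf is evaluated in log space via log-gamma. The two-sided p-value
  is `min(1, 2·min(P(Y≤y), P(Y≥y)))` with both tails including the
  observed `y`. Since `P(Y≤y) + P(Y≥y) = 1 + p(y|x) > 1`, the lower tail
  is computed first (log-sum-exp over `y' ≤ y`); the upper tail is only
  summed directly when the lower tail exceeds ½, term by term from `y`
  upward with the term ratio `(x+y'+1)/(y'+1) · r/(1+r)`, stopping when
  the geometric remainder bound falls below 1e−15 of the accumulated sum.
  The upper sum is accumulated as a scale factor on the first term, so it
  cannot under- or overflow even when `p(y|x)` itself underflows a double.
  Against an exact rational-arithmetic oracle the worst relative error
  over all `x, y ≤ 50` and library ratios 1/10–10 is ~1e−13.
- `log2_ratio` is the log2 of normalized counts `(y/N2)/(x/N1)`; gene
  length cancels, so this equals the RPKM ratio. Zeros are substituted by
  1 **only** inside the ratio; genes at zero in both samples are excluded
  from testing entirely. This keeps the exact test untouched while
  avoiding infinite ratios.
- `N1`/`N2` default to the per-sample totals of uniquely mapped reads
  (consistent with the RPKM definition); `run_contrast(..., totals=...)`
  switches to any other totals (e.g. total clean reads) since the two
  conventions differ in principle.
- Benjamini–Hochberg adjustment is computed per contrast over tested genes
  only (delegated to statsmodels; a naive double-loop oracle guards it in
  the tests). Ties receive identical q-values by construction of the
  step-up.
- The hypergeometric upper tail `P(X ≥ m)` includes the observed `m`, the
  standard over-representation convention (delegated to scipy's
  log-space survival function; an exhaustive-enumeration oracle covers
  every configuration with N ≤ 12 in the tests).
- Percent rendering (mapping reports, enrichment tables) is exact integer
  arithmetic rounded half-away-from-zero to 2 decimals, so renderings
  never inherit binary floating-point artefacts.
- The two-sided construction is **not** exactly invariant under swapping
  the two libraries (conditioning moves from `x` to `y`); the swap
  agreement is asymptotic and is asserted only at moderate counts. What is
  exact is that p depends on the libraries only through their ratio.

## DEG calling and set analysis

A gene is a DEG when `FDR ≤ 0.001` **and** `|log2 ratio| ≥ 1` (a
conjunction; both thresholds configurable). Direction is the sign of the
log2 ratio oriented second-sample-over-first in the `<A>_vs_<B>` naming
convention. Shared DEGs are the intersection of two contrasts' DEG sets;
opposite-direction genes are shared DEGs whose directions differ — the
signature of processes that respond to the *rate* of cooling rather than
to cold itself.

## Pathway typing

Enrichment significance is `p ≤ α` (α = 0.05) on **raw** p-values; the
reference pathway table reports values just above 0.05 alongside dashes
for non-significant cells, which implies uncorrected reporting (Bonferroni
values are still computed and written). The four types are decided per
pathway from the three contrasts (fs = fast vs slow, cf = control vs fast,
cs = control vs slow):

- **I** — significant in cs but not cf;
- **III** — significant in cf but not cs;
- **II vs IV** (significant in both): type II when the fs contrast is
  itself significant *or* `p_cs < p_cf`, else type IV.

The II/IV disambiguator is a package rule chosen because it reproduces
every row of the reference table (including a row significant in both
control contrasts whose fs p-value is 0.064); it is exposed as an
overridable callable (`rate_difference_rule`) for users who prefer a
different notion of "more significant under slow cooling". One reference
cell ("RNA transport", 39 DEGs printed as 0.38% of 1027) is internally
inconsistent with its own counts and is excluded from the percent checks.

## The synthetic generator

`generate_experiment` emulates the study-shaped experiment: per-gene
baseline means are log-normal around `baseline_mean` (σ = 0.5 by default —
a moderate between-gene spread that keeps planted effects in the
detectable range; real transcriptomes are heavier-tailed, which users can
emulate by raising `baseline_sigma`), planted classes multiply the mean in
the affected columns (shared_up/shared_down in both treatment columns,
fast_only/slow_only in one — split evenly up/down by deterministic
alternation — and opposite: up under fast, down under slow), and each
column's means are rescaled so its expected sum equals the requested
library size. Rescaling makes realized folds slightly smaller than planted
ones (by the ratio of column scale factors, ~6% in the benchmark); the
planted-fold checks budget for this. Counts are Poisson draws (negative
binomial when `dispersion > 0`). Pathway membership is uniform except for
planted pathways, which draw a capped multiple (`factor`) of the class's
background rate from the target DEG class. All randomness flows from one
integer seed through named `SeedSequence` spawns, so identical spec + seed
gives byte-identical TSV/GMT/FASTQ output.

What the generator does **not** emulate: mapping ambiguity and gene-length
biases (counts are drawn directly, not from reads), correlated gene
modules, library-preparation batch effects, and heavy-tailed expression.
Passing recovery tests therefore demonstrate correctness of the pipeline's
inference under its own sampling assumptions, not performance on real
libraries.

Benchmark problem sizes were chosen to keep every check in seconds to a
couple of minutes on one core: the planted-recovery scenario uses 5,000
genes with 1e6-read libraries (baseline mean 50, fold 4, 100+100 shared
and 20 opposite genes, one 10× enriched pathway among 50); null
calibration uses 20,000 Poisson(50) gene pairs; the exact-test oracle grid
covers all `x, y ≤ 50` at five library ratios; the hypergeometric oracle
enumerates every universe up to N = 12. The study-scale defaults of
`ExperimentSpec` (20k genes, three 1e7-read libraries, 570 shared /
12 opposite planted genes) remain available for larger runs.

## Known limitations

- The exact test's null calibration is conservative-to-nominal under
  Poisson sampling (~4–5% of null genes at p ≤ 0.05) and anti-conservative
  under over-dispersion; no-replicate designs cannot do better.
- Adapter handling is whole-read removal by exact substring match; no
  trimming, no fuzzy matching.
- The enrichment background is caller-supplied (default: all genes with
  at least one pathway annotation); whether a genome-wide or
  expressed-gene background is appropriate is a study-design question the
  package does not decide.
- FDR is controlled per contrast; no cross-contrast multiplicity control
  is attempted.
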