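# Methods

## Data model and coordinates

All internal coordinates are 0-based half-open (BED convention).  Bismark
coverage and BSMAP-methratio inputs are 1-based and converted on read, so a
cytosine has one canonical position regardless of the dialect it arrived
in.  Rows with zero total reads carry no information and are dropped with a
warning rather than rejected; methratio rows are restricted to CpG context
when a context column is present.  Bulk data move as pandas DataFrames;
`CpGCall`, `SampleInfo`, `GeneModel` and `DmrCall` named tuples are the
validated row-level contract.

## Tiling

CpG observations on the − strand are pooled with the + strand C of the same
CpG dinucleotide (position p−1) before tiling.  Tiles are anchored at
genome coordinate 0 in steps of `tile_size` (non-sliding), which makes tile
identity comparable across samples.  Tile methylation is the read-weighted
pooled ratio, not the mean of per-CpG ratios, so that the per-tile
significance test operates on the same primitive counts.

The minimum-coverage phrase "10 CpGs per 100-bp tile" is ambiguous between
*pooled CpG read observations* and *distinct CpG sites*.  The default
interprets it as ≥ 10 pooled read observations (the common RRBS tiling
convention, and the only reading that behaves sensibly when a 100-bp tile
contains fewer than 10 CpG sites); a strict-sites mode (≥ N distinct sites
covered ≥ 1×) is available via `TilingParams(strict_sites=True)`.
Replicates are tiled per sample; pooling across replicates happens
downstream (means for deltas, summed counts for tests), so the caller — not
the tiler — owns replicate semantics.

## DMR definitions

Parameters (percent-methylation points unless noted), all on `DmrParams`:

| parameter | default | meaning |
|---|---|---|
| `delta_specific` | 50 | min difference target vs another tissue |
| `min_discriminating_tissues` | 5 | tissues that must satisfy the delta |
| `delta_postnatal` | 35 | min newborn−adult difference |
| `alpha_tile` | 0.05 | per-tile significance level |
| `prenatal_max_newborn_pct` | 5 | newborn level below which a tile is prenatal |
| `late_age_boundary_weeks` | 3 | age separating early from late demethylation |

"50 % less methylated" is read as an absolute difference of ≥ 50 points
(consistent with heatmap scales and standard DMR practice); a
relative-ratio mode exists behind `relative_delta`.  The nine-tissue panel
includes the target, so the comparison set is the eight other tissues and
the rule is "≥ 5 of the non-target panel"; both the panel size and the
count are parameters.  Tissue means use adult-age samples
(`age_filter=15.0` by default), since specificity is defined against the
mature state of each tissue.  Tiles with data in no more than half the
comparison panel are reported as untestable rather than silently counted
as negatives — RRBS sparsity must stay auditable.

The per-tile newborn-vs-adult test is Fisher's exact test on the
replicate-pooled 2×2 table (methylated/unmethylated × newborn/adult):
counts are the primitive data and replicate numbers are small.  A
replicate-level Welch t-test on percent values is available
(`tile_test_method="ttest"`).  The ≥ 35-point delta is applied to replicate
means, the significance test to pooled counts.  Per-tile p-values are used
at face value (`p < 0.05`) to match the published definitions of this
analysis style; Benjamini–Hochberg adjustment is available behind `fdr`.

Timing is a partition: *prenatal* (newborn level already below 5 %) takes
precedence; then *early/late postnatal* requires both the delta and the
test; *late* means the newborn-to-3-week drop has not yet reached the
postnatal delta.  When no boundary-age samples exist, postnatal calls are
labelled `early_or_late_unknown` instead of guessing.  De novo calls mirror
every sign (prenatal = already > 95 % at 1 week).

## Permutation test

The null replaces the k target-tissue columns with k columns drawn
uniformly without replacement from the non-target pool; drawn columns leave
the comparison panel for that permutation, and the true target columns are
excluded entirely, so the permuted design has the original shape and never
leaks target signal into the null.  The identical specificity rule is
re-evaluated per permutation from running per-tissue sums/counts (labels
change, reads do not, so no re-tiling).  The add-one estimator
`p = (1 + #{permuted ≥ observed})/(n_perm + 1)` never returns 0; when no
permutation reaches the observed count the result is flagged as an upper
bound.  10,000 permutations on the default 20,000-tile, 81-sample dataset
take well under a minute on one CPU.

## Annotation

Promoter = strand-aware [TSS−1 kb, TSS+100 bp); intragenic = gene extent
extended 1 kb past the TES; everything else intergenic; promoter wins when
both overlap, and overlap means ≥ 1 bp.  Nearest-TSS distances are signed
by gene orientation (negative upstream) with ties broken by lexicographic
gene id.  Gene assignment keeps multi-gene overlaps (no nearest-gene
collapse) because the association stage counts genes; "adjacent to a gene"
defaults to promoter ∪ intragenic, with a TSS-window mode as the
alternative adjacency definition.

## Expression association

Upregulated genes come from a supplied differential-expression table when
available; otherwise an internal stand-in rule is applied (mean fold ≥ 1.5
and Welch t-test p < 0.05 on log2(x+1) replicate values).  The background
is random segments length-matched to the DMR set (removing length bias;
fixed-length mode available), drawn uniformly with chromosomes weighted by
length, and passed through the *same* assignment routine as the foreground.
Both proportions are computed over gene-assigned intervals, and compared
with the pooled two-proportion z-test.  With both pooled proportions 0 or
1 the statistic is defined as 0 when the proportions agree and ±∞
otherwise.

## Synthetic data

The generator emulates the design the analysis assumes: 9 tissues × ages
{1, 3, 15} weeks × 3 replicates; 20,000 covered 100-bp tiles spaced 1 kb
apart on two chromosomes; 5–15 CpGs per tile with per-CpG depth
1 + Poisson(29); tile-level dropout at 10 % emulating RRBS missingness.
Planted truth: 100 prenatal, 40 early, 60 late (late > early, matching the
observed predominance of late demethylation in maturing liver), and 50
de novo tiles at a 60-point effect over a background mean of 85 %, plus a
10 % fraction of everywhere-unmethylated "island" tiles.  Per-CpG
methylation probabilities are Beta-distributed around the tile mean with
concentration 100 — dispersion kept small enough that pooled tile estimates
sit within binomial sampling error of the planted means (within 5 points
for ≥ 99 % of tiles at default depth).  The per-tile background level is
jittered but *shared across tissues*, so a zero-planting configuration is
exchangeable under tissue relabelling — the property the permutation-test
calibration study requires.

A gene grid (one 5-kb gene per 10 tile slots, alternating strand) receives
60 % of planted tiles inside gene bodies; 70 % of genes containing
early/late tiles are induced (fold 3) from the tile's demethylation onset
age, on a log-normal expression baseline with log-sd 0.1 replicate noise.
`dko_mode` freezes the target tissue at its 1-week methylation state at all
ages and attenuates the planted induction (factor 0.5 toward baseline);
`insr_mode` freezes only late-class tiles.  These emulate perturbations
that block all, or only late, postnatal demethylation.

What the generator does **not** model: genome sequence, CpG-density and
fragment-level coverage correlation, batch and conversion-efficiency
artifacts, cell-type heterogeneity, and hydroxymethylation.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed generative structure, not robustness to every artifact of real
bisulfite data.

## Numerical and degenerate-input choices

All thresholds are inclusive (≥).  Missing cells are NaN throughout;
means are over non-missing replicates, and a tile with no target-tissue
data is never called.  Fisher's test requires positive totals in both
groups and errors otherwise.  Random segments are redrawn up to 1,000
times each against the exclusion set before failing.  Every stochastic
routine takes an explicit seed; the pipeline derives all stage seeds from
one global seed and records it in the run manifest together with input
checksums, so reruns are byte-identical.

## Problem sizes used in validation

The statistical test suite runs the full default dataset (20,000 tiles,
81 samples, 10,000 permutations) once, a 200-run null-calibration study at
1,000 tiles × 1,000 permutations per run, and down-scaled (2,000-tile)
datasets for threshold sweeps and module-level properties — sizes chosen so
the whole suite completes in a few minutes while keeping every planted
effect detectable at the same signal-to-noise ratio as the full design.
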