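# Methods

## Scope and model

`gbmethyl` analyzes an invertebrate-style methylome in which CpG
methylation concentrates on gene bodies, forms two populations of low- and
high-methylated genes, is essentially tissue-invariant, and couples
inversely to chromatin accessibility and gene-expression variability. The
pipeline has six analysis stages (I/O, methylation calling, methylome
features, differential methylation, expression variability, accessibility)
plus an integration stage, and a synthetic-data generator that provides
ground truth for all of them. All genomic coordinates are 0-based
half-open internally; GFF3 is converted at the boundary, and the TSS of a
minus-strand gene is `end − 1`.

## Methylation calling

A CpG dyad has a cytosine at position p on the plus strand and p+1 on the
minus strand; each strand is called independently (per-strand sites are
the atomic unit; a pooled dyad view exists as a derived convenience). A
read observation survives filtering when the Phred quality at the C is at
least `q_c` (default 30) and the qualities of the two read bases before
and after the C — read coordinates, not reference — are all at least
`q_flank` (default 20); a read whose C lies within two bases of a read end
cannot satisfy the flanking rule and is dropped. A strand's site is
retained only with `min_per_strand` (default 3) surviving informative
reads. The ratio is C/(C+T); bases outside the bisulfite-informative
alphabet (sequencing error) count toward neither state, because the ratio
is defined over the informative alphabet only. Overlapping mates of one
pair contribute once per position (the first mate encountered wins), to
avoid pseudo-replication. "Uniquely mapped" is taken from the input's
own designation (MAPQ ≥ 20 and not secondary/supplementary); alignment is
out of scope and is not re-adjudicated.

Bisulfite conversion is estimated genome-wide from cytosines in non-CpG
context, assumed unmethylated: rate = T/(C+T) after the same base-quality
filters. This is a construction choice of the package — the standard
non-CpG estimator — exposed as `estimate_conversion`.

The streaming pileup is implemented in this package over
pysam-parsed records: the filter needs each observation's read-coordinate
flanking qualities and once-per-pair semantics, and the inputs are plain
coordinate-sorted SAM; its correctness is checked against an independent
per-read replay oracle in the tests.

## Methylome features

* Windowed tracks: unweighted mean ratio of retained CpGs per window
  (default 2 kb; step defaults to the window, i.e. non-overlapping).
  Windows without CpGs are missing, not zero.
* Gene-body methylation: unweighted mean of per-CpG ratios in the gene
  interval. Coverage weighting is deliberately avoided so sequencing depth
  cannot leak into the methylation estimate. Genes with fewer than 5
  retained CpGs are flagged `insufficient` and excluded from histograms,
  ranks and class-based stratifications (the threshold is configurable;
  5 is this package's default for "sufficient coverage").
* Classes: high iff mean > 0.4 (a mean of exactly 0.4 is low);
  `unmethylated` means a mean of exactly 0 over retained CpGs. A separate
  0.5 split used by some heatmap-style summaries is a configurable, not
  the default.
* CpG o/e = (#CpG · L)/(#C · #G) over the gene body; classes low < 0.6,
  medium < 1.2, high ≥ 1.2; undefined (flagged) when C or G is absent.
* Methylated-CpG density: strand-specific count of sites with ratio ≥ 0.8
  and coverage ≥ 3 per 1-kb non-overlapping window, per kb.
* Repeat methylation: mean ratio per (repeat class × intragenic/intergenic)
  stratum; a repeat is intragenic iff it overlaps any gene interval.

## Differential methylation

Between tissue groups the test is Wilcoxon signed-rank on the paired
per-CpG-position differences of group mean ratios, restricted to positions
retained in every sample; genes with fewer than 5 shared positions are
flagged underpowered and skipped. Zero differences are dropped before
ranking; the exact null distribution is used up to n = 25 without ties,
otherwise average ranks with the normal approximation and continuity
correction (scipy's implementation). The source procedure's description —
a rank-sum test "applied as a paired difference test" — is internally
ambiguous; the paired signed-rank reading is primary here and an unpaired
Mann–Whitney variant over the per-position group means is available behind
`paired=False`. The cutoff is raw p < 0.1 with no multiple-testing
correction by default, mirroring the screen it reproduces;
Benjamini–Hochberg is available via `fdr=True`.

Between species, a gene is differentially methylated iff the absolute
difference of gene-body means exceeds 0.1 (strictly), with the sign
recorded; `dmg_direction_summary` reports the fraction more methylated in
each species. `group_mean_comparison` is a two-tailed two-sample t test on
per-gene values (gene-body means, or per-gene CV).

## Expression variability

CV = sample SD (n − 1 denominator; configurable) divided by the mean of
TPM across replicates within one tissue and species; undefined and flagged
at mean 0. Expression ranks are equal-count bins (quintiles/octiles) of
the per-tissue mean TPM across replicates — pooled-replicate means, not
per-replicate ranks — with ties broken deterministically by gene id.
Methylation rank 0 holds genes whose gene-body mean is exactly 0 over
retained CpGs ("completely unmethylated"); genes with insufficient CpG
data are excluded rather than ranked 0; the remaining genes form deciles
1–10. All statistics run on raw TPM; log10(TPM+1) is for display only.

The rank–CV trend statistic is Spearman ρ computed over genes
(each gene contributing its methylation rank and CV), not over the 11
per-rank medians: with only 11 rank-level points the null distribution of
ρ is far too wide to certify the absence of a trend, while the gene-level
statistic is calibrated at any study size. The per-rank median/IQR table
is still reported for display. The expression-rank methylation profile
fits a quadratic in rank over genes and reports the curvature sign
(negative = inverted U, extremes undermethylated).

## Accessibility

TSS coverage is per-base fragment-overlap count on
[TSS − flank, TSS + flank) (default flank 2 kb), strand-oriented so that
positive offsets point into the gene body; for minus-strand genes the
window is (TSS − flank, TSS + flank] before reversal so offset 0 lands
exactly on the TSS. Window parts outside the scaffold are masked invalid,
not zero-filled. Metagene profiles are the per-offset mean over stratum
genes, binned to 10 bp; values are raw mean fragment coverage (no
library-size normalization by default — synthetic comparisons are within
one library — with a counts-per-million switch for real multi-library
input). Replicates are checked by pairwise Pearson correlation, then
pooled. The promoter window for peak overlap is [TSS − 1000, TSS + 500)
strand-oriented; this definition is a package default — the quantity is
sensitive to it, and it is configurable. A peak counts once no matter how
many promoters it touches.

## Integration

The two-state model is an explicit operationalization (stated in the
report headers): `methylated_stable` = methylation class high and CV
quintile in {1, 2}; `low_meth_variable` = class low/unmethylated and CV
quintile in {4, 5}; anything else, or any gene missing an input, is
unassigned with a reason. `figure_faithful=True` restricts to quintiles
{1} and {5}. Housekeeping flags come from the annotation (the generator
plants them); sequence-similarity identification of housekeeping genes is
out of scope. `build_report` writes every stage table with a fixed float
format plus a manifest (package versions, seed, config hash, per-table
sha256); a missing stage raises rather than emitting a partial report, so
reruns are byte-identical by construction.

## Synthetic data generator

The generator emulates, at desk scale, the statistical structure the
analyses assume. Defaults (the "paper-like" preset): 2 scaffolds × 500 kb;
300 genes of 1.2–3.6 kb placed without overlap (gene sizes are a generator
convention chosen so the genes fit the scaffolds with realistic intergenic
space; high-methylation genes draw from the upper part of the range);
gene-body methylation a 0.45/0.55 mixture of Beta(1.5, 20) and
Beta(20, 3); housekeeping fraction 0.12 drawn 90% from the high component;
CpG dyad rates 0.022/bp (low-methylation genes), 0.011/bp (high;
CpG-poorer, echoing methylation-driven CpG depletion) and 0.012/bp
intergenic with Beta(1, 40) site-level methylation; repeats of five
classes, 40% intragenic (inheriting host-gene methylation by position);
read depth 20 per dyad (Poisson per strand), conversion 0.99, base error
0.001. Expression: mean TPM log-normal (ln-scale μ = 2, σ = 1.2) in the
gene's expression percentile, replicate TPMs Gamma with
CV(g) = 0.6 − 0.4·m(g) + N(0, 0.15), floored at 0.05; an optional
parabolic coupling (default 0.25) undermethylates the extreme expression
percentiles. Accessibility amplitude =
(1 + 1.5·u_expr) · exp(−1.5·m) · (1 + 1·(1 − u_cv) if m < 0.4 else 1),
fragments Gaussian around the TSS (SD 150 bp) over a uniform background
of 0.5 fragments/kb; peak intervals are emitted where 200-bp binned
fragment counts exceed 5× the background median (a deliberately simple
stand-in for peak calling, which is out of scope). Planted species
differences shift gene-body methylation of 50 genes by 0.3 (90% downward
in the second species, i.e. the parent species more methylated), planted
only on genes with headroom for the full shift so clipping at [0, 1]
cannot silently shrink the planted effect. Presets `null_preset` (all
couplings off) and `high_noise` (shallow, poorly converted, noisy) cover
the null and stress conditions. Every draw consumes one seeded
`numpy.random.Generator`, so outputs are byte-reproducible.

What the generator does **not** emulate: read-level error profiles
(indels, adapters), PCR duplicates, mappability structure, CHH/CHG
methylation (the modeled pattern is CpG-specific), hydroxymethylation,
Tn5 insertion bias, or real peak calling. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artifact of real libraries.

## Numerical choices and problem sizes

Ratios at zero coverage are NaN, never 0. Equal-count binning breaks ties
by gene-id order (deterministic). Histogram modes are plateau-aware local
maxima of 0.1-bin counts. The tests and the acceptance script size their
simulations for tight Monte-Carlo bands at interactive runtimes: 1,000
random dyads for calling-oracle equivalence; 300 genes at depth 30 for
gene-mean recovery (compared, per gene, within 3 binomial SDs of the
conversion-adjusted expected called ratio); 1,000 genes for tissue
invariance and the null calibration of the tissue test; 4,000 genes for
the accessibility orderings, where the limiting comparison — the
near-equality of the two high-methylation variability strata — needs
large strata because stratum means inherit the between-gene spread of the
other amplitude factors.

## Known limitations

* The tissue test's pairing of per-position group means is one reading of
  an ambiguous prose description; the unpaired variant is provided for
  comparison but the two are not interchangeable on real data.
* The promoter window and the metagene flank are package defaults; counts
  that depend on them (promoter-overlapping peaks) are not comparable
  across tools without matching those definitions.
* Gene-body means are unweighted across CpGs, so genes with few retained
  CpGs are noisy; the `insufficient` flag (< 5 CpGs) is a blunt guard.
* The conversion estimator assumes non-CpG cytosines are unmethylated;
  genuine CHH/CHG methylation would bias it downward.
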