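# Methods

This note documents the estimators implemented in `divscan`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not show.

## Coordinates and genotype model

All internal coordinates are 0-based half-open (BED convention); VCF `POS`
(1-based) and GFF3 (1-based closed) are converted at ingest, so a SNP at VCF
position *p* lies in window [s, e) iff s ≤ p−1 < e. Genotypes are diploid
dosage codes 0/1/2 with an explicit missing code; half-called genotypes
(`./1`) are treated as missing and phase is ignored. Multiallelic and indel
records are dropped at ingest with logged counts; chromosome exclusion (e.g.
the X) is a configurable ingest-time list.

## Hard filters

Rules apply in a fixed order — chromosome exclude → QUAL → depth →
missingness → MAF — and each dropped site is charged to the first rule it
fails, so drop counts sum to sites dropped. Defaults: QUAL ≥ 30, site depth
within [⅓×, 2×] of the dataset mean, missingness ≤ 0.10, MAF ≥ 0.05. The
QUAL/depth defaults are this package's choices of commonly used values; the
missingness and MAF values follow the pruning stage's published thresholds.
The MAF rule applies to variant sites only: invariant records carry no minor
allele and must survive as callable sites for the π/Dxy denominators.

The depth rule is *mean-relative* (an absolute-bounds alternative would be
trivial but mean-relative adapts across datasets). A consequence worth
knowing: re-filtering a filtered matrix recomputes the mean, so strict
idempotence is guaranteed only when depths are constant or the depth rule is
disabled; in practice surviving depths are confined to the original band and
re-drops are rare to none.

## LD pruning

Greedy windowed pruning in the style of `--indep-pairwise 50 10 0.2`: within
each 50-SNP window, every pair of still-kept sites with dosage r² > 0.2 loses
its later-positioned member; the window then advances 10 SNPs. r² is the
squared Pearson correlation of dosages over pairwise-complete samples.
Removing the *later* site of an offending pair is a deterministic tie-break
(reference implementations vary by version); the output is invariant for a
fixed input and verified post hoc by re-scanning all windows.

## Window statistics

π and D<sub>xy</sub> use per-site numerators and denominators summed over the
window:

- site π numerator c(n−c), denominator n(n−1)/2, with c the alt-allele count
  and n the called alleles at that site (skipped when n < 2);
- site D<sub>xy</sub> numerator c₁(n₂−c₂) + c₂(n₁−c₁), denominator n₁n₂
  (skipped when either population is uncalled).

Invariant sites contribute zero numerator and full denominator. This is the
missing-data-aware ("pixy-style") estimator: genotypes missing completely at
random change both numerator and denominator proportionally, leaving the
estimate unbiased — verified in the tests by 10% MCAR masking. Absolute
per-bp values require all-sites input; for variant-only VCFs a
"window_length" denominator mode divides by window span and is labelled as
such in the output, because the two modes are not comparable.

F<sub>st</sub> is the Weir–Cockerham (1984) two-level diploid estimator. Per
variant site the among-population (a), among-individual (b) and
within-individual (c) variance components are computed from per-population
sample sizes, allele frequencies and observed heterozygote frequencies; a
window reports Σa / Σ(a+b+c) over its variant sites (the "weighted" ratio of
sums, as in the standard window-scan tools) rather than the mean of site
ratios, which is unstable at low-frequency sites. Negative values are
retained: clamping at zero would bias the empirical outlier threshold.
Windows with fewer than `min_variant_sites` (default 1) variant sites report
F<sub>st</sub> as undefined and are excluded from ranking. Sites where a
population has no called genotype, or with mean sample size ≤ 1, are skipped.

Windows are built per chromosome from position 0 with starts at multiples of
the step (defaults 50 kb / 10 kb) and truncated at the chromosome end.

## Outlier regions and core islands

The empirical top fraction (default 1%) flags the ⌈q·W⌉ highest-valued
defined windows; ties at the boundary are all included and the realized
threshold is reported. Flagged windows that overlap or lie ≤ 10 kb apart
merge into regions (the boundary is inclusive: a gap of exactly 10,000 bp
merges; this follows the realized-analysis description over the stricter "<"
phrasing of the protocol text, and the boundary is explicitly tested).
Core islands intersect the F<sub>st</sub> and D<sub>xy</sub> flag sets *at
the window level* before merging, which makes the core cover provably nested
inside both single-statistic covers (asserted on every pipeline run). Genes
overlap a region if they share ≥ 1 bp under half-open semantics.

## Relatedness (PI_HAT)

The method-of-moments estimator equates observed identity-by-state counts
(IBS0/1/2 over sites called in both samples, polymorphic in the panel) to
their expectations under the three IBD states given panel allele
frequencies, solving sequentially for P(IBD=0), P(IBD=1), P(IBD=2). The
solution is bounded: a state probability above 1 pins that state (this is
what produces PI_HAT = 0 for pairs *less* similar than random panel draws,
e.g. across diverged populations); negatives are clamped and the triple
renormalized. PI_HAT = P2 + P1/2; dissimilarity = 1 − PI_HAT. The
finite-sample correction factors some tools apply to the IBS expectations
are omitted; with the panel sizes used here the resulting bias is far inside
the ±0.05 validation tolerance. Pairs with < 50 informative sites are
flagged low-confidence.

Frequencies default to the pooled panel (the common single-run setup).
Pooling strongly diverged populations inflates apparent within-population
relatedness, because population-specific alleles look like IBD against
pooled expectations — a known property of the estimator, not a bug; a
per-population frequency mode is provided for de-confounded within-population
estimates.

## LD decay

Pairwise dosage r² is computed for same-chromosome variant pairs within 1 Mb
with MAF ≥ 0.10, and averaged in right-closed 10-kb bins ((k−1)·10kb,
k·10kb]; empty bins are reported with n = 0. Populations with < 4 samples
are refused unless forced: with two diploids nearly every polymorphic pair
gives r² ≈ 1 at any distance, so the curve carries no information. Between
independent sites the expected r² is ≈ 1/(n−1) ≈ 1/n (the sampling floor),
which is what the decay curve approaches at large distances.

## Enrichment

Over-representation is the upper hypergeometric tail P(X ≥ k) for k
candidate hits among a K-gene term, n candidates in an N-gene universe —
identical to the one-sided Fisher exact test on the 2×2 table, computed via
scipy's log-space implementation. The universe defaults to the genes
annotated in the term map (per-namespace universes arise by restricting the
map); candidates outside it are dropped with a logged count. Terms with
K < 5 are excluded before testing; the ranking carries no multiple-testing
correction (an optional BH-FDR column is emitted but never filters), and the
p < 0.10 display threshold affects reporting only.

A note on calibration: a strict discrete test is conservative — its attained
size P(p < 0.05) under the null is below 0.05 by an amount set by the
granularity of the test statistic. The null-calibration experiment therefore
uses large terms and candidate sets (near-continuous regime, attained size
≈ 0.048) and checks the empirical rejection rate both against the exact
analytic attained size and against the nominal level. With small terms the
test is *more* conservative, never anti-conservative.

## Synthetic data generator

The cohort generator draws, per site, an ancestral frequency p ~ U(0.10,
0.90), population frequencies from Beta(pλ, (1−p)λ) with λ = (1−F)/F (the
Balding–Nichols model, mean-preserving with E[F<sub>st</sub>] ≈ F), and
diploid genotypes Binomial(2, p_pop). Inside planted islands F jumps from
the background 0.05 to 0.60. Defaults emulate the motivating study design:
7 + 2 samples ("GLG"/"WL"), a 6-Mb genome (three 2-Mb chromosomes) at one
all-sites record per 400 bp with half the records invariant, 5% MCAR
missingness, and two 150-kb islands (5% of the genome). Asymmetric drift
(per-population F) is supported for emulating unequal diversity; the default
uses a shared F because it gives the analytic E[F<sub>st</sub>] ≈ F target.
The mutation rate (6×10⁻⁹/site/generation) and generation time (3 y) ride
along in the config for split-depth scaling and do not enter the draws.
QUAL and DP annotations are constants above the filter defaults unless a
filter-stress fixture is wanted. Everything is deterministic given the seed,
byte-for-byte.

Pedigree pairs are generated by Mendelian transmission from founder
genotypes (MZ copy, parent–offspring, full sibs, unrelated; expected PI_HAT
1, 0.5, 0.5, 0). LD is generated separately by haplotype copying from a
small founder pool with per-bp switch probability, giving r² that decays
with distance toward the 1/n floor; the cohort generator itself draws sites
independently (no linkage), which is why its r² profile is flat at the floor.

Fixture emission writes the all-sites VCF, popmap, a GFF3 with 10-kb genes
tiled every 20 kb (so islands always overlap known genes), a gene→term table
with one term planted on exactly the island genes plus random background
terms, the truth table, and island BED intervals.

### What the validation shows — and does not

The simulator validates estimator correctness (closed forms, oracle
equivalence, parameter recovery, calibration), not realism. It omits
linkage within the cohort, selection, demographic history, sequencing-error
structure, non-random missingness, and genotype-call uncertainty. Passing
the planted-island recovery therefore shows the scan machinery ranks and
merges truly divergent windows correctly under the stated model — it does
not certify power or error rates on real resequencing data, where window
autocorrelation and low-recombination regions can inflate clustering of
outliers.

## Validation experiment sizes and the island-recovery protocol

Validation experiments use 5,000-site genomes with 20+20 samples for
F<sub>st</sub>/π recovery, 20 replicate pairs × 5,000 sites for relatedness,
10 replicate cohorts for island recovery, and 1,000 null draws × 40 terms
for calibration — sizes at which the Monte-Carlo error is a small fraction
of each tolerance.

Island recovery flags the top-q fraction of windows where q is the realized
prevalence of planted-island windows (windows with ≥ 50% of their span
inside an island), ~5% under the default fixture. This measures what the
experiment can measure — that the scan *ranks* island windows above
background and merges them correctly; a 1% flag budget over a 5% planted
prevalence would bound recall at ~0.2 by arithmetic alone, saying nothing
about the statistics. The production default for real scans remains the
top 1%.

## Numerical choices

- Undefined values (uncallable sites, F<sub>st</sub> in variant-free
  windows, all-missing MAF) are NaN, excluded from ranking, and flagged —
  never silently zeroed.
- Outlier ranking is rank-based (⌈q·W⌉ windows) rather than
  interpolated-quantile-based, with boundary ties included: reproducible
  without quantile-method ambiguity.
- Degenerate inputs: empty flag sets merge to empty region lists; an
  all-equal statistic flags every window with a logged warning; empty
  candidate sets yield an empty (all-k=0) enrichment table with a warning.
- Dissimilarity matrices are exactly symmetric with a zero diagonal by
  construction.
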