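# Methods

This note documents the models and procedures implemented in `loopvar`, the
defaults that matter, the design choices made where the procedure was
genuinely open, and what the synthetic-data tests do and do not establish.

## Coordinates and loop geometry

All intervals are 0-based, half-open (BED convention); BEDPE I/O preserves
this. A loop is a pair of same-chromosome anchors stored in canonical order
(anchorA.start <= anchorB.start, ties by end); loops are unstranded. The
distance between two intervals is always the *gap* distance (0 when they
overlap). Two loops are "within s bp" when **both** anchor pairs have gap
distance <= s; midpoint distance was rejected because merged anchors would be
ill-defined for wide anchors. Merging groups loops by the transitive closure
of this relation (connected components). With the `union_span` keep rule the
bounding anchors of two separate groups can themselves fall within the slack
through different member pairs, so merging iterates to a fixpoint; this makes
`merge_loops` idempotent for every keep rule. Tie-breaks everywhere are:
smallest p/q, then smallest total anchor length, then coordinate order.

`find_span` returns [anchorA.start, max(anchorA.end, anchorB.end)); the max
only matters for degenerate nested anchors and keeps the span at least as
long as each anchor.

## Harmonizing caller output

Fit-Hi-C-style grids are pruned by requiring, for each anchor with the other
fixed, that at least 3 of the 5 bins immediately upstream of the opposing
anchor are significant OR at least 3 of the 5 downstream (out-of-range bins
count as not significant); the published wording is ambiguous between OR/AND
across the two directions and anchors — we use OR within an anchor and AND
across anchors, which is the strictest reading that keeps isolated one-sided
stripes. After pruning, interactions are merged within 20 kb keeping the most
significant call, and singletons (no other pre-merge interaction within
20 kb) are discarded.

HICCUPS-style calls merge within 20 kb at resolutions <= 10 kb and within
twice the anchor size (2 x resolution, anchors being one bin wide) above
that. Collapsing across resolutions groups all calls at 20 kb slack, keeps
the finest-resolution call, records support = number of distinct
contributing resolutions, and drops support < 3 (HICCUPS-style) or < 7
(Fit-Hi-C-style) — thresholds read inclusively ("less than"). Cross-caller
intersection keeps the member with the smallest total anchor length per
group. Union merge events are resolved by size: 1 kept, 2 merged with
bounding anchors, 3 -> closest pair (Chebyshev distance on anchor gaps)
merged and the third kept as called; events larger than 3 (possible on
synthetic data) are resolved by greedy disjoint closest-pair merging and
flagged `big_event`.

## Null loop sets

Assembly gaps are deleted to build a piecewise-linear no-gap coordinate
system per chromosome. For each null set and chromosome one shift d is drawn
uniformly from (2 Mb, no-gap length - 2 Mb) — per chromosome, not
genome-wide, because the constraint is stated in terms of the chromosome
size. Each loop moves as a unit (start shifted modulo the no-gap length; a
loop crossing the chromosome end is placed at the beginning), so anchor
lengths and anchor-anchor distances are preserved exactly for every
survivor and the removal fraction on a gap-free genome is zero. After
mapping back, loops with an anchor overlapping a gap are removed; on the
synthetic genome (5% gap fraction) this removes a fraction of loops
comparable to the anchor-gap collision rate checked by a Monte-Carlo oracle.
The generator seed is recorded in the provenance of each set.

## Differential contact propensity

TMM follows the standard formulation: reference sample by upper-quartile
closeness to the mean, M/A double trimming (30% / 5% from each tail),
inverse-variance (delta-method) weights, factors rescaled to log-mean zero.
Factor invariance to rescaling one library is near-exact, not exact, because
the precision weights feel the library size. logCPM uses a prior count of
0.5: log2((y + 0.5) / (N·f + 1) · 1e6); other fixed priors would be equally
acceptable — nothing downstream depends on the choice.

The per-loop test is a two-group negative-binomial GLM with offset
log(library x TMM factor). Dispersion is a trend: per-loop moment estimates
(df-adjusted Pearson-style) smoothed by lowess against average abundance.
The statistic is the deviance drop of the group effect divided by an
empirical-Bayes-moderated quasi-dispersion (per-loop deviance / residual df,
shrunk toward a fitted scaled-F prior via the moments of log s2; prior df by
trigamma inversion), referred to F(1, d0 + df). This mirrors the
quasi-likelihood count pipeline widely used for such data but is an
independent implementation and is not bit-identical to any existing package;
its acceptance surface is calibration — type-I error within [0.03, 0.07] at
p < 0.05 on null NB counts, >= 95% power for 4-fold effects at the study's
sample sizes (11 vs 13), and log2FC bias <= 0.05 at mean count >= 50 — all
asserted in the test suite. Loops with q < 0.01 (BH) are CTALs, signed by
the iPSC-positive fold change.

Compartments: PC1 of the correlation matrix of the normalized 1-Mb contact
matrix (all-zero bins masked; sign fixed by the largest-magnitude loading for
determinism); the sign partitions bins, and the side with the higher mean
read count in all three activity assays (RNA, H3K27ac, ATAC) — or in two of
three when they disagree — is labeled A. `variance_explained` is the plain
one-way between-group R².

## Family-based phasing correction

The crossover scan is the cumulative score S_k = sum s_i with s_i = +1 when
the transmitted allele matches parental haplotype 1 only, -1 for haplotype 2
only, 0 otherwise. "Extreme points" are operationalized as turning points at
which S retreats from a running extreme by at least m informative sites
(default m = 10, configurable); extremes at the sequence boundary are not
turning points. The published procedure gives no threshold; m = 10 balances
missing short true double-crossovers against calling noise.

The trio pipeline feeds the scan the *genotype-derived transmitted-allele
sequence* (child homozygous sites, plus child-het sites where the other
parent is homozygous) rather than the raw child haplotype: the raw haplotype
is corrupted by the child's own switch errors (at the synthetic 1% per-site
switch rate roughly half the chromosome is in a flipped state), while the
derived sequence is immune to them. The scan operation itself accepts any
allele sequence. Within blocks, a local window match (nearest 5 informative
sites each side) refines the block haplotype so short phasing-switch
segments in the *parent* do not propagate into predictions.

Re-phasing sets each child site to the predicted (paternal, maternal) pair
when it is consistent with the child's genotype; unphased sites with a
unique consistent assignment are phased; when exactly one parent's
prediction conflicts with the genotype, the genotype-implied allele
overrides the prediction with the lower local-match margin. Sites with no
consistent assignment are marked, never silently altered, and removed
family-wide by the final filter (which is idempotent and leaves zero
genotype-level Mendelian violations — asserted exhaustively).

Identifiability: with a single child per founder couple, a founder's phasing
switch errors and the crossovers of that founder's meiosis produce identical
signals and cannot be separated. Error correction is therefore scored on the
three non-founders (>= 99% of injected switch errors fixed), and crossover
localization (within 10 informative sites) on the proband's two meioses,
whose parents have been corrected first. Founder haplotype labels are left
as given. Sex chromosomes are out of scope; all sites are treated as
autosomal and biallelic.

The parent-combination matcher averages concordance in 1-Mb bins at
child-heterozygous sites. At sites where child and parent are both
heterozygous, biallelic haplotypes are complementary, so only
parent-homozygous sites actually separate the two pairings; an exact tie is
an error (ambiguous input — e.g. heavily switch-corrupted phasing, where the
global pairing is genuinely meaningless; the site-wise fix does not depend
on it).

## Allelic imbalance and power

A contact is informative for a loop when its ends fall in the two opposing
anchors padded by 25 kb and all overlapped het-SNV labels agree; conflicts
are discarded. Per individual, Z = (k - n/2)/sqrt(n/4) on the greater allele
count, p half-normal, clamped into (0, 1]. Individuals with zero informative
contacts at a loop are excluded from that loop's meta-analysis; df = 2 x
contributors (the source is silent; excluding non-contributors is the only
choice that keeps Fisher's method well-defined). The minimum per-individual
depth defaults to n >= 1 and is exposed as a flag. Allelic fold change is
log2(greater/lesser), pseudocount 0.5 when a side is zero. BH q < 0.05
defines HTALs.

The power grid reads the design calculation deterministically: Z from the
*expected* greater-allele count k = f·n (not rounded), power 100% when the
half-normal p <= alpha, else 0% — the only reading consistent with "100%
power at n = 50, f = 0.70, alpha = 0.02", which the grid reproduces. The
same table carries the Fisher-combined power across 7 identical individuals.
An exact-binomial mode (power = P(p(K) <= alpha), K ~ Binomial(n, f), by
enumeration) is provided as a labelled alternative and is never the default.
The discrete-n normal approximation makes the per-loop test slightly
mis-calibrated at small n; under Binomial(50, 0.5) nulls the meta-test's
empirical type-I error at 0.05 sits within [0.04, 0.07] (asserted).

## Enrichment statistics

Every 2x2 enrichment routes through one `fisher_exact` path: exact
hypergeometric p (two-sided by the point-probability rule), sample odds
ratio with a 0.5 continuity correction only when a cell is zero (the p-value
is always exact). State enrichment compares anchor-bin composition against
the genome-wide bin composition (so anchors covering the whole genome give
OR = 1 identically), Bonferroni at 0.05/n_states. The paired-state network
enumerates all unordered state pairs including self-pairs (the stated "125
pairs" for 15 states does not match C(15,2)+15 = 120; we enumerate the 120);
expected counts come from null loop sets in permutation mode or from the
contrast group (HTAL vs non-HTAL, FDR) in contrast mode. Threshold sweeps
keep the full union as background (HTALs included — the stated comparison is
against the union set; an exclusion flag exists), so the loosest threshold
has OR = 1 by construction. The CNV test is the stated one-sided
binomial-normal against mu = 0.37 (= 1045 duplications / 2812 CNVs).
Mann-Whitney is exact (enumeration-verified) for groups of <= 8, otherwise
normal with tie correction. Concordance is Pearson on raw pairs with binned
quartile summaries for display; maternal fold change is log2(maf/(1-maf)).

## Synthetic data: what it emulates and what it does not

Scale defaults: 2 chromosomes x 30 Mb, 5% gap fraction, 500 loops (anchor
width 10 kb, spans log-normal clipped to 70 kb–1 Mb), 11 + 13 samples over 7
individuals, NB counts with mean 100 and dispersion 0.05, ~50 informative
contacts per loop per individual, 10% CTALs (|log2FC| uniform 0.5–2), 1%
HTALs at imbalance 0.75, phenotype fold changes with sd 2 coupled to loop
fold changes with slope 0.1 and noise 0.1 — so phenotypes swing orders of
magnitude further than loops, as in the real system. The pedigree default is
30,000 het sites per 30-Mb chromosome (density-matched to roughly one het
site per kilobase genome-wide), 1–2 crossovers per chromosome per meiosis,
1% switch, 0.1% point and 2% unphased rates applied to all seven
individuals. The full pipeline runs in well under five minutes on one CPU.

Not emulated: restriction-fragment structure, read-level sequences and
mapping bias, GC/mappability fields (held constant in the real analysis by
comparing identical loci), distance-dependent contact decay inside anchors,
and linkage disequilibrium. Passing tests therefore establish the
correctness and calibration of the *statistical machinery* under the stated
generative model, not robustness to alignment artefacts or biased phasing
input. Caller emulation attaches true loops to >= 7 / >= 3 resolutions with
one-bin jitter and spurious calls to <= 2 resolutions; harmonization
recovering >= 95% of true and <= 5% of spurious loops is a property of this
noise model at these densities.

## Numerical details

Newton iterations for NB group means are clipped to +-5 per step and run to
1e-10; dispersions are clipped to [1e-6, 10]; p-values are clamped to the
smallest positive double before logs; BH is scipy's step-up. All randomness
flows from explicit `numpy.random.Generator` seeds; identical seeds give
byte-identical outputs. Degenerate inputs (empty loop sets, all-zero
libraries, single-sample groups, zero informative contacts, n = 0 tests)
raise or are skipped with counters as documented per function, never
silently imputed.
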