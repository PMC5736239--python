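# Methods

## Data model and coordinates

All genomic intervals are 0-based half-open internally; the on-disk
ascat dialect (1-based inclusive) and sequenza dialect are converted at
parse time.  A segment call is a tuple (sample, chrom, start, end,
n_major, n_minor) with n_major ≥ n_minor ≥ 0; total copy number is the
sum.  Within one sample, calls must be pairwise non-overlapping — this
is what every allele-specific caller emits, and it is validated rather
than repaired.  Calls with identical flanking values are *not* merged at
parse time (caller output is preserved verbatim); compaction happens
only in the breakpoint partition, where it is provably
frequency-preserving.

## Window partition

Each chromosome is tiled from position 0 with windows of length L
(either a fixed bp length, default 2 Mb, or a per-chromosome percentage,
rounded down to whole bp).  A window overlapping the centromere interval
is replaced by its intersection with the chromosome arms; any resulting
piece — including the chromosome-terminal remainder, which we treat by
the same rule for uniformity — with length strictly less than L/2 is
merged into its upstream contiguous window (downstream when it is the
first piece of an arm).  Merging never crosses the centromere.  An arm
shorter than L/2 still yields one window covering the arm, so the
partition's union is always exactly "chromosome minus centromere".  The
procedure is deterministic; ties cannot arise.

## Windowed matrices and rounding

For sample A and window W, every base of W carries either its called
total copy number or a fill value — A's ploidy for the analysis matrix
M, a fixed 2 for the ploidy-estimation matrix M_p — and the entry is the
length-weighted mean rounded to the nearest integer.  All rounding in
the package is **half away from zero**, chosen so gains and losses are
treated symmetrically about the baseline, and the mean is evaluated in
exact integer/rational arithmetic (window sums are integers; a
fractional tie-averaged ploidy is carried as an exact rational), so a
mean landing exactly on .5 rounds deterministically rather than at the
mercy of binary floating point.

The relative matrix is M′ = M − round(p_A), clamped to [−4, +6].  The
ploidy is integerized *before* subtraction: with a tie-averaged ploidy
such as 2.5, subtracting the rational and then rounding half-away would
map the rounded-ploidy state (3 copies) to +1 rather than 0, breaking
the invariant that a sample at its own baseline reads 0.  Rounding the
ploidy first keeps that invariant and matches the classification rule
below; for integer ploidies the two procedures coincide.  The clamp
bounds follow from the display range: a relative value of −3/−4 is only
reachable for samples of ploidy ≥ 3/≥ 4, and gains above +6 are
saturated (display pools ≥ +4 into one bin; storage keeps +4, +5, +6
distinct).

## Ploidy estimation

M_p is built at 10%-of-chromosome resolution with fill 2 — at this
window size the fill has little leverage on any single window, and
chromosomes entirely absent from a sample's calls still contribute
windows at the default.  The sample's ploidy is the modal window value
pooled genome-wide; if several values tie for maximal frequency the
ploidy is their arithmetic mean (possibly fractional).  Sex chromosomes
are included by default (configurable).  A user-supplied ploidy table
takes per-sample precedence over the estimate.

## Breakpoint partition (M_s) and classification

Per chromosome, the union of all samples' call boundaries induces a set
of elementary intervals; each call copies its allele counts onto every
interval it covers, and intervals covered by no call are dropped, so the
partition's union equals the union of the input calls and absent samples
remain absent (no fill at this resolution).  Adjacent intervals whose
sample→state maps are identical are coalesced; this changes no per-base
value and no downstream frequency, and makes the partition invariant to
arbitrary fragmentation of the input calls.

Each cell is classified against the sample's rounded ploidy rp:

| property      | rule                                |
|---------------|-------------------------------------|
| gain/neutral/loss | sign(total − rp)               |
| LOH           | n_minor = 0 and n_major ≥ 1         |
| cn-LOH        | n_minor = 0 and n_major = rp        |
| homozygous    | min(n_major, n_minor) = 0           |
| heterozygous  | both alleles > 0                    |

A homozygous total deletion (0, 0) is homozygous loss but **not** LOH:
no allele is retained, and the LOH tracks are about allelic imbalance of
retained material.  The LOH rule itself (minor allele entirely lost,
with or without net change) is the conventional reading; only the
copy-neutral special case has a canonical definition, so the general
rule is an explicit package convention.

## Frequency tracks

For every partition interval (or window, when full resolution is
disabled) and relative category in [−4, +6], the percentage of the
cohort carrying that category is 100·k/N with the explicit sample list
retained.  The denominator is always the full cohort size N: a sample
without a call at an interval counts in no category, rather than being
imputed as neutral.  The cn-LOH (and optionally LOH) lines report the
percentage of flagged samples per interval in negative ordinates; the
het/hom histogram stacks {het, hom} × {gain, neutral, loss} with gains
and neutral up and losses down.  The windowed variant derives categories
from M′, whose ploidy fill makes uncovered regions read neutral — the
two resolutions agree wherever events are unions of whole windows and
coverage is complete, which the tests assert.  Category 0 (neutral) is
computed and exported but omitted from the stacked plot.

## Clustering

Dendrograms and heatmap orderings use "ward.D" agglomeration: Ward's
coefficients in the Lance–Williams recurrence applied to **unsquared**
Euclidean distances,

    d(i∪j, k) = ((n_i+n_k)·d(i,k) + (n_j+n_k)·d(j,k) − n_k·d(i,j)) / (n_i+n_j+n_k),

with merge heights equal to the fusion distances.  This is implemented
in-package because the common library routine implements the squared
(ward.D2) variant; ward.D2 and other standard criteria (average,
complete, single) are also available, and both the metric and the
criterion are user-configurable.  Copy-number matrices are small
integers, so tied inter-cluster distances are common; ties are broken
deterministically toward the pair with the lexicographically smallest
(min cluster id, max cluster id), making results platform-independent.
Samples are always clustered; windows are clustered for the heatmap
unless the genomic column order is requested.  Clustering runs on M by
default or on M′ on request; the two coincide whenever all samples share
one ploidy.  The test suite cross-checks the implementation against a
naive O(n³) agglomeration oracle and against R's hclust(ward.D).

## Region comparison and Fisher test

A sample's category over a region is the length-weighted modal *binned*
category of its classified cells intersected with the region (ties go to
the higher bin; a "max over the region" aggregator is available).  The
default bins are +1, +2, +3, ≥+4; samples whose modal bin is neutral or
loss fall into a "no gain" row only on request.  The two-sided p-value
for the resulting r×2 table is exact: the sum of conditional
(multivariate hypergeometric) probabilities of all same-margin tables no
more probable than the observed one, accumulated in exact integer
arithmetic — the probability-ordering convention, stated explicitly
because two-sided conventions differ.  Tables with total beyond 200 fall
back to seeded Monte-Carlo sampling from the null, with the replicate
count logged; degenerate margins return p = 1 with a warning.

## Synthetic cohorts: what they emulate, and what they do not

The generator emulates *caller output*, not raw signal: per-sample
baselines at the planted ploidy (allele split ceil/floor of p/2),
planted events overwriting the baseline on an exact number of carriers
(gains add to the major allele; losses remove minor-allele copies
first; cn-LOH sets (round(p), 0)), one contiguous coverage gap per
chromosome, and value-preserving fragmentation.  Carrier counts are
exact — round(fraction·n) samples drawn by seeded shuffle, with
overlapping events given disjoint carrier sets — and gaps are placed
inside event-free regions so planted frequencies stay exact under
partial coverage.  Everything is deterministic given the seed.

Consequently the generator does **not** model caller noise, breakpoint
uncertainty, subclonality/intra-tumour heterogeneity, or contamination.
Passing tests therefore demonstrate that the *bookkeeping* — partition,
windowing, classification, counting, clustering, testing — is exact on
clean calls; they say nothing about robustness to upstream caller error,
which is out of scope (calls are taken as given).

The bundled 96-sample preset mirrors a hepatocellular-carcinoma-like
pattern: 70 diploid / 26 tetraploid samples; both 1q and 8q gained in
48/96 samples but with ≥+4 carriers at exactly 7/96 versus 24/96; an 8p
loss in 38/96; a 17p cn-LOH region in 29/96; a 5% coverage gap rate and
mild fragmentation.

## Problem sizes and numerical choices

Randomized oracle checks run on cohorts of ≤ 5 samples over two
chromosomes of ≤ 1 Mb with ≤ 50 calls (per-base arrays stay cheap at
full exactness), ploidy recovery on 3 × 10 Mb builds across ploidies
{1, 2, 3, 4, 6} with 30% gaps, clustering oracles on matrices of ≤ 8
samples, and Fisher enumeration on tables with total ≤ 40; the
end-to-end checks use the full 96-sample preset on hg19.  Tie tolerance
in agglomeration is 1e-12 relative; height comparisons in tests use
1e-9.  Exact quantities (percentages, Fisher p on enumerable tables,
matrix entries) are compared with no tolerance at all.

## Known limitations

* Integer clonal copy numbers only; subclonal states are out of scope.
* No two-group comparison beyond the two-region Fisher test; generate
  per-group histograms and compare them.
* GISTIC recurrence statistics are not re-implemented; the segmentation
  input file is exported for the external tool (seg.mean =
  log2(total/2), zero totals floored at 0.1; marker counts are a
  length/10 kb surrogate with a floor of 5, since the format requires a
  column the segment data do not carry).
* hg18/hg19 descriptors are bundled; other assemblies need a custom
  sizes + centromeres pair (no liftover).
* Rendering is presentation-only; every figure's content is exactly
  reproducible from its text export, and nothing downstream depends on
  pixels.
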