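# Methods

## MeDIP window model

MeDIP-seq enriches methylated DNA fragments, so regional methylation is read
out as fragment depth. Each mapped read stands for one fragment; reads are
extended to `fragment_length` (default 400 bp, the assumed sonicated fragment
size) from their 5′ end — rightward for `+`/strandless reads, leftward for
`-` — and clipped to chromosome bounds. The genome is tiled into
non-overlapping `window` = 200 bp windows and a fragment increments every
window it overlaps by at least 1 bp.

Coverage filtering is deliberately literal: a window is kept when every
sample has **at least** `min_per_sample` = 1 read (≥) and the mean count over
all samples is **strictly greater** than `min_mean_depth` = 10. The mean is
taken over all samples, not per group.

### The conditional exact negative-binomial test

Counts are first scaled to a common library size (geometric mean of the
per-sample totals) and rounded to integers. Window counts are modelled as
NB(μ, φ) with Var = μ + φμ² and a single common dispersion φ shared by all
windows, estimated by method of moments: per window, m = mean normalized
count and v = pooled within-group variance; φ̂ = median over windows of
max(0, (v − m)/m²), floored at zero. A common dispersion (rather than
tagwise shrinkage) keeps the test fully specified and oracle-checkable;
TMM-style compositional normalization is intentionally not implemented.

For one window with group sums Y_A (n_A samples) and Y_B (n_B samples), the
test conditions on N = Y_A + Y_B. Group sums are NB with sizes r_g = n_g/φ
and means n_g·μ̂ where μ̂ = N/(n_A+n_B); the conditional probability of a
split (a, N−a) is P(a) ∝ f_A(a)·f_B(N−a), normalized over a ∈ [0, N]. The
two-sided p-value sums P(a) over all splits with P(a) ≤ P(observed), with a
relative tie tolerance of 1e-7 (the convention of standard exact-test
implementations). At φ = 0 the conditional law is Binomial(N, n_A/(n_A+n_B))
and the test is the exact binomial test; the suite verifies bit-level
agreement for all N ≤ 50. The pmf is evaluated through the NB recurrence
f(j)/f(j−1) = (j−1+r)(1−p)/j so only cheap cumulative sums are needed;
agreement with direct log-pmf enumeration is < 1e-13. The log2 fold change
is computed on normalized group means with a 0.5 pseudocount; an all-zero
window returns p = 1.

### Merging and permutation FDR

Significant windows (p strictly below `alpha` = 5×10⁻⁴) overlapping zero
reference CpGs are discarded (a CpG belongs to a window when its C position
lies in [start, end)). Remaining windows are merged when *bookended*
(next.start == prev.end) with the same fold-change sign; since windows tile
the genome, any gap implies an intervening non-significant window. A DMR's
p-value summary is the minimum member p (conservative for ranking and
identically computable under permutation); its direction is hyper iff
log2FC > 0 in the case group.

FDR: each permutation draws a balanced relabeling of samples (uniformly,
with replacement, from all splits of the observed group sizes, excluding the
observed split; complementary splits are identified when group sizes are
equal — for a 4v4 design there are 35 distinct splits, 34 usable), re-runs
the segment test and merge with the dispersion estimated under the observed
labelling, and records null DMR p-values. For an observed DMR with
min_p = p: FDR = (mean number of null DMRs with min_p ≤ p per permutation) /
(number of observed DMRs with min_p ≤ p), clamped to [0, 1] and made
monotone non-decreasing in p. The dispersion is not re-estimated per
permutation because mixing the groups would fold planted signal into the
null dispersion and deflate it.

## WGBS pairwise model

With one individual per condition there is no replication, so each CpG is
tested marginally: Fisher's exact test on
[[meth_A, unmeth_A], [meth_B, unmeth_B]], after removing CpGs covered by
fewer than 5 reads in either sample (CpGs absent from one table count as
coverage 0). `fisher_exact_2x2` enumerates the conditional hypergeometric
distribution in exact integer arithmetic, so ties in the "probability ≤
observed" rule are resolved exactly rather than through a floating-point
tolerance; the reported odds ratio is the sample estimate ad/bc (+inf when
bc = 0). A CpG is differential when p < 0.05 **and** |level_A − level_B| >
0.20, both strict, computed on the same counts as the test. No
multiple-testing correction is applied at the CpG level; the delta filter
does most of the error control. Differential CpGs with the same sign and
consecutive distances strictly below 1000 bp are chained; chains with at
least 5 CpGs are reported as DMRs spanning the first to last CpG (end =
last C position + 2).

## Annotation, enrichment, profiles

- Location labels use the precedence promoter > exonic > intronic >
  intergenic with ≥ 1-bp overlap, so the fractions always partition the DMR
  set. The promoter is the 2-kb region immediately upstream of the TSS,
  strand-aware. A DMR in one gene's intron and another gene's promoter is
  "promoter".
- Track overlap fractions are reported against two denominators (all DMRs,
  and repeat-overlapping DMRs) in the CLI summary, since either convention
  is common for repeat-composition figures.
- A DMR is assigned to every gene whose body or promoter it overlaps; a gene
  touched by both hyper and hypo DMRs carries both labels.
- Enrichment uses the upper-tail hypergeometric probability P(X ≥ k) with
  the universe taken from the gene annotation (all annotated genes), not the
  union of GMT genes — the query arises from genome-wide DMR assignment and
  a GMT-only universe would inflate enrichment. Raw p-values are reported
  per set (ties ordered by set name); Benjamini–Hochberg values are optional.
- The metagene profile splits each gene body into 40 equal windows
  (remainder to the last) and each 2-kb flank into 20; a window's value is
  (overlapping fragment count) / (window length × library size), averaged
  over genes with minus-strand genes reversed so the axis runs 5′→3′. The
  2-kb flank matches the promoter scale. Note that the count-based density
  slightly over-weights short windows (a fragment overlapping a window need
  not lie inside it); profiles are comparable across samples of different
  depth but windows of very different lengths are not strictly comparable
  to each other.
- CpG coverage is the fraction of reference CpG sites overlapped by ≥ 1
  extended fragment; the saturation curve subsamples fragments without
  replacement at fractions 0.1…1.0 and reports the Pearson correlation of
  the window-count vector against the full data (exactly 1 at fraction 1).

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults encode the study conditions: 4 vs 4 samples,
mean_depth = 15 reads per 200-bp window, NB dispersion φ = 0.1, 50 planted
600-bp regions at fold change 3, WGBS coverage 20 with planted Δ = 0.4, CpG
rate 0.02/bp, on 2 × 500-kb chromosomes (tests use 2 × 120–400 kb to keep
runtimes short; the geometry is otherwise identical).

The genome is uniform random sequence scrubbed of accidental CG pairs, with
CG dinucleotides injected independently per position — so CpG counts are
Binomial and there are no CpG islands. MeDIP background reads are 49-bp
forward-strand anchors placed uniformly within each window, with per-window
per-sample counts drawn NB via the gamma–Poisson mixture; because every
anchor's 400-bp extension spans ~3 windows, the *extended* background is
uniform with dispersion ≈ φ/3 (the caller estimates the dispersion from the
data, so the test remains self-consistent). Differential signal is planted
as extra reads confined so their extension lies inside the planted region
(hence regions must be ≥ 400 bp): hyper regions add reads to group C, hypo
regions add the same excess to group Y. This choice is what makes
window-level truth sharp — uniformly smeared planted reads would give the
boundary windows on either side of a region identical count distributions,
making recall and precision jointly unachievable regardless of the caller.
The cost is realism: real MeDIP boundaries are soft, so real-data precision
at region edges will be worse than the synthetic benchmark suggests.

WGBS baselines are Beta(7, 3) per CpG (mean 0.7, a diffuse high-methylation
baseline; no bimodality, no island hypomethylation). Planted differences
shift the *lower* sample of the pair down by Δ — the control inside hyper
regions, the case inside hypo regions — because shifting up from a 0.7
baseline would clip at 1 and attenuate the planted effect. Coverage is
Poisson per CpG per sample with no positional autocorrelation.

Gene models are non-overlapping with simple equally spaced exon blocks;
repeats and regulatory tracks are uniform random intervals with no
clustering or directional bias. The spiked gene set draws half its members
from genes hosting planted DMRs, giving the enrichment stage a true signal.

Consequently, passing tests demonstrate the *algorithmic* correctness and
calibration of the callers under their stated model — not robustness to CpG
islands, copy-number artefacts, mappability gaps, batch effects, or the
soft boundaries of real immunoprecipitation data.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based half-open everywhere; 1-based CpG tables are
  converted on read (`one_based=True`). Chromosome naming can be normalized
  to `chr`-prefixed or plain styles on read.
- Strictness follows the written rules: ≥ 1 read/sample, mean > 10,
  coverage ≥ 5 kept (< 5 removed), |Δ| > 0.20, gap < 1000, ≥ 5 CpGs,
  p < α everywhere.
- Tie handling: the NB conditional test uses a 1e-7 relative tolerance when
  comparing split probabilities; the Fisher test compares exact integers.
- Degenerate inputs: all-zero windows give p = 1; a significant window with
  exactly zero log2 fold change cannot be oriented and raises; permutation
  FDR requires at least one balanced relabeling besides the observed one;
  empty gene lists, universes, or CpG maps raise rather than returning
  silent zeros.
- Seeds: every stochastic component (simulation substreams, permutation,
  saturation subsampling) takes an explicit seed and is reproducible to the
  byte.

## Problem sizes used by the test suite and acceptance script

Recovery benchmarks run on 2 × 400-kb genomes (≈ 4000 windows, 50 planted
regions) for MeDIP with 200 permutations, and 2 × 150-kb genomes (≈ 6000
CpGs, 30 planted regions) for WGBS; exactness checks enumerate all 2×2
tables and hypergeometric tuples with margins ≤ 25. These sizes exercise
every code path at full statistical fidelity while keeping a complete run
under a minute.
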