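# Methods

## Model

`tftarget` integrates two noisy measurements of transcription-factor
activity. Binding evidence: ChIP peaks near a transcript's TSS, weighted by
an exponential distance decay and summed into a *regulatory potential*.
Expression evidence: a signed statistic (t-statistic or log fold-change)
from a perturbation experiment, whose sign encodes up- vs down-regulation.
Transcripts carrying both kinds of evidence are candidate direct targets;
the aggregate direction of the association determines whether the factor is
called an inducer or a repressor of its targets.

### Coordinates and windows

Internally all intervals are 1-based inclusive; BED input/output converts
at the boundary. This makes a window of half-width D printed as
(start, end) satisfy end − start + 1 = 2·D exactly. The TSS is the region
start on the `+` (and `.`) strand and the region end on `-`; `.` is treated
as `+` so strandless inputs behave deterministically. Windows are
[tss−D, tss+D−1] on `+`/`.` and [tss−D+1, tss+D] on `-` — both exactly 2·D
wide with the TSS inside — and are clipped at coordinate 1 on the left
(logged), never dropped, so there is always one window per input region.
Chromosome names match as exact strings: no `chr` aliasing, because
aliasing silently hides genome-build mismatches, which are the single
largest driver of rank discordance between runs.

### Distance decay

A peak overlapping a window by ≥1 bp is assigned to it; a peak can be
assigned to every window it overlaps. The peak's position is its midpoint
⌊(start+end)/2⌋ (well-defined even for peak calls without summits), its
signed distance is midpoint − TSS (negated on `-` so positive means
downstream), and its score is

    score = exp(−(0.5 + 4·|d|/D)),

which is e^−0.5 at the TSS and e^−4.5 at the window edge. The decay is
normalised by the *chosen* D rather than a fixed 100 kb, so re-running the
analysis at D = 50 kb re-calibrates the edge score to the same e^−4.5; the
relative weighting of near- vs far-TSS peaks is then comparable across
distance choices. Midpoints of edge-straddling peaks can lie slightly
beyond D; their scores are simply smaller than e^−4.5, not capped. The
regulatory potential of a region is the sum of its assigned peak scores;
regions with no assigned peak have potential 0 and stay in the output.

### Rank products

Potentials and expression statistics are joined on the transcript id
(unmatched rows on either side are dropped with a logged count). Three
rankings are computed: potential descending (`rank_potential`), statistic
descending (`rank_up`), statistic ascending (`rank_down`). Ties receive
distinct ranks, broken by first occurrence after a pre-sort of the joined
table by transcript id — this makes every output invariant to input row
order. The normalized rank product per direction is

    rp_dir = rank_potential · rank_dir / n²,

the product of the two fractional ranks, bounded in [1/n², 1], smaller =
stronger evidence. The n² normalization is the only reading consistent with
published rank magnitudes of order 1e−7 on transcriptome-sized inputs,
where a single division by n could not drop below 1/n. Ranking operates at
the transcript level; collapsing to genes is deferred to the concordance
comparison (`by="symbol"`), which keeps the best-ranked transcript per
symbol.

### Grouping and statistical testing

Transcripts are grouped on the signed statistic of the *joined* set (groups
are only used downstream on joined targets): the down group is the lowest
⌈lower_q·n⌉ values, the up group the highest ⌈(1−upper_q)·n⌉ (nearest-rank
quantiles, thresholds inclusive, so ties can enlarge a tail; q·n is rounded
to the nearest integer first when within 1e−9 to absorb float round-off).
Defaults are the 10th/90th percentiles. If every statistic is identical the
grouping is degenerate: everything is labelled none, with a warning.

Each regulated group is compared to the none group with a two-sample,
two-sided Kolmogorov–Smirnov test on `rank_potential` (KS is invariant
under strictly monotone transforms, so this equals testing raw potentials;
the ranks match how the ECDFs are plotted). The statistic is the exact
sup-difference of the two step ECDFs; the p-value is asymptotic, hence
deterministic at any sample size. Sidedness is deliberately standard
(two-sided): the *direction* of the shift is recovered separately by
comparing the group's mean potential rank with the none group's mean, which
keeps the test conventional and the directional call explicit. A group is
"shifted" when its mean rank is smaller (better) than none's and its KS
p-value is below alpha (default 0.05, a flag). Up shifted → inducing; down
shifted → repressive; both → both; neither → none. Raw p-values are
reported with no multiple-testing correction across the two directions or
the cutoff sweep, which reports one row per quantile pair of the default
grid (0.1, 0.9), (0.2, 0.8), (0.3, 0.7), (0.4, 0.6).

ECDF curves exported for plotting reach exactly 1 at each group's maximum
(the conventional ECDF definition). KS needs ≥2 observations per sample;
smaller groups raise an error rather than returning a meaningless test.

### Concordance

Concordance at N is |top_N(A) ∩ top_N(B)| / N between two ranked id lists;
the curve over N = 1..N_max (default 10,000, clipped to the shorter list
with a warning) is computed incrementally with two seen-sets in O(N_max).
Before taking top-N each list is ordered by its rank product with a stable
transcript-id tie-break, so curves are deterministic. Lists from different
gene annotations are matched by shared id string only.

## Synthetic data

The simulator emulates the structure of a ChIP + perturbation-expression
study: `n_transcripts` (default 2,000) transcripts of 1–50 kb placed
uniformly with random strand on `n_chromosomes` = 5 chromosomes of 100 Mb;
`n_target` = 200 planted direct targets receiving Poisson(3) peaks each,
with midpoint offsets from the TSS drawn from an exponential of scale D/4
truncated at D (TSS-proximal enrichment; no empirical offset distribution
is imposed) and random sign; 2,000 background peaks uniform genome-wide;
peak widths uniform 200–600 bp. Expression statistics are standard normal,
with planted targets' means shifted by ±`effect_size` (default 2 SD) for an
inducing/repressive factor and unshifted under the null. One
`numpy.random.default_rng(seed)` stream drives everything, so identical
configs give byte-identical files. The defaults were chosen as a realistic
desk-scale study: a few thousand peaks, ~10% planted targets, and a 2-SD
expression shift comparable to a clearly perturbed regulon.

What the simulation does *not* emulate: read-level noise, peak-caller
artefacts, correlated expression noise between co-regulated genes, gene
clustering along chromosomes (beyond random collisions), multiple
transcripts per gene, and real annotation sizes. Passing recovery tests
therefore shows the method's internal consistency and sensitivity at these
noise levels, not performance on any particular real dataset.

## Numerical and design choices

- Distance anchor = peak midpoint (not nearest edge): well-defined for
  summit-less peaks and matches common practice for decayed-distance
  scores. The overlap test still uses the whole peak interval, so an
  edge-straddling peak is assigned even when its midpoint is outside.
- Association output is sorted by (region_id, |distance|) with
  (distance, peak_id) tie-breaks, making the table deterministic regardless
  of interval-tree iteration order.
- The interval overlap engine is `intervaltree`; tests verify it against a
  brute-force all-pairs loop exactly. The KS test is
  `scipy.stats.ks_2samp(method="asymp")`; tests verify the statistic
  against a brute-force sup over pooled points to 1e−12.
- Decay constants (0.5, 4): fixed calibration points of the score scale —
  e^−0.5 at the TSS, e^−4.5 at the edge for any D.
- Degenerate inputs: <2 joined records, an empty join, all-identical
  statistics, quantile pairs with lower ≥ upper, negative distances, and
  orphan region ids in an association table are all explicit errors or
  warnings rather than silent results.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 2,000-transcript simulation across 100 seeds per experimental arm
(inducing, null; 30 for the mirrored repressive arm), 20 random fixtures
for the overlap oracle, and 10,000-point concordance curves; one pipeline
run takes well under a second, the whole suite well under a minute. These
sizes give Monte-Carlo rates stable to a few percent while keeping the
package quick to check; they are package choices, and all rates are
recomputed, never stored.

## Known limitations

- Group-vs-group KS (up vs down directly) is not implemented; both groups
  are compared to none.
- No permutation p-values on rank products, no multiple-factor comparison
  mode, no per-peak confidence weighting, no GTF/bigBed input, and no
  liftover between genome builds (runs on different builds are compared by
  shared id only).
- The asymptotic KS p-value is anti-conservative for very small groups;
  groups below 2 members are rejected outright, but groups of a handful of
  members deserve caution.
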