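# Methods

## The measurement model

Marker-frequency analysis reads replication activity off sequencing
depth: in an exponentially growing, unsynchronized population, a locus
at fork-travel distance *d* from an origin firing at relative rate *w*
is over-represented relative to the terminus. We model the relative
expected copy number at position *x* on a circular chromosome of length
*L* as an exponential-of-linear mixture over origins,

    c(x) = Σᵢ wᵢ · 2^{Aᵢ · (1 − dᵢ(x)/Dᵢ)},

where dᵢ(x) is the circular fork-travel distance from origin *i*
(bidirectional forks, stopping at the origin's antipode, or at the
terminus-region edges when the Tus/Ter fork trap is modeled), Dᵢ is the
maximal travel distance, and Aᵢ is the peak-to-terminus gradient height
in log₂ units. A is a growth-rate proxy: A = 1.32 reproduces a ~2.5-fold
ori:ter ratio of a fast-growing wild type (the value follows from the
closed form, since *dif* sits almost diametrically opposite *oriC*);
A = 0 is a stationary-phase profile. The fork trap is a single additive
log₂ plateau over the terminus region rather than fork-queue dynamics —
one parameter that reproduces the characteristic terminus peak of cSDR
strains. This model is phenomenological, not a cell-cycle simulator;
every downstream statistic depends only on the gradient shape, which is
what it captures.

Observed bin counts are negative binomial around
`depth_per_bin · c(midpoint)/mean(c)` with size (dispersion) parameter
*r*; the default r = 50 gives the over-dispersion typical of sequencing
counts (CV ≈ 15% at 200× per bin, never below √(1/r) however deep).
Defaults — 200-nt bins, 200 expected counts per bin — match deep
(~200×) short-read sequencing of a 4.6-Mb chromosome.

## Profile construction

- **Binning**: depth summed in non-overlapping windows (`ceil(L/bin)`
  bins; a short final bin is kept but excluded from mode estimation
  because its count is not comparable).
- **Mode normalization**: the baseline is the histogram mode of the
  positive bin counts, with cell width median/50 and ties broken toward
  the smaller count; the estimate is the mean of the counts in the
  modal cell. The width is proportional to the median rather than an
  integer so that rescaling all counts rescales the mode identically
  (normalization invariance); at ~200× depth this coincides with an
  integer-width histogram. The mode, not the median, is the right
  baseline under a gradient: most of the chromosome sits near the
  terminus plateau while the gradient drags the median upward.
- **Masking**: zero-count bins are masked (log₂ undefined); bins beyond
  4 median-absolute-deviations of the normalized values are also
  masked — a deterministic stand-in for removing visually obvious
  outliers before curve fitting. The order is fixed: mask, then the
  mode is estimated from what remains.
- **Recentering**: positions map to signed offsets from *oriC* in
  (−L/2, +L/2], positive clockwise; the mapping is exactly invertible.
- **LOESS**: degree-1 local regression with tricube weights
  (statsmodels `lowess`), span 0.1 of bins by default — at 200-nt bins
  on a 4.6-Mb genome this is a ~460-kb window, smooth enough that the
  ±100-kb peak rule (below) is meaningful. Known deletions are dropped
  before fitting; bins inside an inversion interval have their
  positions reflected about the interval midpoint, which restores the
  sample's own gradient. Because the axis is circular, each end of the
  recentered axis is padded with the wrapped 2% of bins from the
  opposite end before fitting and the padding discarded afterwards;
  this removes the artificial edge slopes a linear fit would otherwise
  produce at ±L/2.

## Peak calling and origin localization

A grid point is an oriK peak if it is a circular local maximum of the
fitted curve and the fitted values, sampled outward at 10-kb steps to
±100 kb, never increase by more than ε = 1e-4 log₂. The strict
"non-increasing outward" reading (rather than a negative net slope)
avoids calling shoulders on another peak's flank. Two additions to the
bare rule:

- a **prominence floor** (default 0.1 log₂ above the profile minimum):
  the literal rule calls 1.02–1.04-fold wiggles on flat stationary-phase
  profiles, which no analyst would report; the floor makes "flat in,
  nothing out" a property of the caller rather than of the analyst.
- peaks closer than the 100-kb window are merged keeping the higher.

Peak positions are grid points of the fitted maximum (bin resolution).
For *parameter* estimates of origin positions this is not enough: when
two origins share initiation the mixture gives shallow, asymmetric
peaks, and the maximum of any smoothed curve is displaced toward the
shallow flank by a distance comparable to the smoothing window — on
noiseless data the displacement reaches ~100 kb at span 0.1. The
`locate_origins` estimator therefore fits the gradient-mixture model
itself (positions, amplitudes, mixture weights, offset) to the binned
log₂ values by bounded least squares, multi-started from the called
peaks plus coarse alternatives. On equal-weight two-origin genomes at
200× depth this recovers both origins with ~10 kb median error.

Ratios are linear folds obtained by exponentiating log₂ differences:
ori:ter = 2^(max fit outside ter − fit at *dif*), max/min likewise
(terminus excluded from the maximum by default). Values below 1 are
meaningful — in a cSDR parent the terminus trap is the strongest
feature, so the *dif* fit exceeds every non-ter value. The terminus
region defaults to *dif* ± 400 kb, wide enough to cover the innermost
Ter sites while leaving the 4.3–4.6 Mb region untouched; it is a
configurable landmark, since the exclusion bounds are a judgment call.

Cross-strain peak ranges are single-linkage clusters of per-strain peak
positions at 150-kb circular radius, reported min-to-max.

## Structural variants from copy number

Deletions and amplifications are segments whose normalized log₂ level
steps away from the local baseline: a flanking-window mean-shift scan
(window = the 20-kb minimum length) marks boundaries with ≥ 0.8 log₂
shift, and consecutive opposite-signed boundaries enclosing a segment
whose mean differs from its flanks by the threshold are emitted.
Zero-coverage bins are floored at log₂(0.5/mode) so complete deletions
appear as (very deep) steps rather than holes.

Inversions are local flips of the gradient. Candidate breakpoints come
from a low-threshold (0.15 log₂, 50-kb window) step scan — an inversion
in a gradient necessarily produces matching opposite steps at its two
breakpoints — or from a user whitelist (e.g. rRNA operon spans).
Candidate pairs are scored by trial reversal. The emission statistic is
the **discontinuity reduction**: the drop in summed boundary step
magnitudes when the segment is reversed. For a genuine inversion the
two steps close up (reduction ≈ twice the gradient difference across
the segment, ~0.6–0.9 log₂ for the rRNA-bounded inversion geometry);
for a spurious pair reversal *creates* steps and the statistic goes
negative. The threshold, 0.35 log₂, was calibrated on seeded scenarios:
planted flips score 0.57–0.88, no-variant genomes never exceeded 0.21
(and typically score ≤ 0), giving full recovery with zero false calls.
A relative roughness gain (reduction in the mean squared second
difference of a local re-fit after reversal) is computed for every call
as a secondary score; it is not the emission criterion because its
null and alternative distributions overlap — baseline roughness is
noise-dominated, so the relative gain is unstable in both directions.
Breakpoints are refined by bin-resolution hill climbing of the
discontinuity statistic. Detection requires a clear gradient (fitted
range ≥ 0.3 log₂); a flat cSDR-parent-like profile is skipped with a
warning, mirroring the fact that flips are invisible without a
gradient. Segments spanning the coordinate origin are not searched.

## R-loop-forming sequences

The m1/m2 patterns: an R-loop initiation zone (RIZ) of at least three
G-tracts (≥ 3 consecutive Gs for m1, ≥ 4 for m2) separated by 1–10-nt
linkers with overall RIZ G-density ≥ 50%; then within ≤ 50 nt a
R-loop elongation zone (REZ) — the longest downstream window of ≥ 100
nt with G-density ≥ 40%, searched up to 2,000 nt. Tracts are maximal
G-runs; shorter G-runs inside linkers count as linker content. All
constants live in one `QmRLFSParams` block. Both strands are scanned
(reverse complement for −) and overlapping same-model sites are merged
to the maximal-scoring one per overlap component (score = RIZ
G-density; ties to the longer span, then leftmost). m1 and m2 site
spans overlapping or within 1 kb merge into loci flagged by model. The
implementation is checked against a brute-force sliding-window matcher
that applies the definition to every candidate substring.

The proximity test asks whether observed copy-number peaks lie within a
radius (default 200 kb) of predicted loci more often than uniform
random positions on the circle. Distance is circular, point to nearest
locus edge (0 inside) — the permissive anchor, chosen because "within
R of a site" does not specify one. The null redraws the *peaks* (the
loci are the fixed prediction); the statistic is the within-radius
count; significance is the one-tailed upper Gaussian tail of the
z-score, with the empirical rank p reported alongside. The Gaussian
form is what a z-score permutation test means, and it is the only way
p-values smaller than 1/n are obtainable at n = 1000. Degenerate nulls
(loci covering nothing or everything) are flagged and given exact
bounds instead of a z-score.

## Collision scoring and expression

With one predominant origin, the fork direction at a gene is clockwise
iff the gene's midpoint lies on the clockwise arc from the origin to
its antipode; a gene transcribed against the local fork direction is on
the lagging strand (head-on). P(HO) is the coverage-weighted head-on
fraction over genes whose midpoints fall in the region (midpoint
membership is deterministic and orientation-free). Genes with midpoints
exactly at the origin or antipode are excluded with a warning. Gene
class filters: all, rRNA (optionally 5S-only, matching rRNA-depleted
library preparations where only 5S survives), mRNA, essential-mRNA.
Per-gene coverage is used as given, with an optional per-kb
normalization flag; strand and class come from PTT/RNT-style tables.
The default region is 3.3–4.25 Mb with 3.3–4.6 Mb available by flag.

Per-gene log₂ fold changes are library-size normalized (both libraries
scaled to the mean of the two totals) with pseudocount 0.5. This is a
positional descriptor, not a differential-expression test — no
dispersion estimation or FDR machinery is involved, deliberately.
Positional correlation smooths both fold-change vectors by LOESS
against the oriC-recentered gene midpoint (span 0.3 of genes, chosen so
the smoother averages hundreds of genes and isolates the chromosomal
trend) and reports Pearson correlations of the raw and smoothed
vectors.

## The synthetic strains

`scenario_presets()` fixes four strain classes used across the analysis
and tests: *wild-type-like* (single origin at oriC, A = 1.32, ori:ter
≈ 2.5), *csdr-parent-like* (weak initiation split over the 4.51-Mb site
and two minor sites, amplitudes 0.2–0.35, plus a strong 0.7-log₂
terminus trap), *suppressor-like* (one dominant origin at 4,510,000
carrying the 3.42–4.20-Mb inversion, A = 1.2), and *stationary-like*
(A = 0). Expression presets place rRNA operons at their K-12 anchor
coordinates with their real transcription directions, 300 mRNA genes
with a 70% leading-strand bias, and rRNA levels 20× mRNA (a
post-depletion ratio); the suppressor's gene table has the inversion
applied (positions reflected, strands flipped).

What the generator does **not** emulate: GC- or sequence-dependent
coverage bias, mappability artifacts, read-level errors, fork-queue
dynamics at Ter, replication-transcription interference on coverage,
and expression regulation beyond gene dosage. Passing tests therefore
demonstrate that the estimators recover the statistical structure they
target (gradients, flips, steps, motif placement, strand asymmetry)
under realistic count noise — not that they are robust to every
artifact of real libraries, which is what the masking knobs and the
configurable landmarks are for.

## Numerical choices and edge cases

- All internal coordinates are 1-based inclusive on a circular
  chromosome; bedGraph/BED convert at the boundary. Multi-record FASTA
  is rejected (single-chromosome model).
- Curve evaluation off-grid is periodic linear interpolation.
- LOESS uses 2 robustness iterations for profile fits (resistance to
  isolated outliers), 1 for local trial-reversal fits, and `delta`
  interpolation (~0.1% of L) for speed.
- Fewer than 10 unmasked bins, all-zero profiles, overlapping
  exclusion/inversion intervals, zero-variance correlation inputs and
  empty count tables raise errors rather than warn.
- Ties in the step scan are broken toward the smaller coordinate; peak
  merging keeps the higher fitted value; ratio computations interpolate
  the *dif* value if its bin is masked.
- Problem sizes in the test and acceptance suites: profile-level
  statistics run at 1-kb bins (4,642 bins per genome) and the
  origin-localization property at the full 200-nt resolution, the sizes
  at which each check is informative.

## Known limitations

- Inversion detection assumes exactly the copy-number signature of a
  single non-nested inversion with both breakpoints covered; nested or
  wrap-spanning events and events in flat profiles are out of reach by
  construction.
- P(HO) assumes one predominant origin; mixed initiation would need a
  fork-direction probability field instead of a bipartition.
- The QmRLFS constants are the package's defaults for the published
  m1/m2 pattern family; analyses that must match a specific QmRLFS
  release byte-for-byte should verify the constants in `QmRLFSParams`
  against that release.
- The permutation null treats peaks as uniform independent positions;
  it does not condition on inter-peak spacing.
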