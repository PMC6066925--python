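# Methods

This note documents the statistical procedures implemented in `loopmut`,
the assumptions behind them, the knobs that matter, and what the synthetic
data generator does and does not emulate.

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open internally (BED-native). Mutation
tables in the ICGC simple-somatic-mutation layout are 1-based inclusive and
are converted exactly once at the I/O layer. Book-ended intervals merge
(`[0,10) + [10,20) → [0,20)`), matching the default of the standard
command-line merge tools. Interval sets are held per chromosome as sorted
numpy arrays; every operation is checked in the test suite against a
per-base boolean-mask brute force on toy chromosomes, which is the
module's independent oracle.

Window grids place one window of width W (default 1 Mb) on each feature
midpoint, defined as `floor((start+end)/2)`. Windows that would extend past
a chromosome end are **dropped, not clipped**, so every bin offset averages
the same number of windows; the drop count is recorded. Blacklist filtering
removes a window entirely if it overlaps an excluded interval by ≥ 1 bp.
Per-bin removal would retain more data but make bin denominators uneven;
whole-window removal was chosen for that reason and because the
boundary-region loss is negligible at genome scale.

## Anchor sets

The union anchor set pools loop-assigned CTCF motif coordinates across cell
lines, merges overlapping motifs so each is counted once, and expands each
merged span to 5 kb around its midpoint. Merging happens *before* the 5-kb
expansion; when motifs from different cell lines nearly but not exactly
coincide, they are fused first and the anchor is centred on the fused span.
Provenance (which cell lines contributed) is kept per anchor. The output is
invariant to the ordering of the input cell lines.

Motif scanning is exact degenerate-consensus matching over both strands
(N in the consensus matches any of ACGT; N in the genome matches nothing).
For the 13-bp PRDM9 core `CCTCCCTNNCCAC` this leaves 11 informative
positions, so the background hit rate on random sequence is 2L/4¹¹ — a
stringent criterion comparable to a PWM scan with a very low p-value
threshold, without the PWM machinery. Overlapping hits are all reported.

The control CTCF set keeps constitutively bound motifs whose distance to
every anchor exceeds a 10-kb flank. The stringent non-CTCF anchor set
applies a sequential filter chain (motif removal → ChIP-bound removal →
optional mappability containment) with per-stage survivor counts; the first
two filters commute. "Uniquely mappable context" is implemented as full
containment of the 5-kb anchor within mappability intervals, configurable
because no fractional threshold is canonical.

## Meta-profiles and Poisson intervals

For a bin of width w, the per-bin aggregate X is the number of events
(SNV positions, or SV breakpoints with two per SV) falling in that bin
across all windows and samples. The rate is

    rate = X / (n_samples × n_windows × w/10⁶)   [events · sample⁻¹ · Mb⁻¹]

Windows of adjacent anchors may overlap (median anchor spacing is far below
the window width); an event is deliberately counted once per window that
contains it — the denominator counts window placements, i.e. the number of
times a genomic position was sampled. Samples are weighted equally.

Uncertainty on each bin is the exact two-sided 95% Poisson interval on X in
the gamma-quantile (Garwood) form — lower ½χ²(0.025, 2X) (0 when X = 0),
upper ½χ²(0.975, 2X+2) — numerically identical to R's `poisson.test`. The
normal approximation was rejected because the focal bins of fine profiles
can hold few events. For integer reporting of half-million-scale aggregates
the bounds are ceiled; `poisson_ci_aggregate(4, 5000, 2284, 11085)` returns
(506363, 504970, 507760). Coverage of the exact interval is verified by
simulation (94–97% at λ = 50).

Fine profiles (default 20-bp bins within ±1 kb) are centred on the anchor's
motif midpoint and, by default, minus-strand anchors are flipped so offsets
read in motif orientation. Whether real fine profiles should be
strand-oriented is genuinely open; `oriented=False` disables the flip, and
for strand-symmetric questions (a central peak) the choice is immaterial.

The focal test compares the mean rate over the central bins against flank
bins resampled with replacement; p = (1 + #{null ≥ observed})/(1 + n), never
exactly zero. Because a window centre can fall on a bin boundary, "the
central k bins" are the k bins whose centres are nearest offset 0, with a
boundary tie going to the bin containing the centre point.

## Circular permutation

The overlap statistic is the count of set-A features touching ≥ 1 bp of
set B. Each permutation draws **one uniform offset per chromosome** and
rotates every B interval on that chromosome rigidly, wrapping at the end;
wrapped intervals are split into two pieces that still count as one
feature. Offset 0 is allowed (probability 1/L). This preserves
inter-feature spacing, the sharpest part of the null. Blacklisted regions
are not excluded from the rotation space (simple circular model); a
masked-aware rotation would be a straightforward extension but is off by
default. Shift curves re-run the test after circularly shifting B by each
requested offset (one-directional shifts of the second set), with the same
seed so z-scores are comparable; offset 0 reproduces the base test and a
full-chromosome shift is the wrap identity.

Empirical p-values use the (1 + r)/(1 + n) pseudocount form. Calibration is
tested two ways: p is approximately Uniform(0,1) under independence (KS
test over 200 simulations), and z has mean ≈ 0, variance ≈ 1. Both
properties hold only where the overlap count takes many values; with very
sparse sets the statistic is coarsely discrete and p is conservative, which
the tests respect by using dense configurations.

## Composition tests

For labelled annotation sets, the marginal is the fraction of universe
members (anchors) overlapping that set. For a k-way intersection the
expected fraction under independence is the product of the marginals
(0.16 × 0.69 = 0.11 in the canonical two-way example). Significance is a
hypergeometric upper tail with N = |universe|, K = members of the first
k−1 labels jointly, n = members of the last label, and x the full
intersection; the parameterisation for k > 2 is not canonical, so it is
documented here and kept symmetric in the code path that matters (k = 2).

GWAS regions are built by extending each 1-bp SNP ±flank (default 5 kb,
the average LD-block span rationale), clipping to chromosome bounds and
merging. Recurrently disrupted loops tally SV breakpoints falling in either
anchor of a loop, with a distinct-sample counting mode. The
anchors-per-gene comparison reports overlap-pair rates for two gene sets
and a 2×2 chi-square p-value **without** continuity correction (so it
matches a closed-form oracle; R's `prop.test` default applies the
correction and differs slightly).

## Feature model

Rows are unique 5-kb windows obtained by merging the (overlapping) 1-Mb
anchor windows and tiling the merged regions — each genomic region counted
once. Interval tracks contribute bp-overlap columns; signal tracks
contribute bp-weighted window means (window-mean aggregation is a choice;
no predictor is standardised, since trees and rank correlations are
invariant to monotone transforms). The response is the event count per
window.

Variable importance is %IncMSE from a bagged ensemble of regression trees
(default 200 trees, `max_features = 1/3`, leaf size 5; the base learner is
pluggable). The bagging loop is in-package so out-of-bag indices are
explicit: importance = 100 × (OOB MSE with the predictor's column permuted
− baseline OOB MSE)/baseline, one seeded permutation per predictor,
deterministic under the seed. Permutation is the standard operationalisation
of "removing" a predictor from a tree ensemble. The unscaled form is used
(dividing by the ensemble SE instead would reproduce the other common
convention). A constant predictor scores exactly 0; correlated duplicates
share and therefore dilute importance, which the diagnostics test
demonstrates. Spearman panels use bootstrap percentile CIs over rows rather
than the Fisher transform because count responses are heavily tied.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
one seeded `numpy` Generator driving everything (byte-identical outputs
under a fixed seed):

- **Genome**: i.i.d. uniform ACGT per chromosome (default 2 × 10 Mb); the
  PRDM9 consensus is planted at a uniform position inside a fraction of
  anchors (default 0.13, the anchor fraction being emulated), N positions
  drawn randomly.
- **Anchors**: default 200 union anchors of 5 kb, motif width 19 bp, placed
  with ≥ 4 anchor-widths separation and a 600-kb margin so 1-Mb windows
  stay on-chromosome. A shared core (default 60%) appears in all of the
  default 7 cell lines; the rest are private to one line.
- **Hotspots**: a fraction ρ (default 0.16) of anchors receives an
  overlapping 2-kb hotspot; the remaining hotspots are placed uniformly
  clear of anchors. The default hotspot count (350) makes the chance
  overlap under rotation ≈ 0.12, the background being emulated.
- **SNVs**: an inhomogeneous point process, per sample per bp
  r(d) = r0(1 − δ·e^(−d/λ)) at distance d from the nearest anchor centre,
  times m inside the 19-bp motif. Defaults r0 = 4 /sample/Mb (the cohort
  average being emulated), δ = 0.5, λ = 100 kb, m = 3. Exponential kernels
  are the simplest smooth shapes matching the observed profiles; no
  functional form is canonical. δ = 0.5 is a choice — the emulated dip is
  described qualitatively ("dramatic"), and 0.5 gives a central rate of
  roughly half the background, consistent with the published profile
  figures. An optional sinusoidal nucleosome-periodicity ripple is off by
  default.
- **SVs**: breakpoints at b(d) = b0(1 + ε·e^(−d/λ)), b0 = 0.1 /sample/Mb
  (two breakpoints per SV and SVs roughly two orders rarer than SNVs),
  ε = 1.0 (the published breakpoint elevation has no printed fold; 1.0 — a
  doubling at the anchor — is of the visually right order and large enough
  to be recoverable at desk scale). Breakpoints are paired into SV records
  within each chromosome and assigned a sample per pair, so the realised
  breakpoint set follows b(d) exactly; at most one breakpoint per
  chromosome is lost to pairing.
- **Tracks**: DSB peaks (250 bp) whose centre-placement intensity is
  `fold` times higher inside anchors (default 3.7, the enrichment being
  emulated), placed fully inside anchors so bp-overlap ratios recover the
  fold up to the small peak-merging bias; and a replication-timing signal,
  smoothed Gaussian noise plus an anchor-proximal exponential elevation,
  on a 5-kb step.

Sampling uses thinning against the rate ceiling, so the realised processes
follow the target intensities exactly. What the generator does **not**
emulate: trinucleotide-context mutation spectra, chromatin-state
segmentation, realistic hotspot width/intensity distributions,
inter-chromosomal SVs, mappability structure, or the empirical spacing of
real anchors. Tests passing on synthetic data therefore demonstrate the
estimators' correctness and calibration, not biological conclusions about
real genomes.

## Parameter recovery and problem sizes

The end-to-end tests recover every planted parameter with the
corresponding pipeline stage, comparing against numeric-integration
oracles over the realised anchor geometry (because default anchor spacing
is below the window width, flanks never return fully to baseline; the
oracle integrates the kernel per bin rather than assuming they do). Tests
run at desk scale — 20–60 Mb genomes, 200–1,000 anchors, cohorts of
2,000–5,000 synthetic samples where focal 19-bp counts need precision —
sizes chosen so each Monte-Carlo tolerance is a small multiple of the
estimator's standard error. The bp-overlap DSB fold estimate carries a
small (~3–5%) downward bias from peak merging at high in-anchor density;
the acceptance script therefore recovers the planted fold from peak-centre
densities, which are unbiased.

## Known limitations

- The hypergeometric parameterisation for intersections of more than two
  sets is one of several defensible choices.
- The circular null ignores masked regions; on real genomes with large
  blacklisted fractions a masked-aware rotation would be preferable.
- `laps_per_gene_test` treats genes as trials in a 2×2 table even though a
  gene can intersect several anchors; rates above 1 make the chi-square an
  approximation to a rate-ratio test.
- The degenerate-consensus scanner does not score partial motif matches;
  PWM-level sensitivity is out of scope.
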