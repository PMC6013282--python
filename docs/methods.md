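# Methods

## The timer model

A coenocyte's nuclei divide synchronously, so the cell's DNA content is a
step function over powers of two. We model the division schedule of each
cell as a renewal process: interval k between divisions is an independent
draw from `Normal(μ, cv·μ)`, with `μ` the mean nuclear doubling time
(default 11 h) and `cv` the cell-to-cell coefficient of variation.
Intervals are i.i.d. both within and across cells — a division's duration
carries no memory of the previous cycle — and the model deliberately
contains no size or nutrient feedback: it is a pure timer. Non-positive
draws are redrawn; at `cv ≤ 0.15` a non-positive interval is a ≥ 6.7σ
event, so redrawing is unbiased in practice.

Every cell starts a fresh interval at t = 0. This models release from
starvation synchronization and is load-bearing: it makes the `cv = 0`
population exactly clonal in timing (the baseline-subtracted asynchrony is
identically zero, an exact invariant the tests assert), and it is what
makes asynchrony *growth* informative about `cv` at all. Initial DNA
contents follow a 1C/2C/4C mixture (0.25/0.50/0.25 by default);
populations apportion it deterministically by largest-remainder rounding
so that multinomial sampling noise does not contaminate the replicate
envelopes (a multinomial mode exists behind a flag).

## Asynchrony and the CV bound

Population asynchrony at a time point is the geometric standard deviation
of DNA content, `log2(GSD) = sqrt(Σ f_i (log2 x_i − log2 geommean)²)` —
the population SD of log2 ploidy. A "literal" unrooted mode (the variance
form) is kept for replicating analyses that used the metric in that form;
no result in this package depends on the choice. Asynchrony series are
baseline-subtracted at t = 0 per replicate before averaging, so an
envelope's mean is exactly zero at t = 0.

`Δlog2(GSD)` does not grow smoothly: it pulses near multiples of `μ`,
where cells straddle a division, and relaxes in between; the pulse width
grows with `cv` and with the number of completed cycles. Because of this
structure, comparing an observed series to envelopes point-by-point with a
two-sided band is fragile — a single observed series drawn from the *same*
process as the replicates falls outside its own ±1 SD band at some
informative time point most of the time. The CV bound is therefore
one-sided: the reported bound is the smallest grid `cv` whose envelope
upper edge `mean + n_sd·SD` is never exceeded by the observed `Δlog2(GSD)`
at any shared time point. One-sidedness is the correct reading of an
*upper* bound — an observed series below a band still means the population
is at least that synchronous. The default `n_sd = 3` is a Bonferroni-style
choice: with ~17 time points, a per-point z of ≈ 3 holds the family-wise
probability of wrongly excluding the true CV near 1%. Self-consistency at
the study's scale (5,000 cells, 100 replicates, observed series from a 5%
CV population, grid {0.025, 0.05, 0.10, 0.15}): 38/40 seeds return 0.05
and the rest 0.10, never 0.025.

In pipeline runs the comparison uses growth-phase time points only
(before the burst window opens): once coenocytes start releasing 2C/4C
newborns, the GSD is dominated by those low-ploidy outliers — the metric's
known sensitivity — and the series stops reflecting timer variability.

## Doubling-time regression and its transient bias

The nuclear content doubling time is `1/slope` from OLS of
`Σ f_i log2(x_i)` on time, restricted to 0–36 h (growth phase, ≥ 3
points); the slope standard error is reported directly and propagated to
the doubling time by the delta method (`SE_T = SE_slope/slope²`). The
regression is unweighted: event counts are near-constant (~5,000 per time
point) so weighting would change nothing.

On a *synchronized* population this estimator carries a small upward
transient bias that users should know about. The expected number of
divisions completed by time t is `E N(t) = Σ_k Φ((t − μk)/(cv·μ·√k))`,
which approaches `t/μ − 1/2 + cv²/2` only asymptotically; over a 0–36 h
window the offset drifts by about half a division, and the fitted
doubling time at `μ = 11 h, cv = 0.1` is 11.69 h in exact expectation
(Monte-Carlo at 5,000 cells: 11.67–11.71 across seeds). The bias is a
property of the protocol (synchronized start + finite window), not of the
implementation; fits on equilibrium (random-phase) populations or
noiseless exponential series recover the generating period to ≥ 10
significant digits. Empirical estimates in the 11–12 h range from an 11 h
timer are therefore expected, not evidence of a slower timer.

## Calibration and ploidy binning

The 1C-equivalent reference intensity is the mode of the lowest
significant peak of a Gaussian KDE of log2 intensities in a mixed-stage
sample; a peak qualifies if its prominence is ≥ 5% of the global density
maximum. The KDE bandwidth is fixed in log2 units (default 0.12, the
scale of a single peak's measurement CV) rather than set by a global rule:
on a ladder spanning 1C–128C, Silverman-type bandwidths scale with the
overall spread (~0.44 log2 units here) and merge peaks spaced 1 log2 unit
apart. Non-integer peak spacing triggers a diagnostic warning rather than
an error.

Events bin to `2^k` with `k = round(log2(I/reference))`; an event is
flagged debris (never silently dropped) when its residual exceeds the bin
tolerance (default 0.5, i.e. nearest-power-of-two assignment, in which
case only sub-1C events can be debris) or when `k < 0`. Histograms are
computed from retained events only and always sum to 1; the histogram
formulas are identities for the per-event mean and SD of log2 ploidy,
which the tests verify against brute-force per-event computation.

## Rank-sum comparisons

Group comparisons use the two-sided Wilcoxon rank-sum test with mid-rank
tie handling. For groups of ≤ 20 observations the p-value comes from the
exact permutation distribution of the rank sum, computed by dynamic
programming over the pooled (doubled) mid-ranks — valid under ties, and
identical to exhaustive enumeration over all `C(n_a+n_b, n_a)` assignments
(asserted for all group sizes up to 8). The two-sided convention is
`min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Larger groups use the tie-corrected
normal approximation with continuity correction (scipy). Serialized
summaries follow the Tukey boxplot convention (median, interpolated
quartiles, 1.5·IQR whiskers).

## The synthetic experiment

The generator emulates the full study design with known ground truth:

- **Timing** is one backbone shared by every media level — media affects
  volume only. This builds in the decoupling hypothesis so the pipeline
  can be tested for its ability to *recover* it.
- **Burst**: each coenocyte draws a cellularization threshold of 64C or
  128C (equal odds) and stops dividing on reaching it; it bursts at the
  threshold-crossing time clipped into the 48–72 h window (cells crossing
  after 72 h stay cellularized). Newborns are 2C with probability 0.8,
  else 4C; their count is threshold/ploidy (nuclei conserved exactly),
  each inherits an equal share of the mother's volume, and the cohort
  resumes dividing on a fresh timer.
- **Volume** grows exponentially from a newborn volume of ~525 µm³ (5 µm
  radius), at 0.043/h in 1× media — chosen so a newborn roughly doubles
  its projected area in ~24 h — falling to 0.012/h at 1/16×. The
  functional form and the sub-1× rates are ordinal stand-ins (the real
  rates are not known quantitatively); only orderings and decoupling are
  ever asserted on them.
- **Instrument model**: DAPI intensity = reference × ploidy × log-normal
  noise (median-1, CV 0.07); SSC = 10 × V^(2/3) × log-normal noise (CV
  0.10; the 2/3 exponent is surface-like scattering, invented, used only
  ordinally); 2% debris events with log-uniform intensity in
  [0.05, 0.7] × reference; ~5,000 events per time point at
  t = 0, 12, …, 72 h.

Per-purpose RNG streams are derived from the root seed with counter-based
spawn keys (timing, per-media volumes, per-(media, time) events and
microscopy, per-media time-lapse), so outputs are reproducible and
enlarging one table does not reshuffle another.

What the generator does *not* emulate: nutrient depletion and the
earlier/lower-content bursts seen at low media, temperature effects,
non-spherical or vacuolated morphologies, doublets and optical artifacts
of a real cytometer, and mother–daughter correlations in division timing.
Passing pipeline tests on synthetic data therefore demonstrate correctness
of the estimators under the stated model, not robustness to every artifact
of real cytometry data.

## Numerical choices and degenerate inputs

- Ploidy at a grid time counts divisions with time ≤ t (closed on the
  right).
- Envelope SDs use the population convention (ddof 0) across replicates.
- A division-interval matrix is extended until every cell's cumulative
  time exceeds the horizon, so late grid points never run out of draws.
- Degenerate calibration samples (a single unique intensity) short-circuit
  to that value; all-debris time points raise an empty-histogram error
  rather than emitting NaNs; non-growing series raise instead of
  reporting a negative doubling time.
- Fit windows require ≥ 3 interior points; rank-sum requires non-empty
  samples; `ssc_by_ploidy` reports under-populated bins (< 250 events by
  default) as missing rather than pooling across time points.

## Problem sizes

Unit tests run scaled-down populations (hundreds of cells); the
acceptance-style end-to-end checks use the study's own scale — 5,000
cells × 100 replicates per envelope, 5,000 events per time point, five
seeds for the cross-media decoupling check — which completes in seconds
to a few minutes on one core.
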