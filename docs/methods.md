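# Methods

## The kinetic model

An event is one capture-to-release passage of a relaxase--DNA complex
through a single α-hemolysin pore.  The model is a strictly sequential,
irreversible chain of seven states: level *i* is a constant-current
state with residual current *I*<sub>RES,i</sub>(%) (percent of the
open-pore current *I*<sub>O</sub>), and the step *i*→*i*+1 leaving it is
a single-barrier crossing, so the dwell in level *i* is exponential with
rate *k<sub>i</sub>*.  The final step 7→O reopens the pore.  Backward
transitions, intra-level substates and reversible flicker are outside
the model; this mirrors the observation that the pattern always runs
through the same seven levels in order.

Consequences used throughout the package:

- The whole-event duration is **hypoexponential**, with mean
  Σ<sub>i</sub> 1/*k<sub>i</sub>* (`hypoexp_mean`); the simulated mean
  agrees with this closed form, and the median ratio between the Y26 and
  Y18 parameterizations (~5.9 at the registry rates) reproduces the
  roughly six-fold slowdown caused by the Y26 kinetic trap.
- On the natural-log time axis *x* = ln *t*, an exponential dwell
  density becomes pdf(*x*) = *A·k·*exp(*x* − *k·e<sup>x</sup>*), a
  peaked curve with mode at *x* = −ln *k*.  Binning dwells in *x*
  spreads decades of time scales over comparable resolution, which is
  why rates spanning 0.17–1051 s⁻¹ can be fit with one procedure.
- A wild-type sample is a **two-component mixture** of molecules (DNA
  bound at Y18 or at Y26) that differ only in steps 2→3 and 3→4; its
  level-2 and level-3 dwell distributions are bimodal and fit by a
  two-component sum of the same log-axis pdf.

The registry (`src/porestep/data/tables.yaml`) stores the published
+120 mV step rates and level residual currents for both constructs, the
endpoint anchors of the two voltage-dependent steps, and the wild-type
mixture weights (0.78/0.22).  The weights are overridable because the
cleavage proportions are precisely the quantity such an experiment
measures.

Voltage handling: printed anchors are interpolated **log-linearly**
(rate–voltage relations are exponential in barrier models); steps with
no significant voltage dependence — and steps whose per-voltage values
were never published, such as the Y26 steps 2→3/3→4 — keep their
+120 mV value across the supported +100…+140 mV range.  Residual
currents are treated as voltage-invariant (they are defined as a current
ratio), and the open-pore current scales ohmically from 230 pA at
+120 mV (~1.92 pA/mV).  Capture frequency interpolates linearly between
the printed 12 events/min (+100 mV) and 55 events/min (+140 mV).

The sliding-window net-charge helper uses integer side-chain charges at
pH ≈ 7.2 (D, E = −1; K, R = +1; histidine 0; no pKa refinement); it
exists to ask whether the first protein segment entering the pore is net
negative and hence pulled by the field.

## The synthetic-data generator

No raw recordings are published, so analyses run on simulated traces
whose structure matches the recordings the methods were built for:

| parameter | default | why |
| --- | --- | --- |
| sampling rate | 20 kHz | digitizer rate of the recordings |
| low-pass filter | 4-pole Bessel, 5 kHz | named recording filter; digital emulation, causal, settled initial state |
| noise | Gaussian, sd 2 pA | typical α-HL RMS noise at 5 kHz bandwidth; no figure is published |
| open pore | 230 pA at +120 mV | stated open-pore current in 2 M KCl |
| captures | homogeneous Poisson | voltage-interpolated events/min |
| min dwell (resolution) | 0.2 ms | stated time resolution |

Events are drawn level by level (independent exponential dwells, level
currents = residual% × open pore) and rendered into the trace with
half-open, 0-based ground-truth spans that exactly tile each event.
Overlapping or overflowing events are dropped with a log warning, which
reproduces the real loss of events at high capture rates.  A
**no-filter mode** exists because the exact analog filter response is
unrecoverable; exactness tests (segment means, Gaussian noise checks)
use it, realism tests use the filter.

A short first level is **emergent, not injected**: level 1 at
~380 s⁻¹ falls below the 0.2 ms resolution in 1 − e^(−k·t_res) ≈ 7% of
events (`fraction_below_resolution`), which is how the analysis's
missing-level-1 flag gets exercised.

The denaturant ("GdnHCl") mode keeps levels 1–4 canonical and replaces
the tail with N ~ UniformInteger(3, 10) irregular blockades, residual
current ~ Uniform(1, 20)% and dwell ~ LogUniform(1 ms, 2.3 s).  These
distributions are synthetic: the blockade dwell upper bound was
calibrated once so the median whole-event duration is 2.0× the
canonical Y18 median (matching the observed 1.93 s vs 0.99 s) and then
frozen in the registry.

What the generator does **not** emulate: baseline drift, capacitive
transients, 50 Hz interference, pore gating, inter-experiment variation
of residual currents, or acquisition-format quirks.  Passing tests
therefore demonstrate correctness of the analysis under the stated
statistical model, not robustness to instrument artifacts.

## Level idealization

Event windows are maximal runs below 0.8 × open-pore current (runs
shorter than the resolution are discarded as noise excursions).  Inside
a window, change points come from recursive **binary segmentation on
segment means**: a split is accepted when it reduces the within-segment
sum of squares by more than a Schwarz-type penalty

    penalty = 3 · τ̂ · σ̂² · ln n,

with σ̂ the median absolute lag-8 sample difference (rescaled) and
τ̂ = max(1, (σ̂₈/σ̂₁)²) an autocorrelation inflation factor.  The lag-8
estimator stays correct for low-pass-filtered noise (lag-1 differences
underestimate it ~3×), and τ̂ compensates for the fact that correlated
noise produces larger spurious gains at equal variance; empirically the
null maximum gain is ~60 pA² for both white sd-2 and filtered noise,
comfortably under the penalty (~120–210 pA²) while the smallest true
level contrast in the seven-level ladders (≈7.8 pA over ≥4 samples)
stays comfortably above it.  A floor proportional to the signal energy
keeps noiseless input from splitting on float round-off, so noiseless
segmentation is exact.

Post-processing: segments shorter than the 0.2 ms resolution are merged
into the neighbour with the closer mean (the bandwidth-limited
invisibility of fast states), and adjacent segments whose means differ
by less than 4.5 standard errors (with the same τ̂ correction) are
pruned.  Segment means are computed with up to 5 samples trimmed from
each end — the settling span of the 4-pole Bessel at these rates — with
the trim shrinking to a quarter of the segment length for short
segments.

Ordinal assignment is **positional**: segments are numbered from level 1
(or level 2 when the first segment's residual current matches level 2
better — the missing-level-1 case) and the longest prefix within
5 percentage points of the construct's residual ladder keeps its
ordinals.  An event is canonical iff the whole pattern matches.  The
5-point cap is a design choice: adjacent template levels can differ by
as little as 1.3 points, but matching is positional (order is fixed by
the model), so the cap only needs to reject gross mismatches such as
denaturant tails.  For mixed samples each event is assigned under its
best-matching construct template.

Known resolution limit: the Y26 level-2→3 boundary combines a ~3 pA
contrast with a ~1 ms mean dwell, so a substantial fraction of Y26
events lose that boundary and are flagged non-canonical rather than
mis-segmented.  Canonical-only statistics remain unbiased because level
currents and dwells are independent in the model.

## Dwell-time fitting

Headline rates come from unweighted least squares of log-axis histogram
counts against the pdf evaluated at bin centers — the way such
histograms are conventionally fit — with 30 bins spanning the observed
ln-dwell range (~10 bins per decade over a typical 3-decade spread) and
initialization at the exact MLE k₀ = 1/mean.  The MLE itself is kept as
an independent cross-check (`mle_rate`); the two agree within 10% at
n = 300 across the seven decades of published rates.  Dwells below the
0.2 ms resolution are excluded before fitting, with no truncation
correction (the induced bias is < 8% even at the fastest published
rate).

The two-component fit is initialized from a count-weighted two-means
split of the histogram and its components are ordered fast-first;
component weights are amplitude shares.  Model choice is by BIC
(Gaussian residual approximation on binned counts) with a degeneracy
guard: components closer than a factor 3 in rate are unresolvable on a
log-axis histogram and force the mono model.  Confidence intervals are
percentile bootstrap over case-resampled dwell sets (≥200 replicates;
how the published intervals were constructed is not stated, so the
bootstrap is this package's choice), with fit-covariance Wald intervals
reported by the fits themselves.

Estimator precision at the study's n = 300 is a sampling sd of ~7% of
the rate (slightly above the 5.8% MLE bound).  Published confidence
intervals were compiled from several pooled experiments and can be
narrower than this single-cohort sampling error — a point to keep in
mind when comparing a single simulated cohort against them.

## Population classification

Features are standardized (log₁₀ *t*₂, log₁₀ *t*₃) per canonical event;
the log transform is forced by the 70-fold dynamic range of the level-3
dwell, and these two dwells are the only features because they are the
only steps that distinguish the constructs.  k-means with k = 2 and 10
restarts splits the cloud; the cluster with the longer mean level-3
dwell (higher standardized feature 2) is deterministically named
"Y26-like".  A silhouette below 0.4 triggers a warning — two-means on a
single Gaussian blob scores ~0.33, genuinely bimodal dwell data ~0.55+,
so 0.4 separates the regimes.

Limitation: k-means tends to equalize cluster sizes, so extreme mixtures
inflate the recovered minority fraction (about −0.05 bias on the
majority at a true 90/10 split; negligible at 78/22 and 50/50).  A
mixture model would remove this bias but is deliberately out of scope —
the analysis stays minimal, as in the experiments it reimplements.

## Problem sizes and reproducibility

Default analysis sizes follow the study conditions: n ≈ 300 events per
dwell-set fit, 60 rendered events per residual-current summary, 10 000
draws for law-of-large-numbers checks.  Every stochastic stage takes a
numpy `Generator` or derives sub-streams from one root seed
(`SeedSequence.spawn`), so pipeline reports are byte-identical across
runs at equal seed (timestamps are isolated in one JSON field).  The
acceptance script (`scripts/acceptance.py`) recomputes all headline
quantities from scratch at these sizes in a few seconds.
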