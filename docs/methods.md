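# Methods

`placeburst` analyzes single-unit recordings of hippocampal place cells made
while a rodent forages in a cylindrical arena, and ships a synthetic-recording
generator so the whole battery can be exercised end to end without recorded
data. This note documents the statistical definitions, the generator's model,
the numerical choices, and what the synthetic tests do and do not establish.

## Rate maps and place fields

Positions are tracked at nominally 60 Hz in an arena-centered frame (cm). The
rate map lives on an axis-aligned grid of square pixels (default 1x1 cm);
pixel (i, j) covers the half-open square [x0+i, x0+i+1) x [y0+j, y0+j+1) with
x0 = -n/2 pixels. Pixels wholly outside the circular arena are permanently
invalid; for a 30-cm arena this leaves on the order of 700 usable pixels.
Each spike is assigned to the pixel of the temporally nearest track sample;
each track sample contributes one sample interval of dwell. Rate =
spikes/dwell per pixel; a visited but silent pixel has rate 0.

Numerical choices made here, since the underlying analysis tradition leaves
them open: a pixel needs at least `min_occupancy` = 0.1 s of dwell to be
valid (suppresses one-sample rate spikes); maps are never smoothed before
statistics are taken; no running-speed filter is applied to spikes or
occupancy.

Two place-field definitions are supported: *above-mean* (valid pixels whose
rate strictly exceeds the mean rate over valid pixels — also the definition
of field size) and *top-quartile* (the 25% highest-rate valid pixels, ties
broken by pixel index order).

## Spatial statistics

* **Selectivity** = log10(mean in-field rate / mean out-field rate). A zero
  out-field rate yields an `inf` sentinel that is excluded from averages but
  still counts as "selective" for the inclusion rule below.
* **Coherence** = Pearson correlation between each valid pixel's rate and the
  mean rate of its valid 8-neighbors; reported alongside its Fisher Z
  (atanh, with r clipped to 1 - 1e-7 in magnitude). Undefined (error) when
  either side has zero variance.
* **Spatial information** (bits/s):
  I = sum_x p(x) lam(x) log2(lam(x)/lam_bar), with p(x) the occupancy
  probability renormalized over valid pixels and lam_bar = sum p(x) lam(x).
  lam_bar is deliberately the occupancy-weighted map mean — internally
  consistent with the formula's own p(x) — rather than session spike count
  over duration; the two differ slightly because spikes are pixel-assigned.

A note on noise behavior: iid pixel noise always lowers coherence, but raises
the *rate* information I (noise inflates apparent rate dispersion and
lam_bar); the per-unit-rate information I/lam_bar is the quantity that falls
monotonically with noise, and that is what the noise-monotonicity test
checks.

## Cross-session stability and cue classification

Similarity between two sessions' maps is the pixel-by-pixel Pearson r over
jointly valid pixels (>= 10 required), Fisher-Z transformed. The rotation
search rotates the first map about the arena center in 1-degree steps with
nearest-neighbor resampling (bilinear would manufacture smoothness and
inflate r; source pixels outside the circle are invalid) and returns the
angle maximizing r, ties to the smallest angle. The reported angle is the
CCW displacement of the field from the first session to the second, the
quantity directly comparable to the cue-card rotation.

Cue-following classification uses a 90-degree-wide arc (+/- 45 degrees,
half-open: exactly 45 falls out) around each reference: displacement near 0
follows the unmoved distal cue; displacement near the card rotation follows
the local cue; anything else is a remap. With a 90-degree card rotation these
windows partition the circle exactly. A random-pair baseline (similarity of
randomly drawn distinct-cell pairs) calibrates what "unrelated maps" look
like.

## Burst detection and temporal statistics

A complex-spike burst is >= 2 spikes, each within 15 ms of its predecessor,
with strictly decreasing amplitudes ("progressively diminishing" is read
literally; an amplitude tie terminates the burst, and the amplitude criterion
can be toggled off). Detection is a greedy left-to-right scan; a violating
spike starts a new candidate. A property test proves the scan equivalent to
an exhaustive maximal-run oracle.

Statistics: burst frequency (bursts/s), intra-burst spike rate (burst spikes
/s over the whole session), mean spikes per burst, intra-burst ratio (% of
all spikes inside bursts), and mean inter-burst interval, measured from each
burst's end to the next burst's start (not onset-to-onset). ISI-k is the
interval between a burst's k-th and (k+1)-th spikes, pooled across bursts.

Histogram conventions (the tradition states none): intra-burst ISI histograms
use 0.5-ms bins on (0, 15] ms; whole-session ISI histograms use 1-ms bins on
(0, 500] ms with the modal bin searched on (1, 50] ms so the reported peak is
the burst-scale mode rather than the refractory edge or the slow tail. Peak =
modal bin center (ties to the smallest); entropy = Shannon entropy of the
normalized histogram over nonempty bins; CV and SD come from the raw
intervals.

Burst reliability is the fraction of bursts whose onset (first-spike)
position falls inside the place field — onset because it best reflects the
triggering location. The burst place-map counts burst onsets instead of
spikes and is otherwise an ordinary rate map, so its coherence is computed
with the same operator.

## Spatial regression

`SpatialRateRegression` fits, at each valid pixel, a degree-1 plane over the
`span * N` nearest valid pixels with tri-cube distance weights, evaluated at
that pixel — the classic locally weighted regression construction. The span
is selected per cell by 10-fold cross-validation (pixels, not time, are the
regression unit; folds are simple random partitions) over the grid
{0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0}, minimizing mean held-out squared
error with ties to the smaller span. Fit quality is
PVE = 100 (1 - sigma_resid^2 / sigma_total^2), the conventional
variance-explained form; it is invariant to shifting or rescaling the rates.
Degenerate neighborhoods fall back to the minimum-norm least-squares
solution; weights are floored at 1e-12.

## Remap logistic regression

log(P(remap)/(1-P(remap))) = a0 + a1 ISI_peak + a2 T + a3 S2 + a4 S3, with T
the genotype indicator and S2/S3 session indicators; a reduced model drops
the ISI term via column selection. The fit is IRLS with step-halving, which
guarantees a non-increasing deviance path (exposed on the results object),
convergence at a coefficient change below 1e-8 or 100 iterations, and
standard errors from the observed information. Perfect separation is flagged
as non-convergence with a diagnostic. The implementation agrees with an
independent maximum-likelihood routine to ~1e-14 in tests. Note that the
full model's group coefficient is not the marginal group effect when ISI
peak differs by group; the reduced model reports that marginal effect.

## Pipeline conventions

Cells enter group tables only if mean firing rate > 0.2 Hz *and* spatial
selectivity > 0.5 (strict inequalities), gated on session 1 by default
(configurable — the tradition does not say which session gates). Pooled
temporal statistics are computed on the three sessions concatenated on a
common time axis. Group comparisons use a two-tailed Welch t-test with
Welch-Satterthwaite degrees of freedom, means +/- SEM per group, missing
values dropped pairwise per metric; a Benjamini-Hochberg column is emitted
for transparency but never used for decisions.

## The synthetic generator

Trajectory: heading follows a Brownian walk with a ~0.7-s decorrelation
time; speed follows an Ornstein-Uhlenbeck process around 6.2 cm/s (sd 20%),
floored at 5% of the mean; steps that would cross the wall reflect off the
wall normal. Defaults: 30-cm arena, 60-Hz sampling, 1500-s sessions.

Spiking is doubly stochastic. Firing *events* are an inhomogeneous Poisson
process (thinning) with rate baseline + peak exp(-d^2 / 2 w^2) around the
field center (defaults: baseline 0.1 Hz, peak 5 Hz at the center, width
4 cm). Each event is a lone spike with probability `p_single` (default 0.8)
or a burst whose extra-spike count is geometric (`burst_continue` = 0.18,
matching ~2.2 spikes/burst) and whose ISIs are gamma with configurable mean
and shape, rejection-truncated to (0, 15) ms so generated bursts satisfy the
detector's definition. Amplitudes decay 30% per spike within a burst, hence
strictly decrease. These defaults put overall rates near 1 Hz and
burst-scale ISIs near the 2.5-4-ms range typical of CA1 complex spikes.

Cue protocol: session 2 rotates the card 90 degrees CCW; sessions 1 and 3
share cues. A distal cell keeps its field; a local cell's field rotates with
the card; a remap cell's field is redrawn (seeded) at a uniformly random
radius between 0.2 and 0.7 arena radii, with the angular displacement
rejection-sampled to be at least 60 degrees (folded) from both the original
and the card-rotated positions. A uniform angular redraw would land inside
one of the two +/-45-degree cue windows about half the time and would then
*correctly* be classified as cue-following — "remap" as a generator class
means a field that genuinely moved away from both references.

What the generator does **not** emulate: theta modulation and phase
precession, multi-unit contamination, electrode drift, speed-dependent rate
modulation, inhomogeneous occupancy biases near walls, and non-Gaussian or
multi-peaked fields. Passing tests therefore demonstrate correctness of the
estimators under a clean generative model, not robustness to every artifact
of real tetrode data.

## Problem sizes used in checks

The packaged checks scale the study design down to keep runs quick while
preserving the statistics being tested: classification accuracy uses 60
cells at full 1500-s sessions; group-contrast power uses 28 vs 32 cells at
300-s sessions over 25 replicates (per-cell ISI-1 means are estimated from
dozens of bursts, so the contrast is far from the detection threshold);
the end-to-end acceptance run uses 12 cells per group at 600-s sessions.
These sizes are the package's own choices and are stated in the relevant
docstrings.

## Known limitations

* Nearest-neighbor rotation resampling quantizes angles; recovered rotations
  on smooth constructed fields are accurate to ~1-2 degrees, but on noisy
  estimated maps the rotation estimate inherits map noise (worst-case errors
  around 10-15 degrees in the acceptance run's conditions).
* The loess fit is O(N^2) per span; full-grid CV on a ~700-pixel map takes a
  couple of seconds per cell-session.
* The `inf` selectivity sentinel (zero out-field rate) is common in short
  synthetic sessions with low baseline rates; such values are excluded from
  group averages but still satisfy the inclusion rule.
* Whole-session ISI entropy depends on the histogram range; intervals above
  500 ms are excluded from the session histogram by construction.
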