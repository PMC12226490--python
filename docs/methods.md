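# Methods

This note documents the models, conventions and numerical choices behind
`socialdist`, and what the synthetic-data tests do and do not establish
about real recordings.

## Input model and filtering

A session is a dense array of per-frame, per-animal, per-body-part labels
`(x, y, likelihood)` in the multi-animal DeepLabCut CSV dialect (four
header rows: scorer / individuals / bodyparts / coords).  Exactly two
animals and five parts (nose, left ear, right ear, tail base, tail end)
are supported; animal identity is taken from the `individuals` header row
in file order, and no identity-swap detection is attempted.

Likelihood filtering at the cutoff *p* (default 0.6) marks a label
**rejected** when its likelihood is below *p* or the label is absent from
the file.  The threshold is inclusive — likelihood exactly *p* is
accepted — because the cutoff acts as a minimum confidence.  Missing and
sub-threshold labels are distinct states internally but equally unusable
downstream, and QC counts them together.  Filtering never alters
geometry, so raw coordinates stay inspectable after the fact.

Calibration multiplies pixel coordinates by the arena scale (default
0.68 mm/px, 30 fps, 480 × 270 px frames).  Tracks carry a units flag and
refuse double conversion.  On write, coordinates are emitted with full
float repr, making the read∘write round trip exact rather than merely
within tolerance; files remain bit-compatible with the DLC dialect.

## Centroids, locomotion, social distance

The per-frame centroid is the unweighted mean of the accepted labels in
the chosen subset (`all`, `no_tail`, `ears_only`).  The minimum number of
accepted labels for a valid centroid defaults to 1: per-part rejection
rates of 10–46 % are normal in this kind of data, and demanding more
parts would discard many frames without a principled cutoff.  It is
configurable, and frames with zero accepted parts are reported.

Locomotion is the mean of `‖c_{t+1} − c_t‖ · fps` over consecutive pairs
of valid frames.  Pairs spanning an invalid frame are dropped rather than
interpolated, and no smoothing is applied anywhere — measurement jitter
therefore inflates locomotion estimates exactly as it does in any
unsmoothed tracking analysis, which is why locomotion comparisons are
only meaningful between groups processed identically.

Social distance is the frame-wise Euclidean distance between the two
centroids, over frames where both are valid.  Sessions aggregate
hierarchically: per 30-s epoch (mean and median over valid frames), then
per session as the **mean of epoch means** and **median of epoch
medians** — not pooled-frame statistics, so epochs with few valid frames
are not down-weighted.  Epochs with zero valid frames carry NaN and are
excluded from the grand aggregation with a logged warning; a trailing
partial epoch is dropped likewise.  Time-binned summaries (default
20-min bins, i.e. 40 epochs) use the same aggregation rule per bin, and
the bin length must divide the session exactly.

## Head-body-tail reduction and symmetry

Regions per animal and frame: **head** = mean of accepted {nose, ears};
**tail** = mean of accepted {tail base, tail end}; **body** = mean of all
accepted labels, i.e. the centroid.  With five labels there is no
dedicated trunk label; the centroid is the natural body proxy, and a
head/tail-base-midpoint alternative (`body_mode="head_tailbase_mid"`) is
available for sensitivity checks.  A region is invalid in a frame when
none of its constituent labels is accepted.

The session matrix `S[i, j]` is the mean distance between animal 1's
region *i* and animal 2's region *j*, each cell averaged over its own set
of frames in which both regions are valid (region validity differs per
region, so forcing a common frame set would discard data asymmetrically).
A cell with no valid frame leaves the matrix, and hence the symmetry
ratio, undefined — surfaced as an error, not silently imputed.

The symmetry ratio `‖S − Sᵀ‖_F / ‖S‖_F` is 0 iff S is symmetric and is
bounded by √2 for entrywise non-negative S (the bound is attained by a
single off-diagonal entry).  It is scale-invariant, so units cancel.

## Annotation QC

Two denominators, deliberately different: per-part rejection percentages
use all frames of a session; the rejected-labels-versus-distance curve
(5-mm half-open bins, lower edge inclusive, both animals pooled per
frame) uses only frames with a defined inter-centroid distance, counting
the excluded remainder.  The frame-weighted average of binned values
equals the session mean over binnable frames exactly — a conservation
identity the tests assert.

## Morphometry

Body size is the absolute shoelace area of a user-supplied outline
polygon, in px² times the squared arena scale.  Polygons must be simple
(validated with shapely) with at least three vertices; orientation and
vertex rotation do not matter.  A synthetic tapered-ellipse outline
generator stands in for manually drawn masks in tests and simulated
cohorts; it is labelled synthetic and makes no anatomical claims beyond
plausible adult-mouse dimensions (a ~75 × 30 mm footprint, a few thousand
mm²).

## Bootstrap test

Given groups A (n) and B (m): Δμ = |mean A − mean B|; the null pools all
n + m values; each of n_boot = 10,000 iterations draws A* and B*, both of
size min(n, m), with replacement from the pool; p is the fraction of
iterations with Δμ* ≥ Δμ.  Ties count toward the null and there is no
+1 correction — the conservative closure, immaterial at 10,000 draws.
Both resamples use size min(n, m) even though this discards information
from the larger group; equal resample sizes keep the null exchangeable.
Significance is read at the 0.05 / 0.01 / 0.0001 tiers.  Resampling is
vectorized (chunked to bound memory) from a single named NumPy generator;
the seed is recorded in every result.  Pearson correlations and OLS fits
delegate to scipy.stats; SEM uses the n−1 sample standard deviation, with
a single observation reported as SEM 0 and flagged undefined.

## Synthetic sessions

The generator is a *statistical* stand-in for video tracking, not a
mechanistic mouse model.  Each centroid takes steps
`step_sd · N(0, I) + attraction · κ · u`, where `u` is the unit vector
toward the other animal and κ = 2 mm/frame, reflected at the arena walls
(inset by the body-template radius so body parts fit).  Five labels sit
on a rigid zero-mean template oriented along the most recent nonzero
step (initial heading +x), plus isotropic Gaussian jitter; emitted pixel
coordinates are clipped to the arena.  Because the template has zero
mean, the noise-free pipeline centroid equals the true centroid exactly.

Occlusion is i.i.d. per label per frame by default: rejected labels draw
likelihood Uniform(0, p), accepted ones Uniform(p, 1), so the sub-cutoff
probability equals the configured per-part rate exactly.  An episodic
mode replaces this with a two-state Markov chain (stationary occupancy =
the target rate, geometric occluded runs of configurable mean length) to
mimic grooming/digging bouts, and rates can multiply beyond a distance
threshold to emulate distance-dependent tracking failure.

Defaults describe one realistic condition: a 300 × 200 mm arena, 30 fps,
10-min sessions (18,000 frames), 80-mm body length, step_sd 4 mm/frame
(mean path speed ≈ 150 mm/s), jitter 1.5 mm (≈ 2 px), and per-part
occlusion rates of 0.44 (nose), 0.32 (tail base), 0.27 (tail end) and
0.11 (ears), reproducing the characteristic nose > tail base > tail end >
ears rejection ordering of top-view tracking.  What the generator does
*not* emulate: identity swaps, systematic (non-isotropic) pose-estimator
bias, wall-following and thigmotaxis, body flexion (the template is
rigid), or fur-colour-dependent label quality.  Passing tests therefore
demonstrate correctness of the measurement pipeline and calibration of
the statistics under known ground truth — not that any particular
biological effect size is recoverable from real videos.

## Pipeline conventions

The statistical unit is the cage/session for social distance and
symmetry, and the individual animal-video for locomotion (two per
session).  Age-split comparisons send boundary ties to the younger
group.  Sessions are treated as independent.  Group comparisons with
fewer than two usable values per side are skipped with a warning.  All
pipeline randomness (session seeds, simulated ages, bootstrap streams)
derives from the single config seed, so a rerun is bit-identical.

## Problem sizes in the test suite

The suite and the acceptance script run entirely on synthetic data
generated at run time: sessions of 900–20,000 frames for unit and
property tests, one full 108,000-frame session for the segmentation
check, 2,000 Monte-Carlo replicates (n_boot 2,000) for bootstrap
calibration, 100 randomized 30-frame sessions for oracle equivalence,
and 10,000 random matrices for the symmetry bounds.  These sizes give
stable statistics while keeping a full run to a few minutes.
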