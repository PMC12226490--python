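# socialdist

Quantitative analysis of **social distance in paired mice** from
markerless pose tracking.

When two mice share an arena, how far apart do they stay, who moves more,
and is their spatial arrangement balanced?  `socialdist` answers these
questions from DeepLabCut (DLC) multi-animal CSV output — per-frame
`(x, y, likelihood)` labels for five body parts (nose, left/right ear,
tail base, tail end) on each of two animals — turning an hour of top-view
video tracking into interpretable, statistically tested metrics.  It is
aimed at behavioural neuroscientists comparing strains, sexes or age
groups (e.g. autism-model BTBR mice against CBA controls) without manual
scoring.

## What it computes

Given a session filtered at a likelihood cutoff *p* (labels with
likelihood < *p* are discarded; default *p* = 0.6) and calibrated to mm:

- **Centroid** — per frame, each animal's position is the unweighted mean
  of its accepted labels, `c_t = (1/k) Σ x_i`, optionally restricted to a
  part subset (`all`, `no_tail`, `ears_only`) as a robustness check.
- **Locomotion rate** — mean frame-to-frame centroid displacement,
  `mean_t ‖c_{t+1} − c_t‖ · fps` (mm/s), over consecutive valid frames
  only (no interpolation).
- **Social distance** — the Euclidean distance between the two centroids,
  summarised per 30-s epoch (mean and median over the epoch's valid
  frames; a 60-min, 30-fps session gives 120 epochs of 900 frames) and
  per session (mean of epoch means, median of epoch medians), plus 20-min
  time bins.
- **Head-body-tail (HBT) symmetry** — labels reduce to head (nose+ears
  mean), body (all-label centroid) and tail (tail-label mean); the 3×3
  matrix `S` holds mean inter-animal region distances (`S_ij` = mean
  distance from animal 1's region *i* to animal 2's region *j*) and its
  **symmetry ratio** `‖S − Sᵀ‖_F / ‖S‖_F` is 0 for perfectly balanced
  interaction and approaches √2 with extreme directional imbalance.
- **Annotation QC** — per-part rejection percentages and mean rejected
  labels per frame in 5-mm distance bins, to catch tracking quality that
  covaries with the distance being measured.
- **Morphometry** — body size as the shoelace area (mm²) of an outline
  polygon.
- **Statistics** — a pooled-null bootstrap difference-of-means test:
  Δμ = |mean(A) − mean(B)|; both groups are pooled, two samples of size
  min(n, m) are redrawn with replacement 10,000 times, and
  p = fraction of resampled Δμ* ≥ Δμ.  Bonferroni correction, Pearson
  correlations with OLS fits, and mean ± SEM summaries round this out.

A synthetic session generator produces two-animal correlated-random-walk
trajectories with tunable locomotion, inter-animal attraction/avoidance,
rigid five-point body templates and per-part occlusion — with full ground
truth, so every stage is testable without video data.

## Worked example

```python
import numpy as np
from socialdist import (SimConfig, simulate_session, apply_p_cutoff, to_mm,
                        compute_centroids, social_distance_epochs,
                        reduce_to_hbt, hbt_matrix, bootstrap_t_test)

# a 10-min session of two mildly avoidant mice
cfg = SimConfig(seed=7, n_frames=18_000, attraction=-0.3)
track, truth = simulate_session(cfg)
filt = to_mm(apply_p_cutoff(track, p_cutoff=0.6))

c1, c2 = compute_centroids(filt, part_subset="all")
epochs = social_distance_epochs(c1, c2, epoch_length_s=30.0, session_id="demo")
print(f"epochs: {epochs.n_epochs}")
print(f"grand mean distance: {epochs.grand_mean_mm:.1f} mm")

regions = reduce_to_hbt(filt)
hbt = hbt_matrix(regions[:, 0], regions[:, 1], session_id="demo")
print(f"symmetry ratio: {hbt.symmetry_ratio:.3f}")

# compare two groups of session-level means with the bootstrap test
rng = np.random.default_rng(0)
a, b = rng.normal(117.8, 15.0, 19), rng.normal(103.6, 11.0, 12)
res = bootstrap_t_test(a, b, n_boot=10_000, seed=1)
print(f"delta_mu = {res.delta_mu_observed:.1f} mm, p = {res.p_value:.4f}")
```

prints

```
epochs: 20
grand mean distance: 182.6 mm
symmetry ratio: 0.001
delta_mu = 10.4 mm, p = 0.0363
```

The 18,000-frame session segments into 20 epochs; the avoidant pair keeps
a large mean separation (182.6 mm in a 300 × 200 mm arena); their
interaction is near-perfectly balanced (ratio ≈ 0, as expected when
neither animal systematically leads); and the two synthetic cohorts of
session means differ by 10.4 mm, which the pooled-null bootstrap calls
significant at p < 0.05.

## Command line

```bash
socialdist simulate --out session_dir/ --seed 3       # DLC CSV + truth
socialdist qc --csv session_dir/session.csv --meta session_dir/session_meta.yaml
socialdist run --config cohort.yaml                   # full cohort pipeline
```

The cohort config lists real sessions (`sessions: [{csv: ..., meta: ...}]`)
or a `simulate:` block with two group parameter sets; the report
(per-session metrics, group comparisons, correlations, time-bin table)
is written as CSV/JSON.

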