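# Methods

This note records the models, numerical choices and known limitations of
the `dfcstates` pipeline, in the order data flows through it.

## Scope and input contract

The package operates on *extracted ROI time series* (T volumes × R regions,
plain TSV). Image-space preprocessing — slice timing, realignment, spatial
normalisation, smoothing, nuisance regression, band-pass filtering — is
assumed done upstream and is out of scope, as is any imaging file format.
The reference protocol is a 239-volume scan at TR = 2 s with the first 10
volumes discarded (229 analysed), parcellated into 160 ROIs grouped into
four networks: default mode (DMN, 34 ROIs), cognitive control (CCN, 53),
sensorimotor (SMN, 33) and occipital–cerebellum (OCN, 40).

## Motion quality control

Framewise displacement follows the Power convention:
FD_t = Σᵢ|Δdᵢ| + r·Σⱼ|Δθⱼ| with translations d in mm, rotations θ in
radians, and r = 50 mm (the conversion radius is a convention, not a
measured quantity). FD at the first volume is defined as 0 and excluded
from the mean, since the differential is undefined there. Subject exclusion
uses the raw realignment parameters: any |translation| > 3 mm or
|rotation| > 3° excludes the subject; the comparison is strict, done in
radians to avoid unit round-off at the threshold. High-FD volume censoring
("scrubbing") is deliberately not implemented.

## Sliding-window connectivity

Windows are rectangular (no taper), default 15 volumes with step 1;
window lengths shorter than 30 s trigger a warning because slow
fluctuations are then under-sampled. Within each window the Pearson
correlation matrix is computed, clamped to |r| ≤ 1 − 10⁻⁷ before
atanh so degenerate windows yield a large finite z (≈ 8.1) rather than
infinity, and flattened to the strict upper triangle in row-major order
((0,1), (0,2), …, (1,2), …) — the on-disk edge ordering contract (see
FORMATS.md). A zero-variance signal inside a window is an error naming the
ROI, not a silent NaN. The Fisher-z diagonal (the transform of r = 1) is
excluded from all means.

## State clustering

k-means under the Manhattan distance, with three deliberate choices:

- **Median centroid update.** The coordinate-wise median minimises total L1
  distance within a cluster, so median updates (true k-medians) are the
  internally consistent companion to an L1 assignment rule and guarantee a
  non-increasing objective, which the implementation asserts per iteration.
  A `update="mean"` switch reproduces the common mean-update variant used
  by general-purpose libraries; it carries no monotonicity guarantee.
- **k-means++ seeding adapted to L1** (selection probability proportional
  to L1 distance from the chosen set), best of `n_init = 10` restarts by
  final cost, iteration to an exact label fixpoint capped at
  `max_iter = 300`, and empty clusters re-seeded to the sample farthest
  from its centroid.
- **Elbow detection on the within-cluster distance curve.** For each
  candidate k the scan records the mean within-cluster distance and the
  within/between distance ratio (mean distance to assigned centroid over
  mean pairwise centroid distance). The selected k is the point of maximal
  discrete curvature (second difference after min–max normalisation) of
  the *within-cluster* curve. The ratio curve is reported for inspection
  but not used for detection: states that differ chiefly in overall
  connectivity strength are nearly collinear in edge space, so the mean
  pairwise centroid distance collapses as k grows and the ratio curve
  need not bend at the true k. A maximal normalised curvature below 0.1
  is declared "no pronounced elbow": the smallest candidate k is returned
  with a warning. This detector is a heuristic — on pure-noise data a
  noisy curve can occasionally exceed the threshold — and it cannot select
  the endpoints of the scanned range, so the range should bracket the
  plausible values.

States are then ordered by centroid strength (mean over all E edge values),
ties broken by fitting order, and named low / middle / high (k = 3).
Window assignment is nearest-centroid by L1 with ties resolved toward the
lower-strength state. Subjects whose label sequence does not visit all k
states are excluded from state summaries, since a per-state mean is
undefined for them. Clustering is run within each diagnostic group by
default (`pooling="per-group"`); a pooled mode clusters all groups jointly.

## Group statistics

Standard fixed-effects machinery, thin wrappers over scipy: one-way ANOVA
(F = MSB/MSW on (g−1, N−g) df), the same test reconstructed exactly from
per-group mean/SD/n (SSW = Σ(nᵢ−1)sᵢ²) for checking published summary
tables, pooled-variance pairwise t tests with Bonferroni adjustment
(p·m capped at 1, m = number of pairs), and Pearson χ² without continuity
correction. Partial correlation uses the residual method: x and y are each
regressed on the covariates plus intercept by least squares and the Pearson
correlation of the residuals is tested on t(df) with df = n − q − 2.
p-values are two-tailed and reported unadjusted. The composite cognitive
score is the unweighted mean of the scale columns (no per-scale
z-scoring; a standardising switch exists).

## Synthetic cohort generator

The generator is the validation instrument: it produces cohorts whose
windowed connectivity genuinely switches among latent states, with all
ground truth retained.

- **Latent dynamics.** First-order Markov chain over `n_states = 3` states,
  uniform start, self-transition probability 0.95 (mean dwell 20 volumes =
  40 s, longer than the 30-s window so windows can sit inside states),
  remaining mass split equally among the other states.
- **Emissions.** Given the state, volumes are i.i.d. zero-mean Gaussian
  draws whose correlation matrix has a network-block pattern: within-network
  correlation 0.15 / 0.40 / 0.70 for the low / middle / high state,
  between-network correlation half of within. Matrices are repaired by
  diagonal loading and re-normalised if a block pattern is not positive
  definite. An optional AR(1) factor (default off) adds temporal smoothness.
- **Group and subject effects.** Diagnostic group scales all off-diagonal
  correlations (NC 1.0, SCD 0.80, AD 0.90 — controls strongest, the
  subjective-decline group weakest, matching the ordering such cohorts
  show). Each subject additionally carries a trait-like multiplicative
  connectivity factor 1 + N(0, 0.15), clipped to [0.5, 1.4] so all scaled
  correlations stay inside (−1, 1); real cohorts show exactly this kind of
  stable inter-subject variation in overall connectivity strength, and
  without it a connectivity–cognition correlation would have no
  within-group variance to estimate.
- **Demographics and scores.** Sex, age, education and mean FD are drawn
  from group-specific distributions typical of an elderly memory-clinic
  sample (ages ≈ 63/65/71 ± 9 y; education ≈ 11/12/9 ± 5 y; FD ≈
  0.22–0.27 ± 0.12 mm). The composite cognitive score is linear-Gaussian:
  15 + 20·(true mean Fisher-z connectivity) − 0.08·(age − 65) +
  0.10·education + N(0, 1.5²), where true mean connectivity is the
  occupancy-weighted mean of the subject's per-state mean z. The slope and
  noise were chosen once so the implied covariate-adjusted
  score–connectivity correlation sits at r ≈ 0.3–0.45, the magnitude such
  cohort studies report.

**What the generator does not emulate:** hemodynamics, scanner noise and
physiological artifacts, spatial structure beyond the network blocks,
subject-specific *patterns* of connectivity (the subject effect is a pure
scale factor), and non-Gaussian or heavy-tailed signals. Passing tests
therefore validate the pipeline's algebra and its behaviour under a
well-specified switching model — not its performance on real BOLD data.

## A measured limitation: window-level state ambiguity

With 15-volume windows, the realized mean correlation of a window
fluctuates around its state's value with an SD of roughly 0.1 in mean-z
units. This fluctuation is shared across edges (all correlations in a
window are estimated from the same 15 samples), so it does not average out
with more ROIs. Since the adjacent-state separations implied by the default
correlation levels are only ≈ 0.16 and ≈ 0.22 in the same units, windows of
neighbouring states overlap substantially: even an oracle classifier that
knows the true state centroids mislabels 5–15 % of within-state windows
(adjusted Rand index ≈ 0.6–0.85 depending on ROI count), and the fitted
clustering inherits this ceiling, further biased by transition-spanning
windows that form a bridge between states. The pipeline reports the
measured recovery honestly rather than restricting evaluation to easy
cases; k-selection, strength ordering, group contrasts and the
score–connectivity correlation are all robust to this ambiguity, but
window-level label accuracy under these dynamics is intrinsically limited.
Longer windows or longer dwell times would raise it; both are protocol
constants here.

## Problem sizes used by the automated checks

The test suite and `scripts/acceptance.py` exercise the pipeline at reduced
scale so each check completes in seconds: cohorts of 6–12 subjects at
16–24 ROIs (full 229-volume scans) for clustering, elbow and pipeline
checks; 100 cohorts of n = 100 subjects at 16 ROIs for the correlation
power measurement; full 160-ROI dimensions wherever only per-window algebra
is involved (window counts, edge counts, top-edge selection). Scaling in R
changes the edge count quadratically but none of the contracts being
checked.
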