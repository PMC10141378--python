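# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `vrsense`, in the order the pipeline runs.

## Trajectories

A trajectory is a strictly time-ordered sequence of planar positions for
one subject, in metres and seconds. Sampling may be irregular; nothing
resamples, smooths or interpolates, and every downstream quantity is
defined directly on the samples. Any vertical component in the input is
ignored (the analysis is of floor-plane movement). Interval speed is chord
distance over time gap, so it slightly underestimates true speed along
curved paths between samples — immaterial at typical telemetry rates.

## Behavioural features

Four features are computed per 5-s tumbling window aligned at the
subject's first timestamp. Windows are half-open `[t0+5k, t0+5k+5)`; only
complete windows count, and a window with fewer than two samples is
skipped with a logged notice. Tumbling (non-overlapping) windows were
chosen over sliding ones to keep windows statistically independent given
the level is constant within a window.

- **Moving time** sums the durations of intervals whose speed strictly
  exceeds 0.2 m/s. The threshold separates purposeful walking from
  incidental drift; *strict* inequality makes the boundary case inert.
  A `moving_time_stat="mean"` variant (mean qualifying interval duration)
  is exposed for comparison but is not the default: the total time moving,
  not the mean interval length, is the quantity with the stress
  interpretation.
- **Track spread** is the maximum distance of any sample from the
  trajectory centroid — exactly rigid-motion invariant.
- **Wandering style** counts unique grid cells (0.1 m squares) per metre
  of path. A position maps to cell `(round(x/0.1), round(y/0.1))` with
  ties rounded half away from zero — deterministic and
  platform-independent, unlike banker's rounding. Zero path length yields
  0 by convention.
- **Hotspot spread** is the distance from the most-visited cell's centre
  to the centroid. "Most visited" is by dwell time: each interval's
  duration is charged to the cell of its *starting* sample (a left Riemann
  attribution — the simplest rule whose per-cell dwells sum exactly to the
  trajectory duration); the final sample contributes presence but no
  dwell. Ties break by sample count, then lowest `(i, j)`
  lexicographically, so results are reproducible. A
  `hotspot_centre="mean_cell"` variant (mean of unique cell centres) is
  exposed for comparison.

Exact invariances worth knowing: track spread is invariant under any
rigid motion; the cell-based features (ws, hs) are exactly invariant only
under grid-aligned translations (integer multiples of the cell size) and
quarter-turn rotations, and approximately invariant otherwise (the grid
phase shifts). Scaling coordinates *and the cell size* by `k` scales
ts and hs by `k` and ws by `1/k` exactly. The test suite asserts the exact
forms and does not assert the approximate ones.

## Stress model

The window features are pooled over all training subjects, z-scored, and
modelled by a 6-state hidden Markov chain with diagonal-Gaussian
emissions. Six states span "very low" to "very high" stress; one global
model is fitted per session (a per-subject model is possible by passing a
single sequence, but ten short sequences fit one model far better than
ten tiny ones).

**Fitting.** Baum–Welch likelihood surfaces with six components are
multimodal, and two failure modes are endemic: (a) plain random restarts
rarely place one initial mean in each true cluster (probability
`6!/6⁶ ≈ 1.5%` for random-row inits), and (b) the Gaussian likelihood is
unbounded, so a state collapsing its variance onto a few near-identical
windows can dominate model selection. The fit therefore runs a two-stage
search: `max(4·n_init, 24)` short (15-iteration) EM runs seeded by
hmmlearn's k-means, by a 1-D k-means over the movement index
`z(mt) + z(ts)` (one state per ordered interval), and by kmeans++ draws;
then full EM from the eight highest-ranked starts. Restarts are ranked by
log-likelihood with every variance floored at `1e-4` (z-space) — the floor
caps degenerate density spikes without penalising genuinely tight states.
All randomness flows from the `seed` argument, so a fit is bit-for-bit
reproducible.

**State ordering.** States are relabelled post hoc so the level rises
with movement: ascending moving-time mean first, ties broken by ascending
track-spread mean. Moving time saturates at the window span for every
regime faster than the threshold, so its fitted means differ only by
noise among fast states; it is rounded to 0.1 s before comparison and the
strictly speed-monotone track spread decides the order. (Ordering by
wandering style instead is unreliable: ws is not monotone in movement
speed.)

**Scores.** Level `k` maps to `k/5`; a subject's score averages over
windows. The default uses the posterior-expected level (forward–backward),
giving a continuous score in [0, 1]; `mode_level` averages the discrete
Viterbi path instead. Both decode modes are exposed. Numerics are
hmmlearn's, in log space throughout; the package's own brute-force path
enumeration (tests) checks Viterbi and forward outputs to 1e-9 in log
space on small models.

## Sentiment scoring

Visual sentiment uses the dimensional model of emotion: valence and
arousal, three levels each. Classes map to {0, 0.5, 1}; averaging four
viewing directions per hotspot therefore yields multiples of 0.125 —
which is also the granularity observed throughout the bundled reference
valence table, the reason four directions is the default. Score-to-class
banding uses `[0, 0.33) / [0.33, 0.66) / [0.66, 1]` with the top band
closed below.

Scoring itself is a provider contract. The reference provider reads a
labels CSV (one class pair per subject × hotspot rank × direction). A toy
brightness/saturation scorer is included solely so the image path can be
smoke-tested end to end; it is deterministic but makes no perceptual
claim, and no neural classifier ships with the package.

## Fusion, summaries and classification

Per hotspot, the visual scores are averaged over directions *first*, then
fused with the behavioural stress score as a weighted average (default
weight 0.5; weight 0 returns the visual mean, weight 1 the behavioural
score). The fused value always lies between its two inputs.

Subject summaries use the **population** SD (÷n): across the bundled
reference tables the printed SD cells equal the population form (e.g.
0.150 for a row whose sample SD would be 0.168), which fixes the
convention. Report values are rounded to 3 decimals, half away from zero.

Subject classification bands the per-subject mean at 0.3/0.6 (the cut
points used in the published narrative; the 0.33/0.66 class bands remain
the default for single scores), and additionally counts subjects with
mean fused arousal below 0.5 as having had a calm experience.

### Reference tables

The regression fixture embeds a published 10-subject evaluation: per
subject, five per-hotspot valence and fused-arousal scores plus printed
Mean/SD cells and a mean-over-subjects row. Printed entries are
3-decimal roundings; any entry that is exactly the half-away-from-zero
rounding of a distinct multiple of 0.0125 (0.163 → 0.1625, 0.288 →
0.2875, 0.438 → 0.4375, 0.688 → 0.6875, 0.813 → 0.8125) is restored to
that four-decimal value before statistics are recomputed. With this
restoration all 40 Mean/SD cells and both column-mean rows reproduce
exactly at 3 decimals; from the raw printed entries, two SD cells differ
by one unit in the last digit (0.207 vs 0.208 and 0.181 vs 0.180) —
pure input-rounding artefacts. Rounding the restored entries back to 3
decimals reproduces the printed tables verbatim.

## Synthetic sessions

The generator emulates the qualitative contrast the stress model relies
on: regime-switching movement where higher stress means faster, more
erratic walking.

- **Movement** is a correlated random walk: per-sample speed is Gaussian
  (truncated at 0) and the heading turns by Gaussian increments with SD
  `(1 − persistence)·π`. The six-regime ladder is

  | level | speed (m/s) | SD | persistence |
  |------:|------:|------:|------:|
  | 0 | 0.05 | 0.015 | 0.99 |
  | 1 | 0.13 | 0.012 | 0.98 |
  | 2 | 0.35 | 0.030 | 0.97 |
  | 3 | 0.50 | 0.050 | 0.96 |
  | 4 | 0.75 | 0.080 | 0.95 |
  | 5 | 1.00 | 0.080 | 0.94 |

  Speeds rise strictly with level and adjacent levels are ≥ 3 SD apart.
  Two further constraints calibrate the ladder: every level sits several
  SD away from the 0.2 m/s moving-time threshold (a regime straddling the
  threshold has bimodal windowed moving time, which a Gaussian emission
  cannot represent), and sample times carry ±15% frame jitter — realistic
  for headset telemetry and necessary to keep windowed features
  continuous rather than lattice-valued.
- **Schedule.** The regime follows a sticky Markov chain at window
  granularity (stay probability 0.9), so each 5-s window has exactly one
  true level and decoded windows compare one-to-one with truth.
- **Labels** are drawn i.i.d. per hotspot × direction; valence uniform
  over its three classes, arousal biased towards calm (0.6/0.3/0.1),
  mirroring a quiet exploratory session.
- **Seeding.** All randomness derives from one session seed through
  documented seed-sequence streams (`[seed, 1, subject]` per trajectory,
  `[seed, 2]` for labels, `[seed, 3]` for the known-model benchmark), so
  any subset of a session regenerates independently and byte-identically.

**What the generator does not emulate:** room geometry and obstacles,
purposeful navigation toward content, stops at points of interest
(beyond the optional attractor-cell bias), inter-subject variability in
baseline gait, and any coupling between what a hotspot looks like and the
sentiment labels. Passing recovery tests on this data shows the pipeline
is correct and self-consistent, not that six stress levels are separable
in real VR telemetry.

## Recovery studies and their scope

Two recovery settings are distinguished deliberately:

- **Parameter recovery (known model, 5,000 windows).** Feature sequences
  are sampled from a six-state Gaussian HMM whose per-level moments are
  measured from the movement generator (emission SDs floored at 2% of the
  across-level spread so the known model is well-conditioned). Baum–Welch
  recovers the ordered emission means within 10% relative error and
  decodes the generating states with ≥ 90% (in practice ≥ 99.9%) window
  accuracy. This is the clean test of the fitting machinery, because the
  data really are conditionally Gaussian.
- **End-to-end recovery (session scale, 600 windows).** Features are
  extracted from simulated trajectories and the fit must rediscover the
  regime schedule. This passes at session scale (≥ 99% window accuracy at
  the preset seed). It is *not* asserted at 5,000 windows: windowed
  trajectory features are not Gaussian within a regime (moving time has
  atoms at 0 and near the window span, the cell count is lattice-valued,
  hotspot spread is nearly uniform on [0, ts] for straight fast walks),
  and with enough data maximum likelihood prefers a different six-state
  partition — EM initialized at the true partition walks away from it.
  That is a model-misspecification fact about Gaussian HMMs on these
  features, documented here rather than papered over; with more windows
  the discrepancy grows rather than shrinks.

Problem sizes in the test suite (600 and 5,000 windows, 1,000 random
trajectories for the property sweep, exhaustive path enumeration up to
T = 6) were chosen so the full suite runs in well under a minute while
every estimate above is still comfortably resolved.

## Degenerate inputs and numerical conventions

- A feature with zero variance across training windows gets unit scale
  and a floored emission variance (1e-6), with a logged warning.
- Duplicate timestamps, non-finite coordinates and empty sequences are
  rejected with errors naming the offending row or field.
- Dwell ties and hotspot-rank ties break deterministically
  (lexicographic); report rounding is half away from zero at 3 decimals;
  trajectory CSVs round-trip float64 exactly (`%.17g` out,
  `float_precision="round_trip"` in).

## Known limitations

- The stress levels are relative to the session: z-scoring and
  movement-ordered relabelling calibrate the scale to the observed
  cohort, so a uniformly calm cohort still spans levels. Absolute
  calibration would need labelled stress data, which is out of scope.
- The behavioural→arousal link (faster movement = higher arousal) is an
  assumption inherited from the underlying model, not validated here.
- The fusion weight is a free parameter with an equal-weight default; no
  principled estimate of the relative reliability of the two channels is
  attempted.
- With six states and four partially redundant features, unsupervised
  fits on *real* telemetry should be treated as exploratory; inspect the
  fitted emission means (exposed in original units) before interpreting
  levels.
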