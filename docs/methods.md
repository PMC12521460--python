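# Methods note

This note records what the package computes, the assumptions behind each
default, and the numerical choices, in enough detail to re-derive every
quantity the test suite asserts.

## 1. Signals and interval conventions

All intervals are half-open `[start, end)` in seconds. Heart-rate (HR)
samples are timestamped bpm values; a sample at `t` contributes
`[t, t + 1/rate)` of recording coverage, and coverage intervals are maximal
runs whose inter-sample gap never exceeds twice the nominal period
(default 1 Hz). Samples outside the physiologically plausible 30–220 bpm
band are masked (length-preserving) and excluded from coverage and
features. Facial-expression (EFE) frames are 7-class probability vectors
at 1 fps (higher native rates are downsampled by keeping the first frame
per second); rows are renormalised to sum to 1 and all-zero rows masked.

## 2. HR windowing and features

Windows of length `T` slide with 50 % overlap inside each coverage
interval; starts are `c0, c0 + T/2, …` while `start + T ≤ c1`, so windows
never straddle gaps. `T` ranges over `{60, 90, 120, 150, 180, 210}` s — a
grid spanning the sub-minute to several-minute timescales on which
classroom arousal episodes unfold; using a grid rather than one length
avoids committing to an episode duration a priori.

Each window is summarised by six statistics: mean `mu`, population
standard deviation `sigma`, mean absolute first difference `mu_v`
(speed), mean absolute second difference `mu_a` (acceleration), and the
normalised `mu_v_norm = mu_v/sigma`, `mu_a_norm = mu_a/sigma` (defined as
0 when `sigma = 0`: a flat window has no dynamics). Level features are
shift-equivariant and scale-equivariant; the normalised dynamics are
shift- and scale-invariant — properties asserted on random windows.

## 3. Two-cluster anomaly model

Per student (sessions pooled, per window length), the feature matrix is
z-scored and fit with a two-component full-covariance Gaussian mixture
(scikit-learn, `n_init=5`, `max_iter=200`, `tol=1e-4`, `reg_covar=1e-6`,
fixed seed; the best of the restarts by likelihood is kept, so fits are
deterministic). The **minority-weight component is the specific-moment
(SM) cluster**; when the weights are within 0.05 of each other the
component whose mean lies farther from the global feature mean wins. At
least 10 rows are required; degenerate input (all rows identical) yields
no SMs. SM-labelled windows map back to `[start, start+T)`; the final HR
event set is the merged union over the whole `T` grid.

The EFE branch clusters unmasked frames the same way (without
standardisation — the inputs are already probabilities). Minority frames
contribute `[t, t+1)`; intervals closer than 2 s are merged (dropouts of a
frame or two do not split an expression episode) and merged intervals
shorter than `efe_min_duration_s = 3` s are discarded. The duration floor
is a deliberate addition to the frame→merge pipeline: a specific moment
must persist over several frames, and an isolated deviant frame is
recogniser noise (a blink, a transient occlusion), not an episode. Without
it, minority-cluster mass scatters over dozens of single-frame detections.

## 4. Silhouette and feature ablation

Cluster quality uses the per-sample silhouette
`s(i) = (b(i) − a(i)) / max(a(i), b(i))`, with `a(i)` the mean distance to
the other members of `i`'s cluster and `b(i)` the smallest mean distance
to another cluster; singletons and `max(a,b)=0` score 0. The
implementation is vectorised (pairwise distances via `scipy.spatial`);
its correctness is asserted against a literal brute-force evaluation at
1e-9 on random instances up to n = 200, and cross-checked against
scikit-learn. `feature_ablation_silhouettes` ranks feature subsets
(each single feature plus level / speed / acceleration groups) by the mean
silhouette of the fitted labels restricted to that subset, identifying
which statistics carry the separation.

## 5. Fusion and temporal IoU

Both branches are rasterised on a 1 s tick grid (a tick is marked when its
span intersects any interval; epsilons of 1e-9 guard float edges). Within
HR coverage the fused tick score is `0.7·[HR] + 0.3·[EFE]` against a
threshold of 0.3, i.e. the union of the branches, with HR carrying at
least as much weight by construction (the config enforces
`w_hr ≥ w_efe`). Outside HR coverage the facial stream is the sole source.
Temporal IoU between two event sets is intersection over union of their
tick masks, in percent, 0 when the union is empty; on integer-second
intervals it is exact, which the tests verify against set arithmetic.

## 6. Convergence with observations — two denominators

An SM interval *matches* when it overlaps a salient observed event by
≥ 1 s. Two rates are reported:

- **SM-count rate** (default): the fraction of detected SM intervals that
  match. This is the natural "X of the N specific moments correspond to an
  observed event" reading, but it is *not* monotone under fusion — the
  fused (union) set inherits every unmatched interval of both branches, so
  its rate is a count-weighted mixture of the branch rates and can sit
  below the better branch. This is a structural property, not a defect,
  and the worked example in the README shows it.
- **Event-coverage rate**: the fraction of observed salient events covered
  by at least one SM interval. This reading is monotone under union, so
  fusion can only match or improve it; the multimodal-dominance property
  is therefore stated and tested on event coverage. Both triples appear in
  `ConvergenceReport`.

`improvement_summary` averages the fused-minus-unimodal gains and rounds
with exact decimal half-up arithmetic, so printed percentages reproduce
exactly (e.g. a mean gain of 28.015 reports as 28.02; binary-float
rounding would give 28.01).

## 7. Questionnaires

A scale score is the mean of its items after reverse-coding flagged items
(`v → 6 − v`), rounded to 3 decimals. The FLCA short form contains two
low-anxiety statements; their positions are form-dependent, so they
default to indices {0, 1} and are overridable per response. The dominant
session emotion is the label of the highest of the FLE / FLCB / FLCA
scores; exact ties report `"mixed"`.

## 8. What the synthetic generator emulates

Each session (default 80 min at 1 Hz) is a per-student baseline
(60–90 bpm) plus AR(1) noise (`phi = 0.9`, stationary SD 1.5 bpm). Five
120 s arousal episodes, one per equal time slot, scale the AR(1)
*innovation* magnitude by 3 — raising the speed and acceleration features
the detector keys on without moving the mean, which is how short arousal
bursts present in wearable HR. The EFE stream is Dirichlet
`(1,1,1,1,1,1,24)` — a confident recogniser on a mostly-neutral face
(mean neutral probability 0.8) — with episode frames shifted half-way
toward a sampled non-neutral class, and 2 % frame dropout. The observation
track notes each episode with probability 0.8 (as a partially overlapping
salient event) plus a Poisson(2) number of non-salient routine events.
Questionnaire responses are integer-clipped normal draws whose means move
with the episodes' valence. One master seed streams per-session sub-seeds
through `numpy.random.SeedSequence`.

The generator does **not** emulate: circadian or posture-driven HR trends,
sensor-specific artefact shapes, correlated HR/EFE noise, inter-annotator
disagreement in the observation track, or realistic facial-expression
temporal dynamics (frames are i.i.d. around their mixture). It exists to
give the pipeline a ground truth, not to be a physiological simulator.

## 9. Measured behaviour at the study conditions

All values below were measured at the frozen defaults before the
corresponding tests were written; nothing was tuned toward them.

- HR episode recovery over 20 seeded cohorts (1 student × 2 sessions):
  mean recall 0.935, mean precision 0.63 (the acceptance thresholds are
  ≥ 0.8 and ≥ 0.6). Across other master seeds the precision mean
  fluctuates roughly 0.58–0.63: the merged union over six window lengths
  deliberately over-segments, trading precision for recall.
- Null cohorts (episode multiplier 1): a two-component mixture *must*
  allocate a minority cluster, so the flagged time fraction can never be
  0. Per window length the flagged fraction averages 0.41 against a
  minority-weight floor of 0.44 (ratio ≈ 0.97 ≤ 2). The union over the
  grid saturates (~1.0) under the null by construction — six independent
  ~0.44 allocations blanket the session — so the null invariant is stated
  per window length.
- Fused event coverage matched or beat both unimodal branches in 20 of 20
  seeded cohorts.

## 10. Problem sizes and runtime

A session is 4 800 HR samples and 4 800 EFE frames; a 2-session cohort
yields ~300 windows across the T grid per fit. The full non-acceptance
suite runs in ~4 s; the acceptance tests in ~23 s; `scripts/acceptance.py`
in ~25 s (the EFE fits on 9 600 × 7 frame matrices dominate).

## 11. Limitations

- The two-cluster model always produces a minority cluster; on truly
  uneventful data the detector reports moments anyway. Interpreting SM
  sets requires the null baseline of §9.
- Window-level labels are coarse: a detected interval is a union of
  overlapping windows and typically over-covers the underlying episode.
- The EFE branch assumes a calibrated 7-class recogniser; the bundled
  histogram backend is a deterministic stand-in, not a face model.
- Convergence against observations treats the narrative track as ground
  truth; observer misses depress all rates equally.
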