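# Methods

This note documents the models, estimators and numerical choices behind
`vitalkin`, what the synthetic generator does and does not emulate, and the
known limitations of each stage.

## The analysis model

A trial is one goal-directed right-hand action (grasp, offer, drop,
point-to-surface, thumb-up, silence gesture, point-to-person) performed in
one of five conditions: two vitality forms (gentle, rude) and three speed
modulations (slow, neutral, fast). The hand starts and ends at a common
rest position, moves to an action-specific goal (GO-phase) and returns
(Return-phase). All statistics and classification use the GO-phase only:
the movement toward the goal is the communicative act; the return is not.

Positions are the four rigid-body centroids C1 (wrist), C2 (elbow),
C3 (shoulder), C4 (chest), sampled at 100 fps in meters. Kinematic features
are computed from the wrist; postural features from the arm/chest geometry.

## Segmentation

Positions are low-pass filtered (zero-phase 2nd-order Butterworth, 10 Hz
default — jerk via triple differencing is noise-dominated otherwise), then
differentiated three times by central differences.

Movement onset/offset uses a speed threshold **relative** to the trial's
peak (default 5%), so slow and fast trials segment comparably:

1. *Onset*: first frame where speed exceeds the threshold for ≥ 50 ms,
   refined by walking back down the rising flank until the speed stops
   decreasing or falls below a quarter of the threshold. The refinement
   matters: a bare 5% threshold structurally clips ~6% of a minimum-jerk
   movement at each end (the profile spends that long below 5% of its
   peak), which alone would consume the GO-duration error budget.
2. *GO/Return split*: the hold at the target is identified as the first
   sustained below-threshold interval that occurs far (≥ 75% of the
   maximum distance) from the start position — speed dips mid-movement and
   the quiescence back at the start do not qualify. The split is the first
   frame entering the minimum-speed plateau inside a 0.3 s window anchored
   at the arrival-distance plateau (walking back from the hold while the
   distance from start stays within ±0.2% of its hold value), again
   flank-refined. Anchoring on a plateau rather than an argmax is what
   makes the split robust to jitter in the hold and to overshooting
   excursions just before arrival.
3. *Return end*: last above-threshold frame; a trial with no sustained
   post-split activity gets an empty return range (with a warning).

All intervals are half-open, 0-based frame ranges. On the default
synthetic conditions the recovered GO duration is within 10% of the
generator's nominal duration on average for every condition; the rude
condition (deliberately spike-laden) has the widest per-trial spread
(90th percentile ≈ 11%, worst trials ≈ 13%).

## The 22 features

* **Vmx, Amx, Jmx** — maxima of speed, acceleration and jerk magnitude
  over the GO-phase (m/s, m/s², m/s³).
* **S (Suddenness)** — the stable-law tail index α of the GO-phase speed
  samples, by a quantile-spread estimator: ν = (q95 − q05)/(q75 − q25) is
  inverted against a table of ν(α) for the symmetric α-stable family
  (ν(2) = 2.4387 is the Gaussian value, ν(1) = 6.3138 the Cauchy value;
  the table was computed from the stable quantile function and is
  monotone). Values are clamped to [0.35, 2]; a spread ratio below the
  Gaussian value maps to 2. The estimator needs ≥ 50 samples; it is fitted
  to the speed magnitude (not a velocity component). Quantile estimation
  makes it robust to the clipping of extreme samples.
* **POWmx, %POWmx, POSmx, %POSmx** — maximum perpendicular distance of the
  wrist/shoulder GO path from its start–end chord (m), and the moment of
  that maximum as a percentage of GO duration.
* **AL** — cumulative sum of inter-sample distances of the wrist path (m);
  computed on the filtered positions, so sub-sample jitter does not
  inflate it.
* **CWmx** — max of κ = ‖v×a‖/‖v‖³ over GO frames with speed > 1 mm/s.
  *Caveat*: κ grows as 1/speed² toward the movement boundaries, so CWmx is
  typically attained on the slowest eligible frame near onset; its value
  is therefore threshold- and grid-sensitive by construction (it is, e.g.,
  not invariant under time rescaling, unlike the interior curvature of the
  path). It is retained in this form for comparability.
* **SMmx, SMa, SMsd** — per-frame smoothness s(t) = 1/(1 + j(t)²) with j
  the jerk magnitude; bounded in (0, 1], higher = smoother. No attempt is
  made to match any particular absolute scale; the score's orderings
  (slow > gentle > neutral > fast > rude) carry the information.
* **VWmx, VWa, VWsd** — absolute residual between the speed signal and its
  zero-phase 2nd-order low-pass at 2 Hz (configurable; chosen below the
  voluntary-movement band so the residual captures tremor-like and
  corrective content).
* **AACmx/a/sd, AEmx/a/sd** — arm–chest angle ∠(C2−C3, C4−C3) and elbow
  angle ∠(C3−C2, C1−C2), in degrees over the GO-phase.

Trials failing any precondition (no movement, too-short GO-phase,
degenerate geometry) are excluded with a logged reason and reported in a
discard table.

## Statistical screening

Per feature, trial values are averaged into action × actor cell means
(7 × 2 = 14 rows when complete). Outliers are removed per condition across
those cell means: |x − mean| > 2.5 SD, single pass, with mean and SD from
the full input (a cell flagged as outlying becomes missing; rows with a
missing condition are dropped listwise). Note an algebraic bound: a single
extreme value among n contributes at most z = (n−1)/√n sample SDs, so no
single value among five can ever exceed 2.5 SD — the rule only bites with
enough cells.

Each feature's cell means are modeled by a one-way repeated-measures
ANOVA across the five conditions (subjects = the 14 rows, textbook
sums-of-squares partition). Mauchly's sphericity test (with the standard
chi-square approximation) gates the Greenhouse–Geisser correction: when
sphericity is rejected at .05, the p-value uses ε-scaled degrees of
freedom, with ε from the double-centered covariance. Normality is reported
per condition with the Lilliefors variant of the Kolmogorov–Smirnov test
(parameters estimated from data; requires ≥ 4 observations). The
implementation is cross-checked in the test suite against an independent
repeated-measures ANOVA (F agrees to ~1e−15, ε exactly; the Mauchly
p-value differs in the third decimal because the reference uses a
higher-order expansion).

Post-hoc: all 10 condition pairs by paired t-tests, Bonferroni-adjusted
(α = .05), encoded as per-condition letter strings (a=gentle, b=neutral,
c=rude, d=slow, e=fast); the letter matrix is symmetric by construction.
The actor comparison is a paired t-test per feature over the 35 matched
action × condition cell means.

The canonical classifier input is the 17-feature set with established
condition effects (all features except POWmx, %POWmx, POSmx, %POSmx and
AEa); the screening of any concrete dataset derives its own significant
set, which the pipeline reports alongside.

**Factor analysis**: principal-axis factoring of the 17-feature
correlation matrix — initial communalities from squared multiple
correlations, iterated eigendecomposition of the reduced matrix until the
communalities converge (tol 1e−6), retention by the eigenvalue-one
criterion on the original correlation matrix, varimax rotation, components
ordered by explained variance and signed so the dominant loading is
positive. Each component's representative is its largest-|loading| feature
(features already taken by an earlier component are skipped, so the
representative set always has one feature per component).

## Classification

Features are scaled to [0, 1] per feature (min–max), with statistics fit
on the training partition only and no clipping of held-out rows. Min–max
is the scaling under which the power-of-two SVM grid (C, γ ∈ {2¹…2⁹}) is
meaningful: under z-scoring, 17-dimensional distances make
exp(−γ·d²) vanish for every γ ≥ 2 and the RBF SVM degenerates. z-scoring
remains available as an option.

* *Grid search* (SVMs): all (C, γ) pairs of consecutive powers of two in
  the configured exponent range, scored by mean inner-5-fold
  cross-validated support-weighted F1 with normalization refit per inner
  fold; ties break toward smaller C, then smaller γ.
* *k-NN*: k tuned over odd {1…15} by the same inner CV.
* *MLP*: one hidden layer of 32 units, fixed 300-epoch budget, fixed seed.
* *Random forest*: 300 trees by default, fixed seed. The full-scale
  leave-one-out run in `scripts/acceptance.py` uses 100 trees, which is
  past the accuracy plateau on 17 features and keeps 1,021 refits
  tractable on one CPU.

Leave-one-out refits normalization per fold; hyperparameters are tuned
once on the full table beforehand (one preliminary grid search).
Leave-one-gesture-type-out runs one fold per action type and re-tunes SVM
hyperparameters independently inside each fold's training partition.
Metrics are support-weighted (the classes are imbalanced) and reported in
percent; the leave-one-gesture-type-out report carries per-fold values
with across-fold mean and SD, and fold F-scores feed a one-way ANOVA +
Tukey HSD comparison across algorithms (or across action types). Every
report stores its pooled confusion matrix (rows = true, columns =
predicted, class order gentle/neutral/rude/slow/fast), from which all
metrics are recomputable — an internal-consistency check exercised in the
tests.

The chance level is the majority-class share (29.48% for the reference
campaign layout, conventionally printed as 29%). A methodological note on
permutation nulls: the leave-one-out accuracy of a *discriminative*
classifier under label permutation is systematically a few points *below*
that chance level — predictions scatter across the near-majority classes,
and permutation without replacement couples a held-out label negatively
with its neighborhood's labels. The null calibration test therefore uses a
maximally regularized SVM (C → 0), which provably degenerates to the
majority-class rule and reproduces the chance level exactly.

## The synthetic generator

Each trial is built from a deterministic base path plus stochastic
structure:

* **Base path**: a minimum-jerk polynomial
  x(τ) = x₀ + (x₁−x₀)(10τ³ − 15τ⁴ + 6τ⁵) between the common start point
  and the action's end point over the condition's nominal duration T
  (peak speed 15/8·D/T — a closed-form oracle used throughout the tests),
  plus a sin²(πτ) lateral bow of configurable height (sin² so position
  *and* velocity vanish at the phase boundaries; a plain sine injects a
  velocity discontinuity whose discrete acceleration spike scales
  incorrectly with T), plus, for path_scale > 1, a sharp Gaussian lateral
  excursion past mid-path that lengthens the path without moving the
  farthest-from-start point beyond the goal (the overshooting "rude"
  trajectory). A stationary pre-phase (0.25 s), a hold at the target
  (0.12 s), an unhurried return (1.15 T) and a post-phase (0.2 s) complete
  the trial, so segmentation is non-trivial and the global speed peak
  belongs to the GO-phase.
* **Heavy-tailed perturbations**: symmetric α-stable velocity draws at an
  8–12 Hz innovation rate (each draw held for fps/rate samples — discrete
  corrective sub-movements that survive the 10 Hz position filter), scaled,
  clipped at a physical 6 m/s cap, gated by the movement envelope,
  integrated to displacement, bridged to zero at each movement phase's
  boundaries (corrections are excursions, not net transport) and capped at
  5 cm per axis. Quantile-based tail estimation is insensitive to the
  clipping.
* **Jitter**: band-limited Gaussian positional noise at Optotrak-realistic
  sub-millimeter amplitudes, gated by the movement envelope
  (signal-dependent motor noise): autocorrelated noise at rest otherwise
  defeats any relative onset threshold.
* **Arm model**: the shoulder sways by a small gain times the wrist
  displacement; the elbow comes from two-link inverse kinematics
  (‖C2−C3‖ = L1, ‖C1−C2‖ = L2 to 1e−9 at every frame) with a fixed
  per-actor swivel angle; the chest is quasi-static. The deterministic
  base path must be strictly reachable (GeometryError otherwise, naming
  the offending sample); noise-driven excursions saturate radially at full
  extension/flexion — an actor cannot leave their own reach. The two
  default actors differ by ~7% in segment lengths and in shoulder
  position, which drives the reported actor effects on the angle features.
* **Campaign layout**: per-cell counts default to the reference campaign
  (1,021 trials; condition totals 294/142/301/143/141), trials alternate
  between actors and cycle through the −45°/0°/45° directions, and each
  trial gets a small deterministic-from-seed variation of duration (±8%)
  and end point (1 cm SD).

The default condition parameters (durations 2.2/1.5/1.1/0.7/0.65 s for
slow/gentle/neutral/rude/fast; rude with path_scale 1.18, tail index 1.1
and the strongest perturbations and jitter; slow with the weakest noise)
were calibrated once so the extracted features reproduce the qualitative
condition structure of the actor study: Vmx ordering
rude > fast > neutral > gentle > slow, Amx/Jmx/AL maximal for rude, S
minimal for rude, smoothness maximal for slow and higher for gentle than
for rude. These hold for any seed at ≥ 20 trials per condition.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: object contact and grasp aperture (transitive
and intransitive actions differ only by end-point geometry), inter-trial
correlations within a session (fatigue, drift), marker occlusion and
relabeling artifacts, actor-specific movement styles beyond arm geometry,
and any facial or vocal channel. Its class-conditional distributions are
cleaner than real actor recordings, so classification accuracies on it are
upper bounds, not forecasts; the meaningful claims are the orderings,
invariances and above-chance generalization gaps that the acceptance suite
checks.

## Determinism and problem sizes

One global seed fans out to per-stage seeds through SHA-256 (always below
2³¹); per-trial seeds derive linearly from the dataset seed. Identical
configuration and seed reproduce every numeric output byte-for-byte
(tested). The test suite works at 3–20 trials per cell (105–700 trials);
the acceptance script runs the full 1,021-trial campaign with
leave-one-out for SVM-RBF/k-NN/random-forest and
leave-one-gesture-type-out for all five algorithms, completing in a few
minutes on a single CPU. Single-feature rankings and subset evaluations
are exercised in the test suite at reduced size; at full scale their
17 × 1,021 random-forest refits dominate runtime without adding
information beyond the per-feature orderings already verified.
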