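# Methods

This note records the models, conventions and judgement calls behind
`occireach`, in the order data flows through the pipeline.

## Task and coordinate conventions

The task is a seated reach from a hanging-arm start pose (elbow fully
extended, forearm mid-position) to the centre of the external occipital
ridge, and back. Marker positions are in millimetres in a lab frame with
X anterior, Y left, Z up, sampled at 100 Hz.

All joint angles are defined against marker-built segment frames, never
against the lab axes, so every reported quantity is invariant to rigid
rotation/translation of the capture volume (tested):

* **trunk frame** — anterior axis from C7 → manubrium (CLAV), mediolateral
  axis from the two acromion markers, vertical by cross product;
* **upper-arm frame** — long axis acromion → olecranon, secondary axis from
  the radial/ulnar wrist-marker pair;
* **forearm frame** — long axis olecranon → wrist-pair midpoint.

**Shoulder decomposition.** The upper-arm direction in trunk coordinates is
decomposed into flexion (positive anterior) and abduction (positive away
from the trunk). Abduction is recovered with `atan2` and spans ±180°;
flexion is the arcsine-bounded middle angle (±90°). The order matters: an
occiput reach passes through ~115–155° of abduction, far beyond what a
decomposition with abduction as the bounded middle angle could represent,
while shoulder flexion in this task stays below ~80° and never approaches
the flexion singularity at ±90° (frames within 1° of it are flagged and
interpolated anyway). Elbow flexion is the angle between the prolongation
of the upper arm and the forearm axis — 0° at full extension, singularity
free. Axial rotation is carried by the segment frames but not reported.
The convention is pinned by round-trip tests: forward kinematics at a
random admissible triple followed by extraction reproduces the triple to
1e-6°.

## Synthetic cohort

The generator emulates the study design this pipeline targets: 10
participants × 2 sides × 5 trials. Each trial is rest (1.0 s) → outward
minimum-jerk movement of all three joint angles toward a sampled end pose →
0.5 s hold at the occiput → minimum-jerk return → rest (1.0 s). The hold
length is not a measured quantity; 0.5 s is a configurable default chosen
as a natural touch-and-return pause.

Per-trial parameters are drawn from truncated normal distributions
(anatomically bounded ranges; elbow flexion must stay below 150°):

| parameter | paralyzed | non-paralyzed | unit |
|---|---|---|---|
| outward motor time | 2.3 ± 0.7 [1.5, 4.4] | 1.3 ± 0.3 [0.9, 1.9] | s |
| return motor time  | 2.3 ± 0.7 [1.5, 4.2] | 1.5 ± 0.3 [1.0, 2.2] | s |
| peak shoulder flexion | 48.9 ± 15.4 | 42.3 ± 11.2 | deg |
| peak shoulder abduction | 117.5 ± 16.7 | 118.9 ± 6.2 | deg |
| peak elbow flexion | 134.2 ± 8.0 | 140.0 ± 6.1 | deg |
| trunk sway amplitude | 3.5 | 2.0 | mm |
| head sway amplitude | 6.0 | 5.0 | mm |
| marker noise SD | 0.2 | 0.2 | mm |

The side contrast encodes mild hemiparesis: the paralyzed limb is slower
and more variable, flexes the shoulder more and the elbow less. Postural
sway is a 0.3 Hz sinusoid with random phase and horizontal direction
applied to the manubrium and posterior-head markers — sway enters the
analysis only as a maximum-displacement covariate, so a low-frequency
oscillation of matching magnitude is sufficient. Arm geometry is scaled
from each participant's sampled height with standard anthropometric
ratios. All sampling is driven by a single seed; identical seeds give
bitwise-identical recordings.

**What the generator does not emulate.** Minimum-jerk joints give smooth,
single-peaked velocity profiles, so synthetic peak angular velocities
scale with amplitude/duration and come out *higher* on the fast
non-paralyzed side. Real paretic movement is segmented and jerky, which
can invert that ordering; the occiput target is an end pose in joint
space, not a contact event; and the trunk is rigid apart from marker
sway. Tests passing on synthetic cohorts therefore validate the
measurement and inference chain (timing, angles, cutoff recovery), not
velocity-direction claims about real patients.

## Segmentation

A phase onset is the first frame beginning a ≥0.2 s run with 3-D
index-finger speed above ε; the end is the first subsequent frame
beginning a ≥0.2 s run at or below ε. Applied twice, this yields the
outward and return phases separated by the hold. "The marker changed /
held the same value continuously" is only meaningful relative to a noise
floor, so ε is explicit and configurable.

Two regimes matter:

* **noisy data** (default, ε = 10 mm/s, 6 Hz zero-phase Butterworth order
  4 before everything): the filtered speed noise floor at 0.2 mm marker
  noise peaks around 6 mm/s, and the sustained-run end rule breaks if a
  single noise frame pierces the threshold inside every candidate quiet
  window — ε must clear the floor with a safety factor (~4× here).
* **noiseless synthetic data** (`ExtractionConfig.for_noiseless()`: no
  filter, ε = 0.1 mm/s): the filter is pointless without noise and its
  time-domain ripple (~1 mm/s) would dominate near the movement edges;
  with a tiny ε the configured duration is recovered within 2 frames.

The threshold rule truncates the slow minimum-jerk tails, biasing motor
time low by ~0.03–0.1 s at the default ε — identical in kind for both
sides, so side contrasts and cutoffs are unaffected (verified by the
recovery tests: the outward cutoff falls strictly between the two
configured side means in ≥95% of replicates).

Peak = maximum (not maximum magnitude) for both angles and angular
velocities, so lowering-phase velocities may legitimately be small or
negative. Angular velocity is a per-frame central difference (one-sided at
the ends); a single displacement/duration quotient cannot produce a
within-phase peak and is not used. Marker displacement is the maximum
Euclidean excursion from the onset position within the phase.

## Statistics

Trials are pooled as observations (they are never averaged within a
participant). The side comparison is a multivariate linear model of the 7
features on side plus covariates (sex, age, BMI, months post onset, and
the two displacement maxima): Wilks' Λ = det(E)/det(E+H) with the exact
one-df F transform F = (1−Λ)/Λ · (v−p+1)/p. With 100 trials, 6 covariates
and 7 features this yields F(7, 86) — the df structure of a pooled-trial
within-subject design. Per-feature follow-ups report F and classical
η² = SS_effect/SS_total from the same adjusted model. An independent
cross-check against `statsmodels` MANOVA is part of the test suite.
Covariates that are constant or collinear (inevitable with very few
participants, where participant-level covariates span fewer dimensions
than their count) are dropped with a warning.

Features failing Shapiro–Wilk at α = 0.05 are additionally compared with
Kruskal–Wallis. Logistic fits are IRLS (statsmodels GLM-Binomial) with the
same covariates; reported per feature: deviance, AIC = deviance + 2·k,
McFadden R² = 1 − ℓ/ℓ₀, overall X² = null − residual deviance with df =
number of non-intercept terms, and Wald z for the feature term.
Quasi-separation is flagged rather than raised — with a strongly
discriminating feature it is the expected outcome, not an error.

ROC analysis sweeps the observed values as thresholds with the fixed
direction *score ≥ threshold ⇒ paralyzed*. The cutoff maximizes Youden's
J (ties broken toward the lowest threshold); AUC is the trapezoid over the
fixed-direction curve, equal to the Mann–Whitney statistic with half-credit
ties (tested), and is reported below 0.5 when the feature discriminates in
the opposite direction. Correlated AUCs are compared with the DeLong
placement-value test; its single-AUC standard error is validated against a
bootstrap within 20%.

The sample-size routine enumerates n ascending; for each n it takes the
smallest critical count c with exact one-sided size P(X ≥ c | p₀) ≤ α and
returns the first n with exact power P(X ≥ c | p₀+g) at target. One-sided
testing is an assumption, recorded as such: with p₀ = 0.5, g = 0.4,
α = 0.05, power 0.8 it uniquely yields n = 8 (c = 7, size 0.035, power
0.813), whereas a two-sided allocation would not reach the target at n = 8.

## Clustering

Pattern identification runs separately for the four conditions
(side × phase) on frame-level rows: every `stride`-th frame (default 10)
within a phase contributes (motor time, shoulder flexion, shoulder
abduction, elbow flexion), so clusters describe joint-trajectory shapes
conditioned on movement speed, and the per-condition N is in the
hundreds-to-thousands. The construction is configurable; trial-level rows
are equally valid input.

The forest is the canonical unsupervised construction: a synthetic
contrast class from independent per-column permutation of the z-scored
features, 500 trees (mtry = ⌈√p⌉, min leaf 5) trained real-vs-synthetic
with max-Gini-information-gain splits, and proximity = fraction of trees
in which two real rows share a terminal leaf. Tree growing is delegated to
scikit-learn's `RandomForestClassifier`, which implements exactly this
split rule; the Gini/IG primitives are also exposed directly and
property-tested (IG ≥ 0 always, = 0 iff the children mirror the parent's
class proportions).

Observations are partitioned by k-medoids on √(1 − proximity): exact
enumeration of medoid sets for tiny instances (verified against brute
force), seeded PAM with restarts otherwise. For the elbow curve, each k's
proximity solution competes with a split-refinement of the previous
solution, keeping the reported WSS curve non-increasing even when PAM
lands in a local optimum. The knee is the k maximizing the second forward
difference of WSS (k = 1 anchors the curve at the total SS); AIC = WSS +
2·k·p and BIC = WSS + ln(n)·k·p are reported alongside as simple
penalized-WSS indices (they are not comparable across software using
likelihood-based definitions). A knee prominence below 25% of the total SS
sets a low-confidence flag — blob-recovery experiments separate planted
3/4-cluster structure (prominence ≳ 0.5) from a single Gaussian blob
(≲ 0.1). Cluster profiles are per-cluster, per-variable means and spreads
of globally z-scored features, with R² = 1 − WSS/TSS.

When choosing leaf sizes for proximity clustering, note that leaves much
smaller than the expected cluster granularity fragment the proximity
blocks and blur the partition; the blob-recovery tests use min leaf ≈
0.4 × cluster size.

## Numerical and degenerate-input choices

* Constant feature columns are detected by exact peak-to-peak zero (a
  floating-point `std` of a constant column is ~1e-16, not 0) and raise a
  degenerate-forest error.
* Segment frames are Gram–Schmidt orthonormalized per frame with a 1e-9
  residual bound; collinear or coincident markers raise an error naming
  the first bad frame.
* TRC files are normalized to millimetres on read (mm/cm/m accepted);
  parse errors name file and line. Batches must share one sampling rate.
* Determinism: every stochastic stage (simulation, forest, permutations,
  PAM restarts) derives from an explicit seed; the pipeline report is
  bit-reproducible for a fixed config (tested).
* Problem sizes in the shipped tests and the acceptance script (default
  cohort 10×2×5, 30–100 replicate cohorts, 60–500 trees, frame stride 10)
  were chosen to exercise the full chain at the study's own design size
  while keeping a complete run in the low minutes on one CPU.

## Known limitations

* The simulator's velocity limitations above; no wrist/finger kinematics,
  no marker dropout or gap-filling beyond what filtering absorbs.
* The MANCOVA treats pooled trials as independent observations; a
  mixed-effects treatment of trial nesting is out of scope.
* No multiple-testing correction across features, and no confidence
  intervals for cutoffs.
* AIC/BIC for cluster solutions are penalized-WSS conveniences, not
  likelihoods.
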