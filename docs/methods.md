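# Methods

`streamwaves` models how a rapid stream of oriented stimuli can be
simultaneously represented in multichannel brain recordings, and provides
the analysis chain used to diagnose the underlying dynamics: linear
circular decoding, temporal generalization (TG), encoding, across-subject
nonparametric statistics, and a systematic search over hierarchical
dynamical systems.

## Hierarchical dynamical systems

A network is a stack of `n_levels` identical levels, each containing one
*observable* unit `x` (visible to sensors) and one *hidden* unit `y`
(invisible: e.g. adaptation currents, or interneuron potentials whose
fields cancel at a distance).  Units are connected by up to 12
*connection types* — (source role, target role, level offset) with offset
−1/0/+1 for feedback/recurrent/feedforward — each applying with a single
weight at every level.  All units update synchronously:

    z(t+1) = f_z( Σ_u  w(z,u) · u(t) )

with `f` one of four monotone activations (identity, relu, and their
saturating versions).  The external step input acts as a virtual level 0
whose `x` and `y` units both carry the drive; it enters level 1 through
whatever feedforward weights the network has.  We read the phrase
"connected following the feedforward weights" inclusively (both virtual
roles): restricting the input to the virtual `x` unit makes it impossible
for any network with epiphenomenal observables to receive input at all,
and such networks are one of the two search outcomes (below).

Numerical choices: zero initial state (no baseline activity before
stimulation); synchronous updates from the time-`t` snapshot; any sample
that is non-finite or exceeds 10⁶ in magnitude marks the simulation
unstable, and unstable models are invalid everywhere downstream (a
necessary guard: weights of magnitude 1 with positive recurrence diverge
under sustained input).

## Traveling-wave validity criteria

A model is *valid* when every level's observable unit shows the
traveling-wave phenomenology of evoked responses under a step input
(samples 30–60 of 120, 10 levels):

1. **Onset** — the maximum `M` (first sample `t_M` attaining it) is
   positive, occurs before the input ends, and the series is
   non-decreasing from input onset to `t_M` (tolerance 1e-9 on every
   step).
2. **Offset** — the minimum `m` (first sample `t_m`) is negative, the
   tail from `t_m` onward is non-decreasing, and the final sample lies
   strictly above `m`.  The recovery clause implements "relaxes toward
   zero": without it, a unit frozen forever at a negative value counts as
   an offset response.
3. **Increasing maintenance** — a half-life `t_h` (samples from `t_M`
   until the activity first reaches `M/2`, no interpolation) is defined
   at every level, requires a monotone decay between `t_M` and `t_m`, and
   strictly increases across levels.  The strict comparison is essential:
   a non-strict one admits pure delay lines, whose constant-width waves
   are exactly the phenomenology these criteria exist to exclude.

Hidden units are unconstrained — they are, by construction, not visible
to the sensors.

These three rules contain genuine interpretation room (tie-breaks at
plateaus, strictness, what "toward zero" means).  We resolved each by
simulation: among the 24 interpretation variants we evaluated
(first/last-attainment tie-breaks × strict/non-strict half-life ×
tail-recovery on/off × input-coupling role sets), the combination
documented here is the only one under which the minimal-complexity
search on the reduced grid reproduces the expected outcome — no valid
model below four connections, exactly two valid architectures at four,
exactly one of them with leaf observables.

## Architecture search

An *architecture* is the set of models sharing the signs of all 12
connection weights; its complexity is the number of present connections.
The search walks complexity levels k = 1, 2, …, evaluating every model
(k-subset of connection types × one grid weight per present connection ×
4 × 4 activation pairs) and stops at the first k with a valid model,
after finishing that level.  Models whose connection subset contains no
feedforward type able to carry the input provably remain at zero and are
counted without being simulated.  Simulation is vectorized across models
(thousands of weight vectors advance in lock-step per time sample); a
property test pins the batch path to the single-model simulator exactly,
and the single-model simulator to an independently written scalar-loop
reference.

With the reduced grid {±0.5, ±1} the search evaluates 2,270,464 models
(closed form Σₖ C(12,k)·4ᵏ·16 for k ≤ 4) in a few minutes on one core
and returns: no valid model at k ≤ 3; at k = 4 exactly two
architectures.  One is a hierarchy of negative feedback loops whose
hidden units maintain and propagate the content while the observable
units read out level differences — transient onset and offset waves with
strictly widening half-lives — and whose `x` units are leaf nodes.  The
other couples an observable chain (self-recurrence + feedforward) to a
hidden feedforward chain delivering delayed negative feedback.  The full
21-value grid of the original design is supported but not the default;
the combinatorial quantities it implies (21¹²·16 > 10¹⁷ models overall,
~1.57 × 10⁹ through complexity four) are reported as closed forms.

## Synthetic streams

The generator emulates the study design: per subject, 672 trials × 8
Gabor patches flashed every 250 ms (SOA 62.5 samples at 250 Hz, realized
as alternating 62/63-sample gaps so the long-run rate is exact), masks
ignored, 5376 oriented stimuli per subject, 15 subjects by default.
Orientations θ are i.i.d. uniform on [0, π).  Analyses use α = 2θ — the
standard bijection of an orientation (period π) onto the full circle,
needed for sine/cosine regression — and δ, the circular orientation
distance to the preceding item (range [0, π/2], undefined at position 1,
uniform by construction and asymptotically uncorrelated with sin α and
cos α).

Each stimulus drives the default network (the leaf-architecture
updating hierarchy found by the search, weights −0.5/0.5/1.0/1.0,
saturating-linear observables) with a 58-sample (233 ms) step.  The
per-level observable profiles are scaled by the three feature values
(mean-centred δ — zero at position 1 — sin α, cos α), superposed
additively across stimuli, projected to 32 sensors through a
subject-specific standard-normal matrix over (level × feature)
components, and summed with i.i.d. Gaussian sensor noise (SD 1).
Feature-scaled superposition is a modelling choice, not a property of
the network (which need not be linear); it is what makes the features
linearly decodable by construction, and is validated by the decoding
tests.  The generator omits everything else about real EEG — no 1/f
noise, no artifacts, no head geometry, no channel covariance — so
passing tests demonstrate the correctness and calibration of the
analysis chain, not its performance on real recordings.

Epochs are cut at (−0.25, 1.0) s around each onset (313 samples,
inclusive endpoints) with no baseline correction; sequence-locked epochs
at (−0.25, 2.75) s cover all eight items.

## Decoding, scoring, patterns

Per time sample, the spatial filter is the ordinary least-squares map
`W_t = (X_t'X_t)⁻¹X_t'Y` from sensors to the three targets (δ, sin α,
cos α); rank-deficient problems (e.g. noiseless synthetic sensors of
rank 3) fall back to the minimum-norm solution with a warning.  Rows
with undefined δ are dropped from the joint fit; angle scoring still
uses every epoch.  The predicted angle is `arctan2(ŝin, ĉos)`
(`arctan2(0,0)` = 0 by convention); the angle score is π/2 minus the
mean absolute circular error (π/2 perfect, 0 chance, −π/2 opposite), and
δ is scored with Pearson's r on δ-defined rows.

Cross-validation is grouped by trial with a seeded shuffle: the eight
stimuli of a sequence share temporally overlapping responses, so they
never span the train/test split.  K = 5 folds by default.  Out-of-fold
predictions are pooled across folds and scored once per time sample; the
TG engine accumulates per-trial score sums (angle) and sufficient
statistics (δ) so its diagonal equals the plain decoding timecourse to
floating-point reassociation error.

Filters are interpreted through the Haufe transform
`P = Σ_X W Σ_Ŷ⁻¹` with uncentred second-moment matrices, which for OLS
filters equals the coefficients of regressing the sensors on the
predicted targets; when the fit is exact (noiseless synthetic data) this
coincides with the encoding coefficients `X'Y(Y'Y)⁻¹` to machine
precision, and the acceptance suite verifies that identity on every
fold.  The encoding analysis is the mirror regression (features →
voltage) per channel and time sample, summarized by cross-validated
Pearson r.

## Temporal generalization diagnostics

Each decoder trained at time t is applied at every testing time t′; one
fold partition is shared across all training times so the matrix is
internally consistent and exactly reproducible from its seed.
"Significant generalization duration" is operationalized per training
time as the extent of the cluster-significant (p < 0.05) positive
testing-time cluster containing the diagonal sample, via the sign-flip
cluster test below.  Because any finite cascade truncates the band at
stimulus onset (making the *full* width grow trivially with training
time for every network), the shape diagnostic uses the *forward* span —
diagonal to the band's future edge: it stays at the stimulus duration
for a pure feedforward chain and grows with training time for the
updating hierarchy.  The diagnostics are computed on a 10-subject,
36-trial stack at noise SD 1; the feedforward reference chain is 100
levels deep so its steady regime covers the measured window.  The
diagonal-vs-reversal comparison contrasts score(t, t) with the
sign-reversed score at one SOA lag, −score(t, t + 0.25 s), returning
their difference (positive when the diagonal decoder wins).

## Group statistics

Second-level inference across subjects uses (1) the two-tailed Wilcoxon
signed-rank test for single estimates and (2) a cluster-based sign-flip
permutation test for repeated measurements.  The cluster test forms
one-sample t statistics per point, thresholds two-tailed at the
α = 0.05 t quantile (exposed as a parameter), clusters by 1-D contiguity
or 4-connected 2-D adjacency, uses cluster mass (sum of t), and builds
the null from random whole-subject sign flips; each cluster's two-tailed
family-wise p is `(1 + #{null max |mass| ≥ |mass|})/(1 + n_perm)`
(default n_perm 1024, seeded).  Degenerate zero-variance points are
excluded with a warning.  A unit test pins cluster identification and
masses to an independent implementation, and the acceptance suite
verifies the empirical family-wise error over 1000 null simulations
falls in [0.03, 0.07].  Note the sign-flip null has resolution 2^(1−S)
for S subjects, so groups below ~8 cannot reach p < 0.05 two-tailed.

## Problem sizes and reproducibility

Default study-scale parameters (672 trials, 15 subjects) are kept for
the design-level quantities; the simulation-heavy analyses in the test
suite and the acceptance script run on reduced sizes chosen so each
property is still unambiguous: 24–48 trials and 1–10 subjects for
decoding/TG fixtures, the {±0.5, ±1} weight grid for the search, 199–255
permutations inside calibration loops.  Every random draw consumes a
named seed (design, per-subject tuning/noise, folds, permutations), and
pipeline runs record seeds and artifact hashes in a manifest so a run is
reproducible bit for bit.

## Known limitations

- The validity criteria contain interpretation room (documented above);
  other readings yield three or more winning architectures, or a minimal
  complexity of three.
- The search's non-leaf winner keeps maintenance in its observable
  chain; with sensors seeing saturated plateau activity it would not
  by itself reproduce amplitude-coded features.  The generator therefore
  uses the leaf-architecture exemplar, whose hidden units maintain
  content while observables mark updates.
- The synthetic noise model (white Gaussian, unit SD) makes decoding far
  easier than real EEG at matched trial counts; effect sizes measured
  here do not transfer to real data.
- Architectures are restricted to one-level-offset connectivity and one
  x/y pair per level; no skip or cross-level connections, no learned
  weights.
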