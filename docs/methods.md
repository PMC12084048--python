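# Methods

## The model

A MOSR classifier is an expression tree over named patient features. The
raw tree output is mapped through a logistic link, `p = σ(tree(x))`, with
probabilities clipped into `[1e-12, 1 − 1e-12]`; the decision threshold for
confusion-based metrics is 0.5 everywhere, for comparability across arms.
The function set `{+, −, ×, ÷, log, exp, √, neg}` is protected (`a/0 = 1`,
`log(x≤0) = 0`, `√x = √|x|`, `exp` input clamped to ±50) so that evaluation
is total on finite inputs and fitness stays finite throughout evolution;
these are standard genetic-programming conventions. Constants are ephemeral,
drawn uniformly from [−2, 2] at node creation and refined by a small
Gaussian perturbation operator during mutation — there is no gradient
fitting, which keeps the engine self-contained.

## The search

Two objectives are minimized jointly:

* `BCE(p, y) = −(1/n) Σ [y ln p + (1−y) ln(1−p)]`
* `pAIC = 2k + 2n·BCE`, i.e. `2k − 2 ln L` under the Bernoulli likelihood,
  with `k` the tree's node count.

The node count is the natural complexity measure for a formula tree; the
`pAIC` form is deliberately simple, documented here, and swappable through
the engine's scoring function if a different penalty is wanted. Selection is
NSGA-II: fast non-dominated sorting plus crowding distance, binary
tournaments, subtree crossover (rate 0.8) and a three-way mutation mixture
(subtree replacement / point change / constant perturbation, total rate
0.2). Initialization is ramped half-and-half at depths 2–5. Each generation
a small fraction (5%) of the offspring slots are filled with fresh random
trees — random immigrants — which guards against premature convergence to a
single-feature formula. Depth and node-count caps (defaults 8 and 48) are
enforced after every genetic operation by rejecting the child in favour of
a parent copy.

An external archive keeps every non-dominated `(BCE, pAIC)` individual
encountered; archive-best BCE is therefore non-increasing by construction
(the elitism invariant checked in the tests). The returned **champion** is
the archive member with the best binary cross-entropy on a validation
partition (by default an internal stratified 90:10 split of the training
data), with ties broken by lower pAIC, then fewer nodes, then earlier
generation. Validation-BCE champion selection is this package's documented
choice among the defensible alternatives (a Pareto-knee rule is the obvious
other candidate).

Default search size is a population of 300 for 500 generations. The tests
and the acceptance script use scaled profiles (populations 40–100,
generations 15–100, cohorts of 250–1,190) chosen so the full suite runs in
a few minutes on one CPU; the qualitative behaviour they probe does not
depend on the full-size profile.

## CPET processing

Recordings are 1-Hz multichannel series with rest / ramp / peak / recovery
phases (0-based sample indexing; phase windows half-open `[start, end)`).

* **Median filter**: running median, default window 5 s, edges handled by
  symmetrically shrinking the window. Five seconds suppresses
  breath-by-breath spikes at 1 Hz while leaving ramp geometry intact.
* **Downsampling**: linear interpolation at `target_len` equally spaced
  points — exact on straight segments, endpoint- and shape-preserving, so a
  V-slope breakpoint's relative position survives resampling to 1000/500/100
  points (verified to 2%).
* **Anaerobic threshold (V-slope)**: two independent least-squares lines fit
  to V̇CO₂ against V̇O₂ over the ramp, split at every admissible breakpoint
  (each segment ≥ 60 samples by default); the split with minimal total RSS
  wins subject to slope₂ > slope₁, with ties resolved to the earliest
  breakpoint at numerical precision. The result is *indeterminate* when a
  single line already fits to numerical precision or when the best split
  improves RSS by less than 5% — the detector names a margin because a
  breakpoint can always reduce RSS slightly on noise alone.
  Ventilatory-equivalent and end-tidal criteria are corroborative
  diagnostics in this design, not part of the primary detector, since no
  arbitration rule between the three criteria is standard.
* **V̇O₂ peak**: highest 30-sample rolling mean within the final 60 s of the
  ramp (the literal mean of the last 30 s is available via `mode="last"`;
  the maximized form dominates it and is robust to a terminal drop-off).
* **TS feature matrix**: channels downsampled and concatenated
  channel-major; column `c__j` is `downsample(channel c)[j]`.

## Synthetic cohort

The generator emulates the statistical structure of a ~1,190-patient
preoperative cohort; it is a model of that structure, not of any real
patients. Each patient carries three latents: fitness `z`, clinical frailty
`c`, and recovery kinetics `w` (all standard normal). Risk is the linear
predictor

```
eta = −crf_effect·z + clinical_effect·c − ts_effect·w + noise_sd·ε
```

Nine POMS domains are conditionally independent Bernoullis given `eta`
(logit offsets ordered from common pulmonary/infectious domains to rare
ones); the day-3 morbidity class is 1 when ≥ 2 non-excluded domains are
positive. The shared domain intercept is calibrated by bisection against
the exact Poisson-binomial probability of `count ≥ 2`, so expected
prevalence equals the configured target (53.2% by default) for any effect
sizes. Day-5/7 assessments reuse a correlated late-risk latent (ρ = 0.8).
Which domains count as routine care (and are excluded) is configuration,
not hard-coded, since exclusions are surgery-specific in practice.

CRF features load on `z` in four correlated blocks (rest / AT / peak /
slopes; within-block correlation ≈ 0.4–0.8) with means and scales at
clinically typical values (V̇O₂/kg at AT centred at 10.6 ml/kg/min, peak at
16.9, etc.); the tabular values carry measurement noise
(`measurement_sd`, default 0.35 of a feature's scale). Clinical features
(age, BMI, ASA, DASI, PPOSSUM scores, comorbidities, labs, surgery type and
severity) load weakly on `c`, making the clinical arm genuinely less
informative than the fitness arm — the construction that yields the
fitness > clinical ordering for every model class.

Defaults were fixed once: `crf_effect = 3.0`, `ts_effect = 0.6`,
`clinical_effect = 0.45`, `noise_sd = 0.55`, chosen so the cohort-level
|Pearson r| between V̇O₂/kg at AT and the day-3 POMS positive count is
≈ 0.69 (mean 0.684 over 8 seeds at n = 1190).

Waveforms are built for the time-series subset from the *noise-free* latent
targets: rest plateau, linear ramp crossing the planted threshold at an
exact sample, a 40 s plateau at the planted peak (so the 30-s peak
extractor recovers the planted value exactly), and exponential recovery
whose time constant depends on `z` and on the waveform-only latent `w`.
V̇CO₂ follows V-slope geometry (slope 0.85 below the threshold sample, 1.15
above). Because `w` enters the risk but is visible only in recovery
kinetics, a "waveform-rich" configuration (larger `ts_effect`) makes the
time-series arm strictly more informative than the scalar subset arm — the
construction behind the TS ≥ subset ordering. With `crf_effect` and
`clinical_effect` at zero the outcome is independent of all features.

What the generator does **not** emulate: real demographic marginals beyond
rough medians, missing data, inter-site calibration drift, breath-by-breath
noise structure, or surgery-specific POMS exclusion patterns. Passing tests
therefore demonstrate protocol correctness and recoverability of planted
structure — not clinical performance on real cohorts.

## Measurement protocol

Continuous features are min–max scaled to [0, 1] with parameters learned on
the training partition only and reapplied unchanged to the test partition;
out-of-range test values are *not* clipped (they map outside [0, 1]) but
are counted and warned about. Binary events stay {0, 1}; non-ordinal
categoricals (sex, surgery type) are one-hot encoded, with unseen
categories mapping to all-zero indicators. Partition objects carry a role
tag and any fit/selection step on a `test`-tagged partition raises — the
no-leakage contract is mechanical, not conventional.

Stratified splits allocate `round(ratio·n)` rows (half-up) with per-class
quotas by largest remainder, reproducing the protocol's printed sizes
(1190 → 952/238 at 80:20; 952 → 857/95 at 90:10); the repeated test
evaluation subsamples `floor(0.9·238) = 214` rows per run without
replacement. Metrics are reported as mean with a Student-t 95% CI over the
10 run means (the CI method is this package's choice; with subsampling
disabled the interval width is exactly zero). Metrics with zero
denominators in a run are flagged undefined and excluded from that metric's
mean with the exclusion count logged. AUC is tie-corrected pairwise
concordance computed via mid-ranks. Grid search scores each configuration
by mean validation AUC over stratified folds, ties going to the earlier
(simpler) configuration in the declared grid order, then refits the winner
on the full training partition (the assumed standard practice).

## Attribution

Shapley values are computed model-agnostically on the probability scale
(clinically readable units): coalition value `v(S)` is the mean model
output with features in `S` from the explained row and the rest substituted
from a background sample (marginal/interventional substitution, the
standard KernelSHAP assumption; a 100-row stratified training sample is the
default background). Exact enumeration over all `2^n` coalitions is used
automatically for ≤ 12 features; otherwise permutation sampling, whose
estimator SD shrinks as `1/√permutations`. Efficiency, symmetry and dummy
axioms hold exactly on the enumeration path and within Monte-Carlo
tolerance otherwise.

## Clinical score baselines

Scores are consumed as numeric inputs, never recomputed from questionnaire
items. Directions are clinically forced: PPOSSUM predicted risk ≥ 0.30 →
high risk; ASA ≥ 2 → high risk (inclusive boundary by default, configurable,
since "a threshold of 2" is ambiguous about the boundary grade); DASI < 34 →
high risk (lower functional capacity is worse); anaerobic threshold
< 11 ml O₂/kg/min → high risk.

## Numerical choices and degenerate inputs

* Protected-operator conventions as above; division tests `b == 0` exactly.
* V-slope tie-break: earliest breakpoint among RSS ties at relative
  precision 1e-9 (the junction sample of a noiseless piecewise-linear curve
  belongs to both segments, so a strict-improvement rule without a
  tolerance would be decided by rounding noise).
* Zero-variance features min-max scale by span 1 (constant 0 output).
* Degenerate (single-class) training outcomes are rejected by the engine;
  single-class subsamples in evaluation yield flagged-undefined metrics
  rather than errors.
* All randomness flows through injected `numpy` generators; experiment
  stages derive their seeds deterministically from a master seed (CRC-based,
  < 2^31).

## Known limitations

* The pAIC parameter count `k` equates each tree node with one parameter;
  operators and constants are weighted equally.
* The champion rule optimizes validation BCE, not AUC; on very small
  validation partitions (tens of rows) champion selection is noisy.
* The time-series arm flattens waveforms to independent columns; no
  convolutional or warping-invariant structure is exploited.
* Shapley exact enumeration is exponential; beyond 12 features only the
  sampling estimator is practical.
* The 18-vs-15 feature discrepancy in time-series experiment descriptions
  (three non-series static columns) is handled by an optional
  `static_columns` argument rather than a fixed identity.
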