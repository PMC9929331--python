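# Methods

## Signal model and preprocessing

A recording is one participant × script conductance trace at 40 Hz with
marker indices delimiting a pre-script pause (≥ 5 s), a listening span and an
imagery window (~60 s). Markers are part of the input; nothing is inferred
from the signal itself.

The baseline `pSCL` is the arithmetic mean of the **final 5 s** of the pause
(200 samples at 40 Hz). The normalized signal is the percent change
`nSCL = 100·(SCL − pSCL)/pSCL`, which makes the analysis scale-free:
multiplying a whole recording by any positive constant leaves nSCL unchanged.
Only the imagery window is summarized (the listening span is excluded); its
mean and variance form the script summary. Variance uses the population
convention (divide by n) by default; `ddof=1` is available.

Within each participant, a script is excluded when **either** its mean
**or** its variance falls outside the Tukey fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` ("and/or" is implemented as OR). Quartiles
use linear interpolation (`numpy.percentile` default); the convention is
configurable because with only seven scripts per participant the fences are
sensitive to it. Fewer than four values give no meaningful fence: all are
retained with a logged warning; constant values collapse the fences onto the
value and everything is retained. The squats test scene participates in the
cleaning diagnostics and in the power analysis but never in mSCL.

`mSCL` is the unweighted mean of the retained non-test script means.
Participants with no retained non-test script are dropped with a warning.
Tercile thresholds on mSCL are the 33.3rd/66.7th percentiles; values strictly
above the upper threshold are "high", strictly below the lower "low",
boundaries "moderate".

## Psychological predictors

Subscales are scored as item means (a sum is equivalent up to the affine
normalization): general imagery (6 items, 1–5), neuroticism (7-point items),
and the three sport-anxiety subscales on their 4-point response scale.
Scores are cleaned with the same IQR rule and mapped onto [−1, 1] by
`x ↦ 2(x − min)/(max − min) − 1`. The default bounds are the theoretical
instrument range, which is reproducible across samples; normalizing by the
observed range is available as an option. Missing items are an error —
imputation is out of scope.

## Power analysis

The per-participant contrast (test-scene mean nSCL minus the mean of the
retained imagery-scene means) yields a mean difference Δ and SD, hence
`d = Δ/SD`. Achieved power of the one-sample t test is computed exactly: the
t statistic under the alternative follows a noncentral t distribution with
`n − 1` degrees of freedom and noncentrality `d·√n`, and power is its mass in
the rejection region. Two-sided testing at α = 0.05 with configurable n and
sidedness is the default. A vectorized Monte-Carlo estimator (seeded;
≥ 10,000 replicates) serves as an independent check; analytic and simulated
power agree within one percentage point at 100k replicates.

For the worked contrast Δ = 0.023, SD = 0.03 (d = 0.77) and n = 30, the
two-sided analytic power is ≈ 98.2%. No standard configuration of this test
(sidedness, paired vs one-sample, plausible n after exclusions) yields the
sometimes-quoted ≈ 91% for these inputs, so the package reports only what
the stated test computes; n, α and sidedness are all adjustable if a
different configuration is intended.

## Regression model

Each of three models predicts mSCL from a predictor triplet (all include
general imagery and neuroticism; the third slot is somatic anxiety,
concentration disruption or worry). Using three 3-predictor models rather
than one 5-predictor model limits overfitting at n ≈ 30 and keeps the
response surfaces directly visualizable.

The network is fixed at 3–7–9–1 fully connected neurons. Hidden layers use
tanh; the **output is linear**, because the outcome spans roughly −9 to +6
percent and a bounded output activation could not represent it. Weights are
Glorot-uniform initialized from a seed; biases start at zero.

Training is full-batch Adam (step 1e-3, decays 0.9/0.999, ε = 1e-8) on the
mean-squared error — the same minimizer as RMSE with cleaner gradients —
with early stopping: after `patience` (default 100) epochs without a strict
improvement in validation RMSE, training stops and the best-validation
weights are restored; the cap is 5,000 epochs. Backpropagation is analytic
and is verified against central finite differences (relative error < 1e-6).

The data are split into k = 10 folds (sizes differing by at most one; at
n = 30 each fold validates on 3 and trains on 27). Each fold trains an
independent network from its own derived seed. The ensemble prediction is
the convex combination of fold outputs with weights
`w_i = (1/L_i) / Σ_j (1/L_j)`, where `L_i` is fold i's validation RMSE (an
epsilon floor guards zero losses). Which loss feeds the weights is
ambiguous in principle — validation-fold RMSE is the default; whole-dataset
RMSE is available via `weight_loss="full"`. All training is bit-reproducible
given (data, config, seed), and models serialize to JSON exactly.

Reported metrics are RMSE and the standard coefficient of determination
`R² = 1 − SSres/SStot`, which by construction cannot exceed 1.

## Interpretation

*Surfaces.* The ensemble is evaluated on a regular grid over two normalized
predictors with the third pinned at each of its tercile midpoints.
Midpoints default to the within-tercile medians (16.67th/50th/83.33rd
percentiles); an "arithmetic middle of the tercile boundaries" convention is
selectable.

*Impact matrices.* The predictor cube is partitioned into 3³ = 27 boxes by
each predictor's observed tercile boundaries. Each box is probed with a
dense interior grid of predictions, every prediction is classified against
the mSCL tercile thresholds, and the box is labelled with the majority
class; ties break toward the class of the box-mean prediction. This is an
explicit operationalization of what is otherwise a qualitative reading of
response-surface plots, and outputs are labelled as such: the matrix depends
on the fitted ensemble and the chosen grid.

*Importance.* Permutation importance is the increase in ensemble RMSE when
one predictor's column is shuffled, averaged over seeded repetitions,
floored at zero and normalized to percentages summing to 100. The
connection-weights alternative chains row-normalized absolute weight
matrices from the output back through both hidden layers (a two-hidden-layer
extension of Garson's algorithm), combined across folds by the ensemble
weights. Permutation is the headline method; the two need not agree in
detail — permutation reflects behaviour on the data distribution,
connection weights reflect wiring — and both are reported.

## Synthetic cohorts

The generator emulates the study's situation: n participants × 7 scripts
(one test scene + six imagery scenes). Trait scores are drawn uniformly over
the instrument ranges (the real trait distribution is unknown; uniform
exercises the full normalized cube). A configurable surface — by default
additive in all five traits with one neuroticism × somatic-anxiety
interaction, signs matching arousal rising with neuroticism, somatic anxiety
and imagery use — gives each participant a true mean percent change;
per-scene values add jitter (SD 1%), and the squats scene gets its own
planted change (default +2%).

Traces are synthesized as: tonic baseline (log-normal, median 5 μS, log-SD
0.4, so conductance stays positive) held through pause (5 s) and listening
(30 s), an imagery window (60 s) whose pre-noise mean is
`baseline × (1 + planted/100)`, plus per-script linear drift (slope SD
0.001 μS/s) and white measurement noise (SD 0.05 μS). The drift default
keeps the baseline-to-imagery contamination near 1% of baseline — large
enough to exercise the normalization, small enough that participant-level
recovery of the planted surface stays faithful (correlation > 0.95), which
is the regime the analysis assumes. Outlier scripts are planted
deterministically (round(fraction × 7) per participant, seeded choice) by
shifting the imagery-window mean, or its variance via a zero-mean square
wave that leaves the mean untouched.

With noise, jitter and drift all zero the preprocessing recovers the planted
per-script changes exactly (float round-off only), giving the pipeline an
exact end-to-end oracle. The generator does **not** model phasic skin
conductance responses, movement artifacts, electrode drift nonlinearity, or
item-level psychometrics — so passing tests demonstrate the correctness of
the computations, not the physiological realism of the inputs.

## Problem sizes and defaults

Tests and the acceptance script use cohorts of 12–30 participants for exact
checks and 200 for recovery-under-noise checks; recovery uses a planted
monotone surface driven by the model-1 traits only (coefficients 3.0 / 2.0 /
1.5, no interaction) so that effect-direction and ranking checks are
unambiguous. Training at these sizes takes seconds on one CPU. All
randomness flows from named seeds; reruns are byte-identical.

## Known limitations

* Impact matrices and surfaces inherit the instability of small-sample
  neural fits; different seeds give different (if qualitatively similar)
  matrices.
* The IQR fences on 7 scripts are sensitive to the quartile convention;
  linear interpolation is fixed as the default and alternatives are
  explicit parameters.
* Tercile thresholds estimated from ~30 values carry large sampling error.
* The coefficient of determination is reported on the training rows unless a
  held-out split is supplied; at these sample sizes it is an optimistic
  summary.
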