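# Methods

This note records the models implemented in `timepls`, the assumptions
behind them, the defaults and why they were chosen, and what the
simulation-based tests do and do not demonstrate.

## Data model

A complete repeated-measures design is assumed: every experimental unit
(a subject, or a subject × condition occasion in a crossover) is observed
at the same T time points, and group membership is constant within a
unit. The data live equivalently in a long table (ST′ rows × J feature
columns) or a cube (S′ × J × T). Reshaping between the two is exact; the
time mode is sorted ascending and the unit mode by unit id, so both
representations are invariant to input row order. Crossover designs are
handled by making the unit the subject × condition occasion, so a
6-subject, 2-condition crossover contributes 12 units to the cube's
first mode.

Feature reduction for real peak-picked tables follows common practice:
a variable is kept when it is detected — defined here as strictly
positive and non-missing, since peak-picking software reports absent
features as zero or missing — in at least 70 % of the samples of every
group × time subgroup, and when its coefficient of variation over pooled
QC injections is at most 0.7. Variables flagged upstream (e.g. extreme
retention times) are accepted as an explicit exclusion list; no
retention-time model is kept in the package.

## Dummy responses

The time-response label assigns 10 to samples inside the response window
and 1 outside it. The default window is the interior of the sampling
grid (all but the first and last time point), reflecting the assumption
that responding metabolites rise after baseline and return by the final
sample; for short protocols where profiles do not return to baseline the
window should be set explicitly (e.g. all post-baseline points). The
magnitude 10 is a tunable: predictive performance is flat in a broad
region around 10, and `ModelSpec(response_magnitude=...)` exposes it for
grid searching against Q² or AUC.

Group codes default to {−1, +1}. The coding is irrelevant for models 1,
2, 4 and 5 (centring absorbs any affine recoding) but decisive for the
model-3 product: with symmetric codes, a variable whose temporal
response is identical in both groups contributes equal and opposite
terms to cov(x, g·τ) and cancels, so model 3 targets genuinely
group-dependent temporal responses. A {0, 1} coding (which instead
zeroes the control samples' response) is available via
`ResponseDesign(group_codes=...)` but makes model 3 behave like a
"intervention-responds" detector that also fires on group-independent
responders.

## Estimators

**Bilinear PLS** is NIPALS PLS1 (single response column; the inner
iteration for multi-column Y is included for completeness): w_a ∝ Xᵀy,
scores t_a = X w_a, deflation of X by the loading outer product, and
coefficients B = W(PᵀW)⁻¹q. Autoscaling (column mean 0, unit sample
variance with denominator n−1) is built into the estimator so that
cross-validation folds and bootstrap resamples refit it automatically.
Zero-variance columns and responses with no covariance with X raise
informative errors rather than producing NaNs.

**Trilinear PLS** fits, per component, the dominant singular pair
(wᴶ, wᴷ) of Z = Σ_s y_s X_s — the rank-1 weight structure maximizing
covariance between unit scores and the response — using numpy's SVD
with a fixed sign convention (the largest-magnitude entry of wᴶ is made
positive, flipping wᴷ along with it so scores are unchanged); an exact
tie between the two leading singular values leaves the direction
undefined and raises. Both X and the response are deflated; because the
X deflation uses the weight outer product, scores are not exactly
orthogonal, and the response is therefore predicted by least-squares
regression on all accumulated scores (the coefficient path for every
truncated model is stored, so cross-validation evaluates all component
counts from one fit). Preprocessing is mode-1 centring followed by
single-slab scaling, RMS_j = sqrt(Σ_s Σ_t x²_sjt / S′T) computed on the
centred cube — scaling is applied to the data actually analysed, which
is the centred data. With T = 1 the component limit A ≤ min(S′−1, J, T)
admits a single component, and the model coincides exactly with
bilinear PLS1 on the unfolded matrix.

**Latent-variable choice** uses unit-wise cross-validation (folds never
split a unit's time points; 7 folds by default, leave-one-unit-out when
S′ ≤ 10) and picks the smallest A whose next component improves RMSECV
by less than 2 % (ties broken toward smaller A; if the curve keeps
improving, the largest A evaluated is returned). In the benchmark the
choice is made once per model on the first replicate and reused, since
replicates share their generating parameters.

## VIP and selection

VIP_j = sqrt(J · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a), where SSY_a is
the response sum of squares captured sequentially by component a (for
the trilinear models, from the nested score regressions). The identity
Σ_j VIP²_j = J holds for every fit, so VIP = 1 marks an average
variable. Balanced bootstrapping (concatenate B copies of the unit
indices, one uniform permutation, split into B blocks — every unit
appears exactly B times across sets) resamples units, keeping each
unit's time points together; preprocessing and the model are refit per
set. Sets that lose one of the two groups are replaced by plain uniform
resamples (logged; exact balance is marginally relaxed). B = 200 is the
default. A variable is selected when VIP\* − σ_VIP > 1, strictly; the
bootstrap spread is the population standard deviation over the B values
(so B = 1 gives σ = 0). The loading-weight alternative applies the same
one-σ rule to √J·|wᴶ_j,1|, whose squared values also average 1, so the
threshold is commensurate.

The bootstrap resampling unit is the experimental unit for both model
families: resampling rows would break the within-subject covariance that
the trilinear models exist to exploit, and would let a subject appear in
a resample at some time points but not others.

## Simulator

Per variable and group, the mean curve is μ(t) = c + a·t^α·e^(−βt)
(baseline c, amplitude a, rise exponent α, decay rate β; the peak sits
at t = α/β). Subject trajectories are x_s(t) = μ(t)·(1 + b_s + w_s(t) +
ε_s(t)): b_s ~ N(0, σ_b²) constant over time (inter-individual level
differences — the all-ones covariance σ_b²·**11**ᵀ), w_s multivariate
normal with AR(1) covariance σ_w²ρ^{|i−j|} (slow within-subject
drifts), and ε i.i.d. N(0, σ_ε²). The noise is multiplicative, as
intensity noise in LC-MS data scales with signal. The `1 +` term keeps
μ the actual expectation of the trajectory; a strictly multiplicative
variant μ·(b + w + ε), whose expectation is zero, is available as
`noise_model="strict"` for completeness but is not the default because
it destroys the interpretation of μ as the mean curve.

Eight profile classes are generated. Classes a–f are discriminating:
sharp early peaks (a), broad later peaks (b), responses in both groups
with larger amplitude under intervention (c), transient dips below an
elevated baseline (d), sustained rises that have not returned by the
last sample (e), and weak responses (f). Class g responds identically
in both groups (a metabolite affected by time of day or the protocol
itself, not the intervention) and class h is flat — the majority of an
untargeted profile. Default study conditions: 10 units per group, 3000
variables of which exactly 80 discriminating (split evenly over a–f),
time grid {0, 2, 4, 24} h, σ_b = 0.3, σ_w = 0.2, ρ = 0.5, σ_ε = 0.1,
and 20 % of the non-discriminating variables in class g. The per-class
uniform parameter intervals (see `simulate.DEFAULT_CLASSES`) were
calibrated once so that the five-model benchmark at these conditions
reproduces the expected qualitative and quantitative structure — model
3 recovering ≈ 76/80 discriminating variables with the best precision,
models 1/4/5 clustered near 55–65, model 2 last, near-perfect Q² for
model 2 and AUC for model 4, and ≈ 79/80 recovery at σ_b = 0.1 — and
then frozen; they are config-exposed (`SimulationConfig(classes=...)`)
but the defaults define the package's reference conditions and are not
adjusted per run.

Train/test pairs share the drawn curve parameters (the "same
metabolome") with independently drawn subjects.

What the simulator does *not* emulate: correlation between variables
beyond what the shared design induces (real metabolites come in
correlated families; effective multiplicity is lower in real data),
missing values, heteroscedastic detector saturation, batch or run-order
effects, and m/z–retention-time structure. Passing benchmarks therefore
demonstrate correct behaviour under the stated covariance model, not
performance guarantees on any particular real dataset.

## Evaluation

Selection is scored against truth by the confusion counts and
recall = TP/(TP+FN), precision = TP/(TP+FP), F_β with β = 1. The
variable-selection ROC ranks variables by the selection score
VIP\* − σ_VIP and sweeps the threshold; its area (computed as the
Mann–Whitney statistic) summarizes ranking quality independently of the
threshold. Predictive ability on held-out subjects uses Q² = 1 −
PRESS/TSS of the model's own dummy response and the ROC AUC of
predicted responses against group labels — per sample for bilinear
models, per unit for trilinear ones; the matrix response of model 5 is
projected onto the centred time-label pattern to produce one scalar
score per unit. The permutation test permutes group labels across units
and uses cross-validated Q² as its statistic with the add-one p-value
estimator. The group-wise t-test flagging used to define "truth" on
real data applies Welch's unequal-variance test at each time point and
flags a variable when any time point reaches p < 0.05.

Benchmark problem sizes in the test suite and the acceptance script —
10 replicates at the default conditions with B = 200 — were chosen as
the smallest runs at which the replicate means of the reported metrics
are stable to well within their tolerance bands (per-replicate TP
standard deviations are ≈ 1–2 variables).

## Known limitations

* Only complete designs are supported; missing samples must be imputed
  or the unit dropped upstream.
* The N-PLS variant implemented uses weight-based deflation without a
  core array; variants differing in deflation can give slightly
  different components beyond the first.
* The permutation test is uninformative for model 2, whose response
  does not depend on the permuted labels.
* AUC for models whose response is not a group indicator depends on the
  score construction above; other conventions yield different constants.
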