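# Methods

## The observer model

PIECE treats single-trial implicit adaptation as inference about the
*cause* of a movement error followed by estimation of its *magnitude*.
The generative model: the hand lands at x_h ~ N(b, σ_h²); on a perturbed
trial the cursor is rotated by r ~ N(0, σ_r²); vision reports the cursor,
x_v ~ N(x_h + r, σ_v²), while proprioception and the efference-copy motor
prediction both report the hand and are fused into a single internal cue
x_c ~ N(x_h, σ_c²). Visual uncertainty rises linearly with the
cursor-to-target distance e: σ_v = α + β·e. The prior over the causal
node is flat (0.5/0.5), matching the task statistics.

Marginalizing x_h (and r, for the perturbed cause) analytically leaves
bivariate Gaussian evidence over (x_v, x_c) with common mean (b, b),
covariance σ_h², and Var(x_v) inflated by σ_r² under the perturbed cause.
The implementation evaluates these in log space and normalizes with
log-sum-exp; linear-space densities are floored at 1e-300 only on output,
so the posterior stays exact even for cue values of order 10³. A
brute-force trapezoidal quadrature oracle (tests/oracle_quadrature.py)
verifies the closed forms to < 1e-6 relative error over 100 cue points
spanning ten parameter settings, including extreme precision ratios.

State estimation shrinks the perturbation observation z ~ N(r, σ_v²) by
the precision-weighted gain K = σ_r²/(σ_r² + σ_v²) and weights it by the
causal belief: r̂ = p(pert | cues)·K·z. The next reach is −r̂ + b + ε with
ε ~ N(0, σ_h²). Because z is centred on the rotation, a deterministic
observer produces *exactly* zero adaptation whenever r = 0: insensitivity
to internally generated error is structural, not fitted.

### Cue handling for the likelihood

How internal cue noise enters the fitted likelihood is underdetermined,
so the package provides two modes. The default ("mean") evaluates the
cues at their experimenter-visible values (x_v = hand + r, x_c = hand,
z = r) and absorbs residual variability into the σ_h response noise,
keeping the likelihood closed-form. A stochastic mode samples x_v, x_c
and z from their generative distributions; it is used for simulation and
posterior predictive checks, not for fitting.

## Parameters

| name | meaning | unit | default | status |
|---|---|---|---|---|
| σ_r | prior SD over plausible rotations | deg | 3.0 | free |
| b | intrinsic reach bias | deg | 0.5 | free |
| σ_c | fused internal-cue SD | deg | 1.0 | free |
| σ_h | intrinsic motor variability | deg | 2.5 | fixed from baseline |
| α | visual-uncertainty intercept | deg | 1.0 | fixed input |
| β | visual-uncertainty slope | — | 0.1 | fixed input |
| p(C=pert) | causal prior | — | 0.5 | fixed (task statistics) |

σ_h is estimated as the sample SD of the last 50 baseline reaches and is
not counted among the three free parameters. α and β are required inputs
whose shipped values are placeholders: the empirical psychophysical
estimates they stand in for are not distributed with this package, and
anyone fitting real data should substitute their own calibration.

The defaults above define the synthetic "study conditions". They were
chosen once so that a default synthetic participant reproduces the
behavioural regime this paradigm elicits — a sign-flipped bivariate EGE
coefficient near 0.6 with an IGE coefficient within a few hundredths of
zero, and σ_c inside the tight (0.2–1.4°) range such fits produce. Note
that the IGE coefficient of a simulated PIECE participant is not exactly
zero even though the deterministic predictor ignores the hand: on rotation
trials the product p(pert|cues)·K varies with the hand angle through
σ_v(e) and the evidence terms, leaking a small systematic hand dependence
(≈ −0.02 at the defaults, growing with β). This mirrors the imperfect
parsing real observers show.

## Rival models

All three rivals cast adaptation as re-aligning the perceived or
estimated hand with the target, so their error signals contain the hand
angle and they respond to motor noise. They share PIECE's response-noise
convention (fixed σ_h) and expose the same predict/simulate/fit surface.

- **PReMo** (6 free: β_v, γ_v, β_p, γ_p, η, b). Sequential saturating
  recalibration: perceived cursor ĉ = c + β_v·clip(0 − c, ±γ_v); felt
  hand p̂ = h + β_p·clip(ĉ − h, ±γ_p); response −η·p̂ + b.
- **PEA** (3 free: σ_p, σ_u, b). Precision-weighted fusion of the visual
  cue at the cursor (sharing σ_v(e) with PIECE), the proprioceptive cue
  at the hand, and a motor prediction centred on the goal; the response
  cancels the perceived hand.
- **REM** (4 free: η, σ_rel, p_rel, b). Causal inference over whether the
  cursor error is relevant to the hand — relevant errors ~ N(0, σ_rel²),
  irrelevant ones uniform over ±90° — with response −η·w(error)·error + b.

### Generating parameters for the rivals

The rivals' simulation defaults were fixed under two constraints. First,
rotation (EGE) sensitivity is matched to the PIECE default (≈ 0.4–0.6),
so the models differ in what they attribute errors to, not in how much
they adapt. Second, each model is placed in its characteristic nonlinear
regime — early-binding saturation for PReMo (γ_v = 1°, γ_p = 1.5°),
narrow relevance gating for REM (σ_rel = 2°). This matters for model
recovery: in their small-error *linear* regimes PReMo and REM are nested
within the 3-parameter PEA, and no model-comparison procedure could then
recover them against PEA's smaller BIC penalty. The saturating/gating
regimes are also where these models' distinctive predictions live.

## Experimental protocol and simulation

The default schedule is 70 baseline null reaches with veridical feedback,
then 18 blocks × 100 trials containing 100 rotation trials at each of
0/±2/±4°, every rotation trial immediately preceded and followed by a
null trial, rotation order randomized, and 50% of main-phase null trials
feedback-absent. Rotation positions are drawn by the gap method (sorted
draws plus offsets), which guarantees non-adjacency — and hence the
flanking constraint — by construction. An optional target-jump variant
adds 400 jump trials under strict null/measured alternation; jump trials
are excluded from every analysis.

Simulation assumes no memory across trials: a reach is N(b, σ_h²) except
immediately after a full-feedback rotation trial, where its mean is the
model's single-trial response; the update washes out on the following
trial. The lag-2 residual analysis (`lag2_residual`) checks this
assumption and detects injected one-trial memory in tests.

## Behavioural analyses

Adaptation is hand_{t+1} − hand_{t−1} across each (null, rotation, null)
triplet, which keeps the outcome free of the centre trial's own reach
angle (the IGE) and so avoids regression-to-the-mean artefacts. Trials
with a per-participant reach-angle |z| > 3.5 are excluded (single pass;
zero-variance participants produce a warning and no exclusions). The
binned analysis splits triplets by rotation level, quintile-bins IGE
within level (edges from each cell's empirical distribution, boundary
ties broken by stable rank), averages adaptation per bin, averages the
25 bins across participants, and regresses the grid on EGE and on IGE
separately (OLS). The bivariate analysis regresses unbinned adaptation
on EGE and IGE jointly, reporting sign-flipped coefficients. Group
inference uses paired and one-sample t-tests plus bootstrap 95% CIs
resampling participants (10,000 draws, seed-controlled). The 0° level
counts as one of the five EGE levels.

## Fitting and model comparison

Per participant, each usable full-feedback triplet contributes
hand_{t+1} ~ N(model prediction(r_t, hand_t), σ_h²) to the likelihood,
trials independent, 0° triplets included. Two documented switches cover
underdetermined alternatives: modelling the pre-to-post difference with
variance 2σ_h², and adding N(b, σ_h²) terms for null reaches (both off
by default). Optimization is bounded L-BFGS-B from Latin-hypercube
starts (20 by default; 8 in the recovery harnesses) with ftol 1e-8;
default bounds σ_r ∈ [0.1, 50], σ_c ∈ [0.01, 20], b ∈ [−10, 10], rates
in [0, 2], saturations in [0.1, 30], p_rel ∈ [0.01, 0.99]. BIC is
k·ln(n) + 2·nll with k = 3/6/3/4 for PIECE/PReMo/PEA/REM.

Recovery analyses run at the full 1800-trial session size: parameter
recovery refits PIECE at three generating conditions × 20 replicates;
model recovery simulates 10 participants per generating model and fits
all four to each. These sizes keep a complete run of the test suite and
the acceptance script within a few minutes on one CPU while leaving the
Monte-Carlo error well below the effects being checked.

## What the synthetic data do and do not show

The generator reproduces the paradigm's structure (trial counts,
flanking, feedback withdrawal, randomized order), Gaussian motor noise
with a participant-level bias, and model-consistent single-trial
responses. It does not emulate reaction/movement-time variation, online
corrections, slow drifts in bias or variance, fatigue, explicit
re-aiming, or kinematic detail — so passing tests demonstrate internal
consistency of the pipeline and discriminability of the models under
these idealized conditions, not that any model fits a particular human
dataset. Fitting real data additionally requires calibrated α/β and a
column mapping onto the trial-table schema (`read_trials(column_map=…)`).

## Numerical choices and degenerate inputs

- Posterior arithmetic in log space with log-sum-exp; linear densities
  floored at 1e-300 on output only.
- OLS r² is reported as 0 when the outcome has zero variance.
- Quintile ties broken by stable first-occurrence rank.
- Group t-tests guard the zero-variance case (p = 1 for identical pairs).
- Every stochastic entry point requires an explicit seed; fits, schedules
  and simulations are bit-reproducible given (data, seed, bounds, starts).
- σ_h must be strictly positive; noise-free behaviour is approximated by
  tiny values (e.g. 1e-12) rather than zero.

## Known limitations

- σ_r is weakly identified when the true σ_r is small relative to σ_v:
  the likelihood depends on it mainly through p(pert)·K, which forms a
  ridge (larger σ_r raises K but lowers the posterior), so individual
  estimates at the σ_r = 2 recovery corner scatter widely even though
  bias b and the median recovery error remain well behaved.
- σ_c is only mildly constrained by deterministic-cue likelihoods; its
  estimates drift within a factor of ~2 without much nll cost.
- The likelihood construction conditions on the observed centre-trial
  hand angle; it does not marginalize internal cue noise.
- No retention/temporal dynamics: the no-memory assumption is built in,
  so phenomena requiring multi-trial state (asymptotes, savings,
  spontaneous recovery) are out of scope.
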