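# Methods

`stressrl` implements, end to end, the computational analysis of an
event-related fMRI experiment in which participants perform a
probabilistic gain/loss selection task under alternating acute-stress and
control blocks: a dual-learning-rate Q-learning model is fitted to
trial-wise choices, its latent prediction errors modulate ROI BOLD in a
first-level GLM, and second-level contrasts test whether stress blunts
prediction-error signalling. Because no raw data from such a study are
bundled, a synthetic-cohort generator with known ground truth stands in
for the behavioural, self-report and BOLD inputs; every claim the test
suite makes is therefore a claim about the pipeline's behaviour on data
that satisfy its own assumptions, not about any real dataset.

## Task model

A session holds 2 runs x 2 blocks (one stress, one control per run,
order counterbalanced across runs: even participant ids start with
stress, odd with control). Each block introduces three fresh stimulus
pairs — gain, loss, neutral — presented 24 times each in random
interleaved order (72 trials/block, 288/session). Within a pair the two
stimuli carry reciprocal outcome probabilities p and 1-p (default
p = 0.75): on gain trials the "correct" stimulus wins 0.5 EUR with
probability 0.75 (else nothing), on loss trials the "correct" stimulus
avoids a 0.5 EUR loss with probability 0.75. Neutral outcomes carry no
money and are excluded from learning and behavioural analysis. The side
on which the correct stimulus appears is balanced 12/12 within each
pair. Responses not given in time are "missing": no outcome, no model
update, a nuisance regressor in the GLM.

Trial timing is configurable because it is a design nuisance rather than
part of the model: default 4 s stimulus-to-outcome delay, inter-trial
interval jittered uniformly on [2, 6] s, 16 s between the blocks of a
run, the clock restarting at each run. These are typical event-related
spacings; they affect design conditioning only.

## Learning model

Per stimulus pair the model tracks the value Q of both stimuli,
initialized at 0 (the neutral prior midway between the possible
outcomes). On each non-missing monetary trial

    delta(t) = r(t) - Q_chosen(t),            r in {-0.5, 0, +0.5}
    Q_chosen(t+1) = Q_chosen(t) + alpha * delta(t),

with alpha = alpha_pos for delta > 0 and alpha_neg for delta < 0
(delta = 0 updates nothing). Choices follow the two-option logistic
softmax P(left) = sigma(beta (Q_left - Q_right)). Parameters: alpha_pos,
alpha_neg in [0, 1]; beta >= 0, interpreted per condition — each
subject gets an independent (alpha_pos, alpha_neg, beta) triplet for
stress and for control. Under these ranges Q stays in [-0.5, 0.5] and
delta in [-1, 1] for any input sequence (a property test enforces
this). The sequential likelihood kernel is compiled with numba; the test
suite checks it against an independently written step-by-step evaluator
to 1e-10.

## Estimation

Per subject x condition, bounded maximum likelihood over the 96
monetary trials of that condition: L-BFGS-B from 20 uniform random
starts (seeded), bounds alpha in [0, 1], beta in [0, 20]. An exhaustive
grid oracle cross-checks that the optimizer never returns a worse
likelihood than an 11^3 grid. No priors are applied; the fit API leaves
an obvious place to add penalties should regularized estimates be
wanted.

A known, consequential limitation: one session per condition carries
little information about alpha_pos. Simulate-and-refit at the study's
own scale yields a Spearman correlation of only ~0.2 between true and
recovered alpha_pos, with a fifth of fits overfitting to the beta upper
bound; the group-level ordering alpha_pos(stress) < alpha_pos(control)
injected by the default generator is *not* reliably recovered from
per-subject point estimates at this data volume (a dedicated acceptance
test documents this and fails by design until more informative data or
a hierarchical estimator is used). Quadrupling the data per condition
raises the correlation to ~0.6 and recovers the ordering, so the limit
is informational, not algorithmic. Weak MAP penalties (Beta priors on
alpha, an exponential penalty on beta) remove the boundary fits but do
not restore the ordering, which is why the simpler plain-MLE default was
kept.

## Behavioural statistics

Choices are coded correct/incorrect against the 0.75-contingency
definition; neutral and missing trials are dropped. Stress responders
are participants whose mean self-report rating (1-9, one per block) is
strictly higher under stress; the manipulation check is a 2x2
(condition x block) repeated-measures ANOVA with partial eta squared
(two-level factors need no sphericity correction; a zero
sum-of-squares effect is reported as an exact null rather than 0/0).

Trial-wise accuracy is modelled with a mixed-effects logistic
regression — fixed effects condition, valence, block (1/2), trial
(1-24, linear), condition x valence; random intercepts per participant
— estimated by lme4::glmer (Laplace) through an Rscript bridge, with
Wald CIs and contrasts computed from the fixed-effect covariance.
Coding is treatment with control and gain as references, so the
condition coefficient is the stress effect on gain trials and the
interaction is the loss-minus-gain difference of stress effects; a
gain-specific impairment appears as a negative condition coefficient
with a positive interaction. Continuous predictors enter on their raw
scale. The simple stress-vs-control effect within each valence is a
single-df Wald F.

## ROI GLM

The first-level model per run contains stick regressors at stimulus and
outcome onset for each condition x valence (neutral and missing as
nuisance), plus four parametric modulators per condition: Q_chosen at
stimulus onset and delta at outcome onset for gain and loss trials.
Modulator values are mean-centered within run and not orthogonalized
against their parent sticks (centering alone keeps the slope
interpretable and avoids order dependence); a constant modulator would
produce an all-zero centered column, so it is flagged and omitted.
Events are binned to the scan grid (floor to the containing TR = 2 s;
no microtime upsampling) and convolved with the canonical double-gamma
HRF (gamma(6,1) minus gamma(16,1)/6, 32-s support, peak-normalized).
Drift is handled by a discrete-cosine basis spanning periods above
128 s plus an intercept. Fitting uses AR(1) prewhitening: rho from the
lag-1 autocorrelation of OLS residuals, Prais-Winsten transform, OLS
refit; noise-free residuals short-circuit to rho = 0.

Per subject, the delta-modulator slope of each condition x valence cell
is combined across runs by inverse-variance weighting. Second level:
one-sample t per cell, paired t for the control > stress main effect
(slopes averaged over valences) and for the condition x valence
interaction. The spatial dimension is deliberately absent: the unit of
analysis is an ROI-averaged time series, so the voxelwise
small-volume-corrected inference of a full neuroimaging analysis is
out of scope and the ROI plays the role of the significant cluster.

Two modulator-free subsidiary models visualise the shape of the
prediction-error response: (i) outcomes split into four bins by signed
delta quartiles within condition x valence (stable sort, contiguous
groups differing by at most one, so ties never empty a bin; boundaries
= the 25/50/75% empirical quantiles, compared across conditions by
paired t); (ii) outcomes split by prediction-error sign (delta >= 0
counts as positive so the measure-zero tie is deterministic), followed
by a condition x sign repeated-measures ANOVA on valence-averaged
estimates, a contrast for the three-way term, and paired t-tests with
Cohen's d per cell. Because these designs have no modulators,
within-cell delta variance projects onto neighbouring regressors; the
test suite shows this cross-talk moves negative-PE cells even when only
the positive-PE response is manipulated — the same caveat applies to
any analysis of this form, which is exactly why the quartile-boundary
comparison exists.

The Spearman correlation between the gain-stress slope and the
self-report responsivity Delta completes the battery.

## Synthetic cohort

The generator's defaults emulate the study conditions the pipeline
targets: 37 participants, 23 of them stress responders (responders are
constructed with stress ratings 1-4 points above control in each block,
non-responders at or below control, so the filter's decision is exact);
alpha_pos ~ N(0.40, 0.10) under control vs N(0.20, 0.10) under stress,
alpha_neg ~ N(0.30, 0.10) and beta ~ N(3, 1) in both conditions
(truncated to their ranges); missing-response rate 13/6624. BOLD per
run is built from the participant's own latent trace: unit responses at
every stimulus and outcome, 0.5 x Q_chosen at stimulus, slope x delta
at outcome, convolved with the same HRF, plus a slow cosine drift
(amplitude 1, period 300 s), a baseline of 100 and stationary AR(1)
noise (rho = 0.3, sd = 1). The unblunted delta slope is a subject-level
trait (1.0 + N(0, 0.3) per valence, shared across conditions — drawing
it independently per condition would inject implausible
between-condition noise into every paired contrast); stress multiplies
it by the blunting factor (default 0.3), optionally restricted to gain
trials or to positive prediction errors, and optionally coupled to the
subject's self-report responsivity (disabled by default). With these
defaults the control > stress main effect is detected in 100/100
cohorts of 23 at alpha = .05, and a blunting factor of 1 (no effect)
rejects in ~5%.

What the generator does not emulate: voxel geometry and spatial noise,
head motion, physiological confounds, habituation of the stress
response, any model mismatch between the agent and the fitted model
(the agent *is* the fitted model), and non-stationary learning rates.
Green tests therefore certify the pipeline's internal consistency and
statistical calibration, not robustness to real-data violations.

## Problem sizes and numerics

The test suite runs cohorts of 8-23 subjects (100 for the mixed-model
sign checks, where the generator's behavioural effect is a few
percentage points of accuracy), 100-cohort batteries for power and
type-I calibration, and 24-40 pooled sessions where likelihood-surface
asymptotics are asserted; these sizes were chosen as the smallest at
which the tested property is statistically unambiguous. All randomness
flows from explicit integer seeds through numpy SeedSequence spawning
(pipeline stages derive child seeds from the master seed by fixed
offsets), so every table and file is bit-reproducible. Numerical guards:
the softmax log-likelihood uses log1p with a linear tail below -30;
AR(1) rho is clipped to [-0.99, 0.99] and set to 0 for numerically zero
residuals; rank-deficient designs are rejected with the offending
columns named.
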