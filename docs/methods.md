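# Methods

## The tracking problem

A participant trains on an N-back task in *blocks* (here 40 trials, ~2–3
minutes at a constant nominal n-level). Per block the log records the
presented n-level `z_t`, the number of target trials `m_t`, and the outcome
counts (hits TP, misses FN, false alarms FP). Block performance is

    accBlock = TP / (TP + FN + FP),

hits over hits + misses + false alarms; correct rejections are excluded.
The quantity of interest is the participant's latent maximal n-back skill
`x_t`, which is never observed; the trackers maintain a posterior over it
given the history of (z, y) pairs and predict the accuracy of the next block.

## Observation model

Item response theory supplies the link between skill, difficulty and
performance: the 4PL item characteristic curve
`a(x, z) = c + (d − c)/(1 + e^{−ρ(x−z)})` with discrimination ρ > 0, guessing
floor c and carelessness ceiling d. Within a block, responses are coupled by
a shared realised ability `â ~ Beta(αa, α(1−a))` (mean a, concentration α);
marginalising the binomial success count over â gives a beta-binomial block
likelihood. As α → ∞ this collapses to the plain binomial. The beta-binomial
mass is evaluated through `scipy.stats.betabinom` (log-gamma arithmetic
throughout); the test-suite checks it against adaptive quadrature of the
defining integral to 1e−6 relative error.

Two reconciliations are needed between accBlock and the binomial support:

* The emission models a count out of `m_t` targets, but accBlock's
  denominator includes false alarms. Models are fitted on the effective
  success count `y_succ = round(accBlock × m_t)`, which keeps the support
  {0..m} while preserving the false-alarm penalty; raw counts stay in the
  record for audit.
* With c = 0 or d = 1 the beta parameters degenerate as a → 0 or 1; a is
  clamped to [1e−6, 1 − 1e−6] before forming Beta(αa, α(1−a)). This keeps
  log-gamma finite and perturbs likelihoods negligibly.

Blocks with `TP + FN + FP = 0` carry no information about skill; they are
kept in the data structures but skipped by fitting and scoring, with a
logged notice.

## Discrete-state tracker (input-output HMM)

The skill grid is {1..N} with N = 10 by default (trajectories in real
training reach level 9; configurable). Transitions are restricted to
adjacent levels — skill moves at most one level per block — and are tied:

* **model-1**: three universal probabilities (down, stay, up), 3 parameters.
* **model-2**: propensities indexed by (skill movement, `z_prev − x_new` in
  {−2..2}, decile bin of the previous accuracy), 3 × 5 × 10 = 150
  parameters. Destinations with `|z_prev − x_new| > 2` are masked. Accuracy
  bins are half-open [(k−1)/10, k/10) with the top bin closed.

Rows are formed by zeroing infeasible destinations (grid boundary, model-2
mask) and renormalising; tensor entries are therefore propensities, not
probabilities, and the tensor's global scale is fixed by setting its largest
entry to 1. If the mask removes every candidate (possible under session-reset
rules that present levels far from the skill estimate) the row degenerates to
a self-transition — a flagged model-misfit regime, not an error.

**Fitting.** Baum-Welch EM adapted to tied parameters and input-dependent
rows. The E-step pools expected transition counts across all participants
into context rows; the M-step maximises the expected complete-data
log-likelihood of the masked, renormalised rows numerically (L-BFGS on
log-propensities with the analytic gradient). A closed-form count-ratio
update would be exact only without masking; because boundary rows are also
renormalised, the same numerical M-step is used for model-1. This yields a
generalised EM whose log-likelihood trace is non-decreasing, which the tests
assert to 1e−6. The initial distribution π is re-estimated from pooled
first-block smoothed marginals (initialised uniform). Convergence: the
per-iteration increase of the total log-likelihood falls below 0.001
(a deliberate allowance for slight imprecision), with a cap on iterations.
Model-2 has a multimodal surface; 5 seeded random restarts by default
(configurable — the recovery experiments use 1, where both a truth-seeded and
a default initialisation reach the same optimum).

The IRT hyperparameters enter the emissions only and are optimised in an
outer grid search (default grid: ρ 1.0–2.5 step 0.1; c ∈ {0, 0.05, 0.1};
d ∈ {0.9, 0.95, 1.0}; α ∈ {1, 3, 5, 8, 11.56, 20}), scored on training or
held-out log-likelihood per configuration.

**Point estimates and prediction.** The reported skill trajectory is the
argmax of the *filtered* belief per block, ties broken toward the lower
level (conservative placement); smoothed posteriors are available through
`forward_backward`. Accuracy predictions are one-step-ahead: the belief
after blocks 1..t−1 is propagated through the transition row driven by
(z_{t−1}, y_{t−1}) and averaged over the ICC at z_t; block 1 is predicted
from π. This is the standard filtering metric and how a deployed adaptive
controller would use the model.

## Continuous-state tracker (UKF)

State (skill, ρ): tracking the discrimination personalises the single item
parameter the HMM shares across participants. Dynamics are linear-Gaussian,
`x_t = A x_{t−1} + B u_t + v_t` with control `u_t = (z_t, y_{t−1}, 1)` —
current challenge, previous performance, bias; `y_0 = 0.5`. The composition
of the three control inputs is a design choice of this package. The
observation is the 4PL with c = 0, d = 1 evaluated at the state's own ρ
(clamped at 0.05 so sigma points cannot flip the curve's sign), with additive
Gaussian noise R on the accuracy fraction.

The prediction step is linear and exact; the measurement update uses Merwe
scaled sigma points (α_UT = 0.5, β_UT = 2, κ = 0; configurable). Because the
dynamics are linear, the RTS smoother is exact given filtered moments. EM
estimates A, B (joint generalised least squares), Q (smoothed residual
second moments), x0/V0 (smoothed initial moments) and R (sigma-point
propagated observation residuals). The E-step is approximate, so
monotonicity of the log-likelihood is asserted only to 1e−4 relative — a
property of the approximation, not a defect. Covariances are kept symmetric
PSD by eigenvalue flooring at 1e−9 (logged when triggered). With a linear
observation substituted, the filter reduces to the exact Kalman recursion
(verified to 1e−8) and EM to standard linear-dynamical-system EM, the basis
of the recovery test.

## LSTM baseline

One LSTM layer (32 units; 4,480 parameters = 4u(u + d + 1) at input
dimension d = 2) plus a dense head (66 = 2u + 2) maps a causal sliding
window of (z, y) pairs to the next pair. Window length 20 by default (a
design choice; configurable). n-levels are standardised by training-set
mean/sd; accuracies stay on [0, 1]. Windows never cross participant
boundaries; a participant's first `window` blocks get no prediction.
Training: full-window MSE over both outputs, Adam (lr 3e−3), batch 32,
80 epochs by default, fully deterministic under a seed. The network is
implemented directly in numpy with backpropagation through time; gradients
are verified against numerical differentiation. Whether to normalise
accuracies or use teacher forcing across whole sequences was an open choice;
independent causal windows are implemented.

## Simulator

The generator emulates the block-level statistics of adaptive N-back
training logs: targets per 40-trial block are Binomial(40, 0.30); hits are
binomial in the realised beta ability around the ICC at (true skill,
presented level); false alarms arrive at rate 0.05 per non-target trial.
The false-alarm process sits deliberately outside the HMM emission, so the
accBlock/binomial reconciliation is exercised by default. Defaults: 18
sessions (within the 16–20 range of typical training courses) of 8 blocks
(a 20-minute session of 2–3-minute blocks), start level 2, level cap 10
matching the HMM grid.

Progression rules: staircases move within blocks on consecutive hits
(3/3/6) and consecutive errors (2/3/2); counters treat correct rejections
as neutral, reset on the opposing event and on any level change, and a
mid-block level change continues the stimulus stream at the new level (the
emitted record keeps the block's starting level as z). Mini-block rules move
between blocks on total errors (<6 up / >8 down; <3 up / >6 down; the reset
variant additionally starts every session at 2-back). The blockwise rule
moves on single-block accuracy >0.85 / <0.70 — "consistent accuracy" is
read as a single-block threshold, with a configurable consecutive-block
count. Within a staircase block, the realised ability is obtained by mapping
one shared uniform quantile through the beta at the current level's ICC
mean, so the constant-level case reduces exactly to the beta-binomial model.

Archetypes: steady learner (climb probability 0.03/block to a plateau of 7,
lapse 0.005), non-learner (constant skill), oscillator (climbs then flips
between plateau and plateau+1 with probability 0.2), and `hmm_generative`
(skill follows a supplied tied transition model exactly — the basis of
parameter-recovery experiments). The defaults are chosen to mimic the
qualitative participant profiles seen in training studies; the simulator
does not model stimulus identity, lure structure, reaction times or
motivation, so passing recovery tests demonstrates estimator correctness
under the stated generative assumptions, not fidelity to any real cohort.

## Evaluation

Pooled test RMSE in percent: 100 × sqrt(mean over scored blocks of squared
(predicted − observed accuracy fraction)), pooled over blocks (the
per-participant MSE breakdown is always reported alongside; pooled RMSE² is
the block-weighted mean of per-participant MSEs). Splits are at participant
level, 80:20 by count with the remainder to train, seeded. First blocks are
scored from the prior by default, with an exclusion flag. RMSE values like
"5.6%" are accuracy-fraction RMSE × 100, not n-level error.

## Problem sizes in the test-suite

Enumeration oracles run at N = 3, T = 4 (exact). Parameter recovery runs at
200 participants × 100 blocks; model-1 recovers its three probabilities
within ±0.02 under the default observation model, and model-2's
row-conditional probabilities are checked within ±0.05 on rows with ≥ 100
realized transitions under a sharp-emission design (ρ = 5, α = 50,
false-alarm rate 0) — sharp emissions make the latent state identifiable, so
the experiment isolates the tied-parameter EM from emission-induced
smearing, which under soft emissions biases individual rows even at the
likelihood's global optimum. Recovery experiments generate with a zero
false-alarm rate so the generative model matches the fitted emission
exactly. The comparative model-1 vs model-2 ordering uses 10 seeded
replicates of 40 × 48-block cohorts. The IRT grid-search recovery check uses
a reduced 3 × 3 (ρ, α) grid over 5 seeds. UKF dynamics recovery uses the
linear-observation special case at 60 × 80.

## Known limitations

* Universal IRT parameters across participants (the UKF's per-participant ρ
  is the one exception); per-participant item parameters are out of scope.
* The HMM reports filtered (not smoothed) trajectories; Viterbi decoding is
  deliberately absent.
* Model-2's 150 tied propensities are identified only through masked,
  renormalised rows; individual tensor entries are not directly comparable
  across fits, and row estimates under soft emissions carry
  smearing bias (see above).
* UKF EM is approximate; its likelihood can plateau with small oscillations
  near a fixed point.
* The simulator's archetypes are stylised; no claim is made that passing
  tests transfers to any particular human cohort.
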