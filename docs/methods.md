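# Methods

`hapticlearn` simulates a robot-assisted motor-learning study — a virtual
pendulum target-hitting task trained with or without haptic guidance — and
fits the linear mixed models that turn its per-wall outcomes into
percent-change learning effects.  This note documents the models, the
numerical choices, and what the synthetic data can and cannot show.

## Task physics

The virtual pendulum has one internal degree of freedom; its pivot is the
haptic-device end-effector, moving in the vertical (y, z) plane.  With
`theta` measured from the downward vertical (positive toward +y) the
internal DoF obeys

    theta_dd = -(1/L) ((z_dd + g) sin theta + y_dd cos theta)
               - c/(m L^2) theta_d

and the rendered rod force is

    F_rod = m ((z_dd + g) cos theta - y_dd sin theta + theta_d^2 L).

Defaults: m = 0.6 kg, l = 0.25 m, g = 3.24 m/s², c = 3.00e-6 N·m·s/rad.
The sign convention is pinned by two facts: with a fixed pivot the equation
reduces to `theta_dd = -(g/L) sin theta`, and at static rest the rendered
force on the hand is the downward pull `m g` = 1.944 N.  The damping
constant is printed in the source material as N·s/rad; we interpret it as a
torque-damping coefficient (N·m·s/rad) — at 3e-6 the distinction is
numerically irrelevant.  The main task's natural frequency is
`sqrt(g/L)/2π` = 0.573 Hz; the dynamics-transfer task scales the rod to
70 % (L = 0.175 m), giving 0.685 Hz.  The published task description says
the rod was "reduced by 70 %", which conflicts with the 0.685 Hz it also
reports; only a reduction *to* 70 % reproduces both frequencies, so the
frequencies are taken as authoritative.

Integration is fixed-step classical RK4.  The reference implementation
defaults to 1/4000 s (the deployed 4 kHz control loop); the batch engine
uses 2 ms, which a step-halving test shows leaves per-wall misses unchanged
to < 1e-4 m.  With zero damping and a fixed pivot, energy is conserved to
better than 1e-6 relative over 60 s.

## Task protocol

Walls arrive every 1 s (1 m spacing at 1 m/s); each carries a target at
offset −0.12, 0 or +0.12 m from the centerline.  The per-wall score is
`100 − 500·|Error|`, floored at zero beyond 0.2 m; a set of 20 walls is
scored by the mean.  The two-session protocol: familiarization (excluded
from analysis), baseline (2 sets main task, 2 position transfer, 2 dynamics
transfer), training (two rounds of 15 main-task sets), one washout set,
short-term retention, and long-term retention structured like baseline.
The main-task target sequence is drawn once per participant and reused
everywhere except mirrored training sets; the dynamics transfer (t2) reuses
it with the short rod; the position transfer (t1) gets fresh sequences,
drawn once per participant and reused across stages so that its 40 walls
keep a stable identity (`NewWalls` 1..40; 0 elsewhere).  Catch sets
(guidance silently off) default to training sets {1, 6, 11} of each round
and mirrored sets to {3, 8, 13}; the exact published positions are not
recoverable from the text, so both are configurable.

## Haptic guidance

At every wall crossing a reference pivot trajectory is planned over the
next 1 s interval, minimizing

    J = w_acc (mass_y(T) − b)² + w_stab ∫ |mass velocity|² dt + w_u ∫ y_dd² dt

subject to the pendulum dynamics (pivot vertical motion held fixed), with
defaults w_acc = 1e4, w_stab = 1, w_u = 1e-3 (the original cost weights are
not published; acceptance does not depend on them).  A PD force
`F_HG = Kp e + Kd e_dot` (75 N/m, 15 N·s/m) pushes the end-effector toward
the reference along y only.

The optimizer is direct single shooting rather than collocation: the
decision variable is the pivot y-acceleration at 21 uniform nodes
(piecewise linear in time), rolled out by RK4 and minimized with L-BFGS-B
from a minimum-jerk warm start.  Gradients are batched central differences,
which makes the solver *exactly* equivariant under mirroring of the problem
(every arithmetic operation is sign-symmetric).  On a 1 s horizon the
rollout is well-conditioned, so shooting matches collocation's optimum
while staying a small, deterministic, unconstrained problem.  If the
optimizer throws, the planner falls back to a plain minimum-jerk
point-to-point path to the target offset and flags the reference.

A second, closed-form backend ("minjerk") plans a minimum-jerk pivot path
whose endpoint is chosen so that the *linearized* hand–pendulum loop puts
the mass on the target at the crossing: the 4-state linear system (pivot
servo + linearized pendulum coupling) is rolled out twice, the terminal
mass position is affine in the endpoint, and the compensating endpoint
follows exactly.  This backend costs two 50-step linear rollouts per wall
and is the default inside batch study simulation, where the shooting
optimizer (thousands of solves per cohort) would be prohibitive.

## Synthetic cohort

The generator's contract is to reproduce the *statistical structure* the
mixed models assume — learning curves, trait-linked effects, motor noise,
crossed random effects — with configurable, exactly-known effect sizes.
It is deliberately not a cognitive model.

Each subject is a noisy pursuit controller holding the end-effector
(admittance mass 0.5 kg, damping 5 N·s/m, hand PD 40 N/m / 12 N·s/m,
stable against the guidance gains).  Per wall interval the subject plans a
swing-compensated minimum-jerk pivot path — the same closed-form planner as
the guidance backend, refined by a short secant iteration on a nonlinear
preview rollout, with endpoints clamped to a ±0.6 m workspace — toward a
*misperceived* target: the true offset plus a zero-mean Gaussian aiming
error.  Because the plan is executed accurately, the realized miss equals
the aiming error up to a ~1e-4 m residual, so the configured noise scale
maps one-to-one onto the emitted |Error| distribution.  That choice is what
makes the injected stage ratios exact on the log10 scale; noise injected
further upstream (e.g. force noise) propagates through the nonlinear loop
and distorts the configured ratios by a few percent.

The aiming-error s.d. is `sigma0` (0.05 m) at baseline, decays across
training as `r + (1−r) exp(−k·s)` (k = 0.2 per set), and sits at the
configured stage ratios afterwards.  Defaults are the study conditions the
generator emulates: error ratios 0.62/0.61 (Control BL→STR/LTR, i.e. the
reported 38 %/39 % reductions) and 0.72/0.685 (Experimental, 28 %/31.5 %).

The recorded interaction force per wall is the mean |hand force| between
consecutive inter-wall midpoints.  The hand force combines the tracking PD
force with a motion-neutral grip/co-contraction sinusoid (2 Hz, amplitude
6 N with 0.12 log10 wall-to-wall exertion variability) — co-contraction
registers in force sensing without moving the arm, and keeping it dominant
makes the per-wall force noise the independent kind the model's residual
captures.  The configured force effects (stage ratios 0.70/0.68 Control,
0.80 Experimental; the Group × LOC × Stage coupling `10^(0.15·LOC)` for
Experimental retention; the Transform-of-Challenge effort-economy factor
`10^(−0.25·TC_c)` for Control retention) multiply the recorded force as an
isometric effort intensity, so their log10-scale truths are exact.

Trait couplings with configurable gains: reliance on guidance
`clip(0.7·(LOC+1)/2, 0, 0.9)` scales the voluntary force under guidance
(external LOC leans on the robot); Transform of Challenge adds
`10^(−0.22·TC_c)` to Control retention error scales (≈5 % extra
improvement at a +0.1 trait level); Free Spirit adds low-frequency (0.3 Hz)
exploratory jitter, kept small (5 mm per unit trait) so it does not distort
the configured ratios; the guidance-experience answers are logistic in
reliance and Free Spirit, and a frustration × Free Spirit coupling acts on
Experimental long-term-retention errors so the perception model has an
exercisable known truth.  Participant heterogeneity enters as lognormal
multipliers on the noise scale and grip amplitude (log10 s.d. 0.065 and
0.05), which become the ID random intercepts.  Cohorts are allocated like
the deployed study: the first 20 at random, the rest by minimization on
(sex, LOC-tercile) marginals with a dominant overall-balance term.

What the generator does *not* emulate: within-set fatigue or attention
drift, session-gap forgetting beyond the configured LTR ratio, systematic
(non-zero-mean) aiming biases, z-axis hand motion, and any dependence of
difficulty on the specific target sequence beyond what the closed loop
produces.  Passing recovery tests therefore show that the analysis pipeline
is correct and well-calibrated for data with this covariance structure —
not that the behavioral model predicts human data.

## Statistical models

Three mixed models are fitted to the long-format trial table (one row per
wall crossing), with treatment coding referenced to Control / BL / mn:

* M1.1 — `log10|Error| ~ Group×(Task+Stage) + (TC_c+LOC_c)×(Task+Stage+sIndex)
  + Task×Stage + Group×TC_c×Stage + (1|ID) + (1|wIndex:NewWalls)`
* M1.2 — the same for `log10|IntForce|` plus `Group×LOC_c×Stage`
* M2 — `log10|Error| ~ (AC_c+FS_c+TC_c+LOC_c)×HRIQ_c×Stage + (1|ID) +
  (1|wIndex)`, per guidance-experience question, Experimental main-task
  data only, all stages.

M1.1/M1.2 are fitted on BL/STR/LTR; the guidance-confounded training phase
is excluded.  The wall random effect groups on the (wIndex, NewWalls) pair
so position-transfer walls get their own levels.  Zero outcomes are floored
at 1e-4 (m or N) before the log; the original handling of zeros is not
stated.

Fitting is REML via statsmodels' MixedLM, with the crossed random
intercepts expressed as variance components over a single all-encompassing
group.  AIC/BIC comparisons refit by maximum likelihood.  On balanced
one-way data the (refined) optimum matches the closed-form ANOVA
estimators to 1e-6, and with variance components pinned at zero the GLS
fixed effects coincide with OLS — the two oracles the test-suite checks.
p-values use the normal (Wald) approximation rather than Satterthwaite
degrees of freedom: with thousands of rows per fit the difference is
negligible, and no conclusion here rests on exact p-values.  Bonferroni
family sizes are configuration (the original per-figure families are not
stated); the default reporting family is the full contrast plan.

Effects are reported as percent changes `100·(1 − 10^Δ)`, Δ the difference
of fixed-effect linear predictors between two fully specified conditions;
Wald intervals map through the same monotone transform, so CI endpoints
keep their order and coverage.  High/low trait levels are ±0.1 on the
normalized scale; Locus of Control is evaluated at its endpoints ±1
(centered with the cohort mean).  Triple interactions are reported as
differences of changes on the same scale.

## Problem sizes and reproducibility

Every run is reproducible from (config, seed): a master `SeedSequence`
spawns one stream per participant and draws happen in a fixed order; the
run manifest snapshots the configuration.  The recovery checks in the
test-suite use 50 replicates of a scaled-down study — 20 participants and
one training round — which keeps each replicate at roughly ten seconds
while leaving the design balanced; the injected truths (the 38 % Control
error reduction and the +0.30 log10 external-vs-internal LOC force
contrast) are covered by the 95 % CIs in ≥ 90 % of replicates.  The
guidance-efficacy check compares median per-set error with guidance on
versus off for the default novice across 50 seeds at identical noise.

## Known limitations

* The planner's cost weights and the exact catch/mirrored set positions are
  reconstructions; both are configurable and nothing downstream depends on
  their exact values.
* The behavior model's aiming-error structure makes per-wall errors
  independent given the participant, so the wall random-effect variance in
  the synthetic data is near zero and fits may flag a boundary (singular)
  component.  This is expected and non-fatal.
* The z-axis is held fixed throughout; the deployed task allowed (unguided)
  vertical motion.
* Interaction force is recorded directly from the simulated hand force;
  the deployed system estimated it with reaction-torque observers from
  motor currents.  The simulation-side quantity is the estimand of that
  observer.
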