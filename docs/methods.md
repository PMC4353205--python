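# Methods

## The model in one paragraph

Effort is treated as a learnable binary *option*. A cortical pathway maps a
stimulus `s` onto actions `k` through non-negative weights `w[s, k]`; the
probability of action `k` is a softmax of `g · w[s, k]`, where the gain `g`
is set by a cortico-basal-ganglia limbic loop. The loop's ACC stage chooses
between Boost (`g = gain_boost = 10`) and NoBoost (`g = gain_noboost = 1`)
by a softmax with gain `γ` over learned option values `Q(state, option)`.
After each trial the chosen option's value (and the state value `V(state)`)
moves toward the net outcome `R − c·x_cost` with learning rate `α` — a
delta rule, i.e. generalized policy iteration with Hebbian-local tabular
updates: only the visited state/option changes, and `Q` equals an
exponentially recency-weighted average of past net outcomes. Boosting costs
`c` whether or not the response succeeds; reward `R` is the stimulus's
reward on correct responses and 0 otherwise.

The normative counterpart evaluates `U(e) = r·e/(d+e) − c·e` in closed form
(`effortrl.optimal`). Its printed optimum is implemented as
`e* = max(0, sqrt(d·r/c) − d)`, the unique stationary point of `U`; a
brute-force grid maximizer in the test suite confirms it to 2e-3. Negative
optima are clamped to zero and `c = 0` is rejected (the optimum diverges).
No quantitative mapping between the two models' effort units is attempted;
they are compared qualitatively only.

## Parameters that matter

| parameter | default | units / role |
|---|---|---|
| `alpha` | 0.5 | learning rate of the option/state value delta rule |
| `gamma` | 3 (schedule sim: 6) | softmax gain of the Boost/NoBoost choice |
| `cost` | 0.2 | effort cost per boosted trial, in reward units |
| `gain_boost` / `gain_noboost` | 10 / 1 | pathway gain applied by the loop |
| rewards | easy 1, difficult 2 (T-maze: LR 1, HR 2) | reward units |
| `delta` | 0.8 | relative confusability of the difficult stimulus, in [0, 1) |

The ventral-striatum activation rule `VS = 10·x_Boost + 1·x_NoBoost` is
passed linearly through the pallido-thalamic stage, so the two gains reach
the cortex unchanged; both are exposed as parameters.

## Protocol notes and design decisions

**Effort allocation (sim 1).** Two difficult stimuli share the action row
`[0, 1, δ]` (correct action competes with a confusable neighbour of weight
δ); rewards 1.5 and 2 when cost is swept (variant 1a), 1 and 2 when δ is
swept at cost 0.2 (1b). 150 training + 50 recorded trials; reported
activation is the mean applied gain over recorded trials. Boosting states
are keyed per stimulus. The activation-vs-δ curve has an interior maximum,
but its rise from the easy edge is shallow (≈ 0.05 gain units): once
boosting dominates, `Q(NoBoost)` is rarely resampled and the boost
preference is sticky, compressing differences between easy and moderate
difficulty. Resolving that edge statistically needs several thousand
replications.

**Conflict pathway (sims 2–3).** Weights `[[w, 0], [δ·w, w]]` with pathway
strength `w = 5`: the correct action carries weight `w`, the difficult
stimulus's wrong action carries `δ·w`. The scale is chosen so congruent
stimuli succeed without boosting (unboosted congruent accuracy
`logistic(5) ≈ 0.99`, matching empirical congruent accuracies) — with
`w = 1` unboosted congruent accuracy is 0.73, boosting pays everywhere, and
the block and sequential effects collapse. At `δ = 0` the two rows are
permutations (no congruency effect); `δ ≥ 1` is rejected because the wrong
response would dominate.

**Proportion congruency (sim 2).** One mostly congruent (80% easy) and one
mostly incongruent (20% easy) 200-trial block per replication, 100
replications; a single always-active context unit keys the boost decision
and its values start fresh each block, so only the block — not the stimulus
— controls effort. The PC interaction `(MC_c − MC_i) − (MI_c − MI_i)` is
positive (≈ 0.09) because boosting is learned to pay in MI blocks.

**Sequential congruency (sim 3).** Same task, one block type, 50%
congruent, boosting keyed per stimulus — *proactively*: the decision for
trial n reads the boost values of the stimulus seen on trial n−1 (the
representation still active when effort for the upcoming trial is
mobilised), while the outcome updates the current stimulus's values. This
timing is essential: if decision and update use the same state, a
stimulus's value is identical whether its last occurrence was one or many
trials back, and no trial-to-trial modulation can arise (we verified the
contrast is then statistically zero). With proactive keying the Gratton
interaction is ≈ 0.07 at baseline. At `α = 0.01` it shrinks to ≈ 0.02 —
strongly reduced but, in our implementation, still detectably positive,
because even slow learning differentiates the two stimuli's values late in
a 200-trial block. With two stimuli, previous congruency is confounded with
stimulus repetition; the contrast is computed over all trials (first trial
excluded) without repetition exclusion.

**T-maze effort discounting (sim 4).** Arms are trained one at a time (100
shuffled trials each, always with an intact system); all three actions
(go-left, stay, go-right) compete in the softmax on every trial. Barrier
matrix `[[10, 0.01, 0], [0, 0.8, 1]]`, no-barrier matrix
`[[10, 0.01, 0], [0, 0.01, 10]]` (rows LR/HR, columns left/stay/right).
With the barrier, the unboosted success of the HR arm is
`e^1/(e^0 + e^0.8 + e^1) = 0.457`, so its unboosted expected value
(2 × 0.457 = 0.91) falls below the LR arm's (1 × 0.9999) — the closed-form
reversal condition checked at `MazeSpec` construction — while boosted
success (0.88) makes the HR arm worth 1.76. The preference probe is a
softmax (`γ = 3`) over `V(arm)` for the intact model and over
`Q(arm, NoBoost)` for the dopamine-lesioned model, which is exactly the
value mixture `Pr(B)·Q(B) + Pr(NB)·Q(NB)` collapsed onto its unboosted
branch. Hence the 2×2 pattern: everyone takes the HR arm without a
barrier; with a barrier only the lesioned model avoids it.

**Variable-interval schedule (sim 5).** A session is a stream of 200
discrete pressing opportunities; the boosting state is the delay since the
last press (tapped delay line, 10 taps). Press probability is
`logistic(gain + bias)` with `bias = −3` (withhold unless boosted), option
gain `γ = 6`. Reinforcement arms with per-step probability `p` and, by
default, waits until collected by the next press (standard variable-interval
arming; a non-persisting variant is available). Costs: the generic effort
cost 0.2 on every boost, plus a fast-pressing surcharge (`press_cost`,
default 4.5 — the midpoint of the 0–9 manipulation) when boosting at the
minimum inter-press delay of 1. The last 50 opportunities are scored:
response rate and obtained reinforcement rate are counts over that window,
and runs are maximal constant bouts of the respond/withhold sequence
(ceiling 50; strict alternation 50, pressing throughout 1). The session is
deliberately structured so that "respond vs. withhold" is meaningful per
opportunity — with multi-step trials every trial contains presses and run
counts degenerate to 1.

With high reward and the default surcharge, the model learns not to boost
at delay 1 but to boost right after, producing near-alternation (≈ 43 runs)
and a response-rate curve that rises and saturates in the obtained
reinforcement rate; the constrained hyperbola `z = a1·x/(1 + a2·x)` fits it
with R² ≈ 0.59 (100 runs per p level). At reward 0.3 boosting barely pays,
the curve stays close to the floor set by the withholding bias and the
boost floor `logistic(−γ·c) ≈ 0.23`, and the origin-constrained hyperbola
fits poorly (R² ≈ −0.1): the fit's R² is dominated by the nonzero response
rate at `p = 0`, which a hyperbola through the origin cannot reproduce.
This floor is a structural property of zero-initialized tabular values
under the stated parameters, not a tunable artefact.

## Numerical choices

- Softmaxes subtract the row maximum before exponentiation (gain 10 ×
  weight 5 = exponent 50 overflows a naive evaluation); two-option
  softmaxes use the logistic of the value difference.
- `Q` and `V` initialize to 0; missing table entries read 0.
- Within-trial event order: option → gain → action → feedback → update.
- The hyperbolic fit is nonlinear least squares with `a1, a2 ≥ 0`,
  initialized from the best line through the origin plus multi-start over
  `a2 ∈ {0, 0.1, 1, 10}`; R² = 1 − SS_res/SS_tot about the mean of z and
  may be negative. All-equal z is rejected (R² undefined).
- Bootstrap CIs are percentile CIs over replications (2000 resamples,
  internally seeded, so repeated analyses are reproducible).
- Replications run as vectorized columns of one seeded substream per
  simulation/grid cell (`numpy` `SeedSequence.spawn`), making every result
  a pure function of (configuration, master seed) and independent of cell
  execution order.

## Replication counts and problem sizes

Defaults follow the stated protocols: 1000 replications for effort
allocation (tests use 200 per grid point), 100 replications of 200-trial
blocks for the congruency protocols, 100 replications of 200 training
trials for the T-maze, and 100 runs per reinforcement-probability level
(51 levels) for the schedule. The full test suite runs in well under a
minute because the replication axis is vectorized.

## What the simulations do and do not show

All inputs are model-generated; there is no empirical data path. The
simulated tasks are deliberately minimal stimulus-action matrices: two
stimuli stand in for whole congruency paradigms, and a three-column matrix
for a T-maze. Passing tests therefore show that the *mechanism* produces
the qualitative phenomena (reward/cost/difficulty trade-offs, proactive and
reactive control, lesion-induced effort discounting, hyperbolic rate
curves) under the stated parameters — not that the model fits any
particular dataset quantitatively. Response times are not modelled
(accuracy only), boosting is binary rather than graded, the indirect
basal-ganglia pathway is not implemented, and values are tabular (no
generalization across states).
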