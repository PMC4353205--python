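"""The five experiment protocols, plus a two-axis parameter-sweep driver.

Each simulation composes the limbic-loop primitives (:mod:`effortrl.core`)
with a task-specific weight matrix, presentation schedule and recording rule:

* Sim 1 — effort allocation for rewarded arithmetic-like stimuli as a
  function of boost cost (1a) and task difficulty (1b).
* Sim 2 — blockwise proportion-congruency effect: a block context unit
  learns whether boosting pays in mostly congruent vs mostly incongruent
  blocks.
* Sim 3 — sequential-congruency (Gratton) effect: per-stimulus boost values
  updated trial-to-trial.
* Sim 4 — T-maze effort discounting with a dopamine-lesioned preference
  stage.
* Sim 5 — variable-interval free-operant schedule with a tapped delay line,
  producing hyperbolic response-rate curves.

All simulations are replicated; the replication axis is vectorized with
numpy, with one seeded substream per grid cell so results are independent of
execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import metrics as _metrics
from .core import (
    BOOST,
    NOBOOST,
    ModelParams,
    TaskSpec,
    success_probability,
)

__all__ = [
    "BlockSpec",
    "MazeSpec",
    "ScheduleSpec",
    "Sim1Result",
    "CongruencyResult",
    "MazeResult",
    "Sim5Result",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "run_sim4",
    "run_sim5",
    "run_sweep",
    "default_p_grid",
]

# Default "sufficiently high" weight of the easy stimulus on its correct
# action: guarantees near-ceiling success without boosting.
EASY_WEIGHT: float = 5.0


# ---------------------------------------------------------------------------
# batch engine
# ---------------------------------------------------------------------------

def _spawn(seed_or_rng, n: int) -> List[np.random.Generator]:
    """n independent child generators from a seed or SeedSequence/Generator."""
    if isinstance(seed_or_rng, np.random.SeedSequence):
        ss = seed_or_rng
    elif isinstance(seed_or_rng, np.random.Generator):
        ss = seed_or_rng.bit_generator.seed_seq
    else:
        ss = np.random.SeedSequence(int(seed_or_rng))
    return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass
class _BlockArrays:
    """Raw per-trial arrays from one vectorized block run (trial x rep)."""

    stim: np.ndarray
    boosted: np.ndarray
    correct: np.ndarray
    q_final: np.ndarray  # (rep, state, option)
    v_final: np.ndarray  # (rep, state)
    gain_boost: float
    gain_noboost: float

    @property
    def gain(self) -> np.ndarray:
        return np.where(self.boosted, self.gain_boost, self.gain_noboost)


def _run_block(
    task: TaskSpec,
    params: ModelParams,
    n_trials: int,
    n_reps: int,
    rng: np.random.Generator,
    stim_seq: Optional[np.ndarray] = None,
    stim_probs: Optional[np.ndarray] = None,
    proactive: bool = False,
) -> _BlockArrays:
    """Vectorized block of trials (replications in parallel).

    The boosting state is derived from ``task.state_key``: one state per
    stimulus, or a single always-active context unit.  Q and V start at 0.

    With ``proactive=True`` the boost decision on trial n reads the Q-values
    of the *previous* trial's state (the stimulus representation still active
    when effort for the upcoming trial is mobilised), while the outcome
    update still credits the current trial's state.  This is what produces
    trial-to-trial (reactive control) adaptation; with decision and update
    keyed to the same state, a stimulus's boost value is identical whether
    its last occurrence was one or many trials ago, and no sequential
    modulation can arise.
    """
    S = task.n_stimuli
    if stim_seq is None:
        probs = (
            np.asarray(stim_probs, dtype=float)
            if stim_probs is not None
            else np.full(S, 1.0 / S)
        )
        edges = np.cumsum(probs)
        edges[-1] = 1.0
        stim_seq = np.searchsorted(edges, rng.random((n_trials, n_reps)), side="right")
    else:
        stim_seq = np.asarray(stim_seq, dtype=int)
        if stim_seq.shape != (n_trials, n_reps):
            raise ValueError("stim_seq must have shape (n_trials, n_reps)")

    if task.state_key == "context":
        n_states = 1
        state_of_stim = np.zeros(S, dtype=int)
    elif task.state_key == "stimulus":
        n_states = S
        state_of_stim = np.arange(S)
    else:
        raise ValueError(f"state_key {task.state_key!r} not supported by _run_block")

    # success probabilities only depend on (stimulus, gain); precompute both
    p_succ = np.empty((S, 2))
    for s in range(S):
        p_succ[s, 0] = success_probability(task, s, params.gain_noboost)
        p_succ[s, 1] = success_probability(task, s, params.gain_boost)

    rows = np.arange(n_reps)
    Q = np.zeros((n_reps, n_states, 2))
    V = np.zeros((n_reps, n_states))
    boosted_out = np.empty((n_trials, n_reps), dtype=bool)
    correct_out = np.empty((n_trials, n_reps), dtype=bool)

    u = rng.random((n_trials, 2, n_reps))  # option draw, action draw per trial
    for t in range(n_trials):
        stim = stim_seq[t]
        state = state_of_stim[stim]
        decision_state = state_of_stim[stim_seq[t - 1]] if (proactive and t > 0) else state
        p_boost = expit(
            params.gamma * (Q[rows, decision_state, BOOST] - Q[rows, decision_state, NOBOOST])
        )
        boosted = u[t, 0] < p_boost
        correct = u[t, 1] < p_succ[stim, boosted.astype(int)]
        reward = np.where(correct, task.reward[stim], 0.0)
        cost = np.where(boosted, params.cost, 0.0)
        net = reward - cost
        opt = boosted.astype(int)
        Q[rows, state, opt] += params.alpha * (net - Q[rows, state, opt])
        V[rows, state] += params.alpha * (net - V[rows, state])
        boosted_out[t] = boosted
        correct_out[t] = correct
    return _BlockArrays(
        stim=stim_seq,
        boosted=boosted_out,
        correct=correct_out,
        q_final=Q,
        v_final=V,
        gain_boost=params.gain_boost,
        gain_noboost=params.gain_noboost,
    )


def _cell_mean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-replication mean of ``values`` over trials selected by ``mask``."""
    cnt = mask.sum(axis=0)
    s = np.where(mask, values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = s / cnt
    out[cnt == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Simulation 1: effort allocation
# ---------------------------------------------------------------------------

@dataclass
class Sim1Result:
    """Per-replication activation and accuracy over the swept grid."""

    variant: str
    param_name: str
    df: pd.DataFrame  # columns: value, replication, stimulus, reward, mean_activation, accuracy

    def summary(self) -> pd.DataFrame:
        g = self.df.groupby(["value", "stimulus", "reward"], as_index=False).agg(
            mean_activation=("mean_activation", "mean"),
            accuracy=("accuracy", "mean"),
            n_reps=("replication", "size"),
        )
        return g


def sim1_task(
    variant: str,
    delta: float = 0.8,
    rewards: Optional[Sequence[float]] = None,
) -> TaskSpec:
    """Two difficult stimuli sharing the confusable action row [0, 1, delta].

    The correct action (column 1) competes with a confusable alternative of
    weight ``delta``; rewards default to (1.5, 2) for variant 1a and (1, 2)
    for 1b.
    """
    if rewards is None:
        rewards = (1.5, 2.0) if variant == "1a" else (1.0, 2.0)
    row = [0.0, 1.0, float(delta)]
    return TaskSpec(
        weights=np.array([row, row]),
        correct_action=np.array([1, 1]),
        reward=np.asarray(rewards, dtype=float),
        state_key="stimulus",
    )


def run_sim1(
    variant: str,
    sweep: Sequence[float],
    params: Optional[ModelParams] = None,
    rng=None,
    rewards: Optional[Sequence[float]] = None,
) -> Sim1Result:
    """Sweep boost cost (variant "1a") or difficulty delta ("1b").

    For each grid point the model runs ``n_train`` training trials followed
    by ``n_test`` recorded trials; mean ACC activation (the applied gain) and
    accuracy are reported per stimulus and replication.
    """
    if variant not in ("1a", "1b"):
        raise ValueError("variant must be '1a' or '1b'")
    params = params or ModelParams()
    sweep = np.asarray(sweep, dtype=float)
    if variant == "1a" and (sweep.min() < 0 or sweep.max() > 0.8):
        warnings.warn("cost grid outside the standard [0, 0.8] range")
    if variant == "1b" and (sweep.min() < 0 or sweep.max() > 1):
        warnings.warn("difficulty grid outside the standard [0, 1] range")
    gens = _spawn(params.seed if rng is None else rng, len(sweep))
    frames = []
    n_tot = params.n_train + params.n_test
    for value, g in zip(sweep, gens):
        if variant == "1a":
            task = sim1_task("1a", rewards=rewards)
            p = params.replace(cost=float(value))
        else:
            task = sim1_task("1b", delta=float(value), rewards=rewards)
            p = params
        block = _run_block(task, p, n_tot, p.n_reps, g)
        test = slice(p.n_train, n_tot)
        gain = block.gain[test]
        stim = block.stim[test]
        correct = block.correct[test]
        for s in range(task.n_stimuli):
            mask = stim == s
            frames.append(
                pd.DataFrame(
                    {
                        "value": value,
                        "replication": np.arange(p.n_reps),
                        "stimulus": s,
                        "reward": task.reward[s],
                        "mean_activation": _cell_mean(gain, mask),
                        "accuracy": _cell_mean(correct.astype(float), mask),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    return Sim1Result(
        variant=variant,
        param_name="cost" if variant == "1a" else "delta",
        df=df,
    )


# ---------------------------------------------------------------------------
# Simulations 2 and 3: congruency effects
# ---------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """One conflict-task block: composition and boosting context."""

    block_type: str  # "MC" | "MI" | "neutral"
    n_trials: int = 200
    proportion_easy: float = 0.5
    context: Optional[object] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion_easy <= 1.0):
            raise ValueError("proportion_easy must be in [0, 1]")
        if self.block_type not in ("MC", "MI", "neutral"):
            raise ValueError(f"unknown block type {self.block_type!r}")


def conflict_task(
    delta: float,
    reward_difficult: float,
    state_key: str,
    pathway_strength: float = EASY_WEIGHT,
) -> TaskSpec:
    """2x2 conflict mapping [[w, 0], [delta*w, w]] with pathway strength w.

    Stimulus 0 (congruent/easy) maps cleanly onto action 0; stimulus 1
    (incongruent/difficult) has its correct action 1 shadowed by a competing
    weight ``delta*w`` on the wrong action.  ``delta`` (relative
    confusability, in [0, 1)) must stay < 1 so the correct response remains
    the more likely one.  The overall pathway strength ``w`` is set high
    enough that congruent stimuli succeed without boosting (unboosted
    congruent accuracy logistic(w) ~ 0.99 at the default w=5), mirroring
    empirical congruent accuracies; with w=1 the unboosted congruent
    accuracy would be only 0.73 and boosting would pay in every block,
    washing out the block and sequential effects.
    """
    if not (0.0 <= delta < 1.0):
        raise ValueError(
            f"delta must be in [0, 1) so the correct action stays maximal, got {delta}"
        )
    w = float(pathway_strength)
    return TaskSpec(
        weights=np.array([[w, 0.0], [float(delta) * w, w]]),
        correct_action=np.array([0, 1]),
        reward=np.array([1.0, float(reward_difficult)]),
        state_key=state_key,
    )


@dataclass
class CongruencyResult:
    """Trial table, per-replication cell accuracies and headline contrasts."""

    trials: pd.DataFrame
    cells: pd.DataFrame
    accuracy: float
    congruency_effect: float
    congruency_ci: Tuple[float, float]
    contrast: _metrics.ContrastResult
    contrast_name: str

    def metrics_dict(self) -> Dict[str, Dict[str, float]]:
        out = {
            "accuracy": {"value": self.accuracy},
            "congruency_effect": {
                "value": self.congruency_effect,
                "ci_low": self.congruency_ci[0],
                "ci_high": self.congruency_ci[1],
                "n": self.contrast.n_replications,
            },
            self.contrast_name: self.contrast.as_dict(),
        }
        return out


_CONGRUENCY = np.array(["congruent", "incongruent"])


def _sample_actions(
    block: _BlockArrays, task: TaskSpec, rng: np.random.Generator
) -> np.ndarray:
    """Concrete action identities consistent with the recorded correctness.

    Correct trials took the stimulus's correct action; error trials sample
    among the wrong actions with the gain-modulated softmax renormalized over
    errors.
    """
    from .core import action_probabilities

    S, K = task.weights.shape
    # wrong-action CDFs per (stimulus, boosted)
    wrong_cdf = np.zeros((S, 2, K))
    for s in range(S):
        for b, gain in enumerate((block.gain_noboost, block.gain_boost)):
            p = action_probabilities(task.weights[s], gain)
            p[task.correct_action[s]] = 0.0
            tot = p.sum()
            wrong_cdf[s, b] = np.cumsum(p / tot) if tot > 0 else np.cumsum(
                np.full(K, 1.0 / K)
            )
    actions = task.correct_action[block.stim].copy()
    err = ~block.correct
    if err.any():
        u = rng.random(block.stim.shape)
        cdf = wrong_cdf[block.stim, block.boosted.astype(int)]
        sampled = (u[..., None] > cdf).sum(axis=-1)
        actions[err] = sampled[err]
    return actions


def _block_trials_frame(
    block: _BlockArrays,
    task: TaskSpec,
    params: ModelParams,
    block_id: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_trials, n_reps = block.stim.shape
    rep, tr = np.meshgrid(np.arange(n_reps), np.arange(n_trials))
    congr = _CONGRUENCY[block.stim]
    prev = np.full(congr.shape, None, dtype=object)
    prev[1:] = congr[:-1]
    state = (
        np.full(block.stim.shape, "context")
        if task.state_key == "context"
        else block.stim
    )
    actions = _sample_actions(block, task, rng)
    reward = np.where(block.correct, task.reward[block.stim], 0.0)
    cost = np.where(block.boosted, params.cost, 0.0)
    return pd.DataFrame(
        {
            "replication": rep.ravel(),
            "block": block_id,
            "trial": tr.ravel(),
            "state": np.asarray(state).ravel(),
            "stimulus": block.stim.ravel(),
            "boosted": block.boosted.ravel(),
            "acc_gain": block.gain.ravel(),
            "action": actions.ravel(),
            "correct": block.correct.ravel(),
            "reward": reward.ravel(),
            "cost_incurred": cost.ravel(),
            "congruency": congr.ravel(),
            "prev_congruency": prev.ravel(),
        }
    )


def run_sim2(
    params: Optional[ModelParams] = None,
    reward_difficult: float = 2.0,
    delta: float = 0.8,
    rng=None,
    n_trials: int = 200,
    n_reps: int = 100,
) -> CongruencyResult:
    """Proportion-congruency protocol.

    Each replication runs one mostly congruent block (80% easy stimuli) and
    one mostly incongruent block (20% easy), 200 trials each.  Boosting is
    governed by a single block-context unit whose Q-values start fresh in
    every block, so only the block (not the stimulus) determines effort.
    """
    params = params or ModelParams()
    task = conflict_task(delta, reward_difficult, state_key="context")
    g_mc, g_mi, g_act = _spawn(params.seed if rng is None else rng, 3)
    mc = _run_block(task, params, n_trials, n_reps, g_mc, stim_probs=np.array([0.8, 0.2]))
    mi = _run_block(task, params, n_trials, n_reps, g_mi, stim_probs=np.array([0.2, 0.8]))

    cells = pd.DataFrame(
        {
            "MC_c": _cell_mean(mc.correct.astype(float), mc.stim == 0),
            "MC_i": _cell_mean(mc.correct.astype(float), mc.stim == 1),
            "MI_c": _cell_mean(mi.correct.astype(float), mi.stim == 0),
            "MI_i": _cell_mean(mi.correct.astype(float), mi.stim == 1),
        }
    )
    contrast = _metrics.pc_contrast(cells)
    ce_per_rep = 0.5 * (cells["MC_c"] - cells["MC_i"]) + 0.5 * (
        cells["MI_c"] - cells["MI_i"]
    )
    trials = pd.concat(
        [
            _block_trials_frame(mc, task, params, "MC", g_act),
            _block_trials_frame(mi, task, params, "MI", g_act),
        ],
        ignore_index=True,
    )
    return CongruencyResult(
        trials=trials,
        cells=cells,
        accuracy=float(trials["correct"].mean()),
        congruency_effect=float(ce_per_rep.mean()),
        congruency_ci=_metrics.bootstrap_ci(ce_per_rep.to_numpy()),
        contrast=contrast,
        contrast_name="pc_contrast",
    )


def run_sim3(
    params: Optional[ModelParams] = None,
    reward_difficult: float = 2.0,
    delta: float = 0.8,
    rng=None,
    n_trials: int = 200,
    n_reps: int = 100,
) -> CongruencyResult:
    """Sequential-congruency protocol.

    Single block type, 50% congruent stimuli; the stimulus (not a block
    context) keys the boosting decision.  Effort for a trial is mobilised
    proactively, from the boost value of the stimulus seen on the previous
    trial, while outcomes credit the current stimulus — so a difficult
    previous trial raises the odds of boosting now, shrinking the congruency
    effect after incongruent trials (the Gratton pattern).  The first trial
    has no predecessor and is excluded from the contrast.
    """
    params = params or ModelParams()
    task = conflict_task(delta, reward_difficult, state_key="stimulus")
    g, g_act = _spawn(params.seed if rng is None else rng, 2)
    block = _run_block(
        task, params, n_trials, n_reps, g, stim_probs=np.array([0.5, 0.5]), proactive=True
    )

    correct = block.correct.astype(float)
    cur = block.stim[1:]
    prev = block.stim[:-1]
    cells = pd.DataFrame(
        {
            "pC_c": _cell_mean(correct[1:], (prev == 0) & (cur == 0)),
            "pC_i": _cell_mean(correct[1:], (prev == 0) & (cur == 1)),
            "pI_c": _cell_mean(correct[1:], (prev == 1) & (cur == 0)),
            "pI_i": _cell_mean(correct[1:], (prev == 1) & (cur == 1)),
        }
    )
    contrast = _metrics.sequential_contrast(cells)
    acc_c = _cell_mean(correct, block.stim == 0)
    acc_i = _cell_mean(correct, block.stim == 1)
    ce_per_rep = acc_c - acc_i
    trials = _block_trials_frame(block, task, params, "single", g_act)
    return CongruencyResult(
        trials=trials,
        cells=cells,
        accuracy=float(trials["correct"].mean()),
        congruency_effect=float(np.nanmean(ce_per_rep)),
        congruency_ci=_metrics.bootstrap_ci(ce_per_rep),
        contrast=contrast,
        contrast_name="sequential_contrast",
    )


# ---------------------------------------------------------------------------
# Simulation 4: T-maze effort discounting
# ---------------------------------------------------------------------------

def _default_barrier_weights(delta: float = 0.8) -> np.ndarray:
    # columns: go-left, stay, go-right; rows: LR stimulus, HR stimulus
    return np.array([[10.0, 0.01, 0.0], [0.0, float(delta), 1.0]])


def _default_nobarrier_weights() -> np.ndarray:
    return np.array([[10.0, 0.01, 0.0], [0.0, 0.01, 10.0]])


@dataclass
class MazeSpec:
    """T-maze configuration: barrier, lesion, weight matrices, arm rewards.

    Column order is (go-left, stay, go-right); row order is (low-reward
    stimulus, high-reward stimulus).  With a barrier the high-reward arm's
    correct action only narrowly beats staying put, so success requires
    boosting; without a barrier the two arms are symmetric.
    """

    barrier: bool = True
    lesion: bool = False
    weights_barrier: np.ndarray = field(default_factory=_default_barrier_weights)
    weights_nobarrier: np.ndarray = field(default_factory=_default_nobarrier_weights)
    reward_lr: float = 1.0
    reward_hr: float = 2.0

    def task(self) -> TaskSpec:
        w = self.weights_barrier if self.barrier else self.weights_nobarrier
        return TaskSpec(
            weights=np.asarray(w, dtype=float),
            correct_action=np.array([0, 2]),
            reward=np.array([self.reward_lr, self.reward_hr]),
            state_key="stimulus",
        )

    def reversal_condition_holds(self, gain_noboost: float = 1.0) -> bool:
        """Closed-form check that an unboosted agent should avoid the HR arm.

        The preference reverses after lesion only if the unboosted expected
        value of the HR arm falls below that of the LR arm:
        ``reward_hr * sigma_hr < reward_lr * sigma_lr`` with sigma the
        unboosted success probability of each arm's correct action.
        """
        task = self.task()
        s_lr = success_probability(task, 0, gain_noboost)
        s_hr = success_probability(task, 1, gain_noboost)
        return self.reward_hr * s_hr < self.reward_lr * s_lr

    def __post_init__(self) -> None:
        self.weights_barrier = np.asarray(self.weights_barrier, dtype=float)
        self.weights_nobarrier = np.asarray(self.weights_nobarrier, dtype=float)
        for w in (self.weights_barrier, self.weights_nobarrier):
            if w.shape != (2, 3):
                raise ValueError("maze weight matrices must be 2x3")
        if self.barrier and not self.reversal_condition_holds():
            warnings.warn(
                "barrier matrix does not satisfy the reversal condition "
                "reward_hr*sigma_hr < reward_lr*sigma_lr; the lesioned "
                "preference reversal is not guaranteed"
            )


@dataclass
class MazeResult:
    """Preference for the high-reward arm after training."""

    pr_hr: float
    pr_hr_per_rep: np.ndarray
    barrier: bool
    lesion: bool

    def as_dict(self) -> Dict[str, float]:
        lo, hi = _metrics.bootstrap_ci(self.pr_hr_per_rep)
        return {
            "value": self.pr_hr,
            "ci_low": lo,
            "ci_high": hi,
            "n": int(self.pr_hr_per_rep.size),
        }


def run_sim4(
    maze: Optional[MazeSpec] = None,
    params: Optional[ModelParams] = None,
    rng=None,
    n_trials: int = 200,
    n_reps: int = 100,
) -> MazeResult:
    """T-maze effort-discounting protocol.

    Training (always with an intact system) presents one arm at a time —
    half the trials the low-reward arm, half the high-reward arm, shuffled —
    while the limbic loop learns Q(arm, option) and V(arm).  The preference
    probe is a softmax over the two arms' choice values: V(arm) for the
    intact model, Q(arm, NoBoost) for the dopamine-lesioned one.
    """
    maze = maze or MazeSpec()
    params = params or ModelParams()
    task = maze.task()
    (g,) = _spawn(params.seed if rng is None else rng, 1)
    # balanced, per-replication shuffled arm presentation
    half = n_trials // 2
    base = np.concatenate([np.zeros(half, dtype=int), np.ones(n_trials - half, dtype=int)])
    stim_seq = np.empty((n_trials, n_reps), dtype=int)
    for r in range(n_reps):
        stim_seq[:, r] = g.permutation(base)
    block = _run_block(task, params, n_trials, n_reps, g, stim_seq=stim_seq)
    if maze.lesion:
        v_lr = block.q_final[:, 0, NOBOOST]
        v_hr = block.q_final[:, 1, NOBOOST]
    else:
        v_lr = block.v_final[:, 0]
        v_hr = block.v_final[:, 1]
    pr = expit(params.gamma * (v_hr - v_lr))
    return MazeResult(
        pr_hr=float(pr.mean()),
        pr_hr_per_rep=pr,
        barrier=maze.barrier,
        lesion=maze.lesion,
    )


# ---------------------------------------------------------------------------
# Simulation 5: variable-interval schedule
# ---------------------------------------------------------------------------

@dataclass
class ScheduleSpec:
    """One variable-interval condition.

    A session is a stream of ``n_trials`` discrete pressing opportunities
    (trials); ``p`` is the per-trial probability that reinforcement becomes
    available (mean programmed inter-reinforcement interval 1/p).  With
    ``persist_reinforcement`` (the standard variable-interval arming rule)
    an available reinforcer waits until the next press collects it;
    otherwise it is lost if not pressed for on that trial.

    Pressing is gated by the limbic loop: press probability is
    ``logistic(acc_gain + bias)`` with a withholding bias of -3, so the
    unboosted press rate is ~0.12/trial and the boosted rate ~1.  The
    boosting state is the delay since the last press, capped at
    ``max_delay`` trials (tapped delay line).  Every boost incurs the
    generic effort cost; boosting at the minimum inter-press delay (1,
    i.e. pressing in consecutive trials) additionally incurs ``press_cost``,
    which is what makes strict alternation optimal when reward is high.
    Only the last ``n_recorded`` trials are scored, after learning has
    stabilised; run counts live on the recorded respond/withhold sequence,
    so their ceiling equals ``n_recorded``.
    """

    p: float
    reward: float = 2.1
    press_cost: float = 4.5
    n_trials: int = 200
    n_recorded: int = 50
    max_delay: int = 10
    bias: float = -3.0
    gamma: float = 6.0
    persist_reinforcement: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.max_delay < 1:
            raise ValueError("max_delay must be >= 1")
        if self.n_recorded > self.n_trials:
            raise ValueError("n_recorded cannot exceed n_trials")

    def _structure(self) -> tuple:
        return (
            self.reward,
            self.press_cost,
            self.n_trials,
            self.n_recorded,
            self.max_delay,
            self.bias,
            self.gamma,
            self.persist_reinforcement,
        )


@dataclass
class Sim5Result:
    """Response-rate curve (one row per p level) plus per-run arrays."""

    curve: pd.DataFrame  # p, response_rate, reinforcement_rate, runs
    per_run: pd.DataFrame  # p, run, response_rate, reinforcement_rate, runs

    def fit_hyperbola(self) -> _metrics.HyperbolicFit:
        """Hyperbolic fit of response rate vs obtained reinforcement rate."""
        return _metrics.fit_hyperbolic(
            self.curve["reinforcement_rate"].to_numpy(),
            self.curve["response_rate"].to_numpy(),
        )


def default_p_grid(step: float = 0.02) -> np.ndarray:
    """Reinforcement probabilities 0..1 inclusive at the given step."""
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def _run_schedule_batch(
    spec: ScheduleSpec,
    p_col: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Simulate one structural condition for many (p, run) columns at once.

    Response and reinforcement rates are counts over the recorded window;
    runs are maximal constant bouts of the recorded respond/withhold
    sequence.
    """
    ncol = p_col.size
    D = spec.max_delay
    alpha = params.alpha
    gb, gnb = params.gain_boost, params.gain_noboost
    Q = np.zeros((ncol, D, 2))
    delay = np.full(ncol, D - 1, dtype=int)  # 0-based; start "long since last press"
    cols = np.arange(ncol)
    pressed = np.zeros((spec.n_trials, ncol), dtype=bool)
    rewarded_hist = np.zeros((spec.n_trials, ncol), dtype=bool)
    armed = np.zeros(ncol, dtype=bool)
    u = rng.random((spec.n_trials, 3, ncol))
    for t in range(spec.n_trials):
        p_boost = expit(spec.gamma * (Q[cols, delay, BOOST] - Q[cols, delay, NOBOOST]))
        boost = u[t, 0] < p_boost
        gain = np.where(boost, gb, gnb)
        press = u[t, 1] < expit(gain + spec.bias)
        if spec.persist_reinforcement:
            armed |= u[t, 2] < p_col
            rewarded = press & armed
            armed &= ~press
        else:
            rewarded = press & (u[t, 2] < p_col)
        R = np.where(rewarded, spec.reward, 0.0)
        # generic effort cost on every boost, plus the fast-pressing
        # surcharge when boosting at the minimum inter-press delay
        cost = params.cost * boost + spec.press_cost * (boost & (delay == 0))
        net = R - cost
        opt = boost.astype(int)
        Q[cols, delay, opt] += alpha * (net - Q[cols, delay, opt])
        pressed[t] = press
        rewarded_hist[t] = rewarded
        delay = np.where(press, 0, np.minimum(delay + 1, D - 1))
    rec = slice(spec.n_trials - spec.n_recorded, spec.n_trials)
    seq = pressed[rec]
    runs = 1 + np.count_nonzero(seq[1:] != seq[:-1], axis=0)
    return {
        "response_rate": seq.sum(axis=0).astype(float),
        "reinforcement_rate": rewarded_hist[rec].sum(axis=0).astype(float),
        "runs": runs.astype(float),
    }


def run_sim5(
    schedules: Optional[Iterable[ScheduleSpec]] = None,
    params: Optional[ModelParams] = None,
    rng=None,
    n_runs: int = 100,
    reward: float = 2.1,
    press_cost: float = 4.5,
    p_values: Optional[Sequence[float]] = None,
) -> Sim5Result:
    """Variable-interval schedule over a grid of reinforcement probabilities.

    Either pass explicit ``schedules`` or let the standard grid be built from
    ``p_values`` (default 0..1 in steps of 0.02) at the given reward and
    press cost.  Each schedule is simulated for ``n_runs`` independent runs
    of ``n_trials`` pressing opportunities, scoring the last ``n_recorded``.
    """
    params = params or ModelParams()
    if schedules is None:
        if p_values is None:
            p_values = default_p_grid()
        schedules = [
            ScheduleSpec(p=float(p), reward=reward, press_cost=press_cost)
            for p in p_values
        ]
    schedules = list(schedules)
    # batch all schedules sharing structural parameters; p varies per column
    groups: Dict[tuple, List[int]] = {}
    for i, s in enumerate(schedules):
        groups.setdefault(s._structure(), []).append(i)
    gens = _spawn(params.seed if rng is None else rng, len(groups))
    rows = []
    per_run_rows = []
    for (key, idxs), g in zip(sorted(groups.items()), gens):
        spec = schedules[idxs[0]]
        p_col = np.repeat([schedules[i].p for i in idxs], n_runs)
        out = _run_schedule_batch(spec, p_col, params, g)
        for j, i in enumerate(idxs):
            sl = slice(j * n_runs, (j + 1) * n_runs)
            rows.append(
                (
                    schedules[i].p,
                    out["response_rate"][sl].mean(),
                    out["reinforcement_rate"][sl].mean(),
                    out["runs"][sl].mean(),
                )
            )
            per_run_rows.append(
                pd.DataFrame(
                    {
                        "p": schedules[i].p,
                        "run": np.arange(n_runs),
                        "response_rate": out["response_rate"][sl],
                        "reinforcement_rate": out["reinforcement_rate"][sl],
                        "runs": out["runs"][sl],
                    }
                )
            )
    curve = pd.DataFrame(
        rows, columns=["p", "response_rate", "reinforcement_rate", "runs"]
    ).sort_values("p", ignore_index=True)
    per_run = pd.concat(per_run_rows, ignore_index=True).sort_values(
        ["p", "run"], ignore_index=True
    )
    return Sim5Result(curve=curve, per_run=per_run)


# ---------------------------------------------------------------------------
# parameter sweeps (heat maps)
# ---------------------------------------------------------------------------

_SIM_AXES = {
    "sim1": {"reward_difficult", "delta", "alpha", "cost"},
    "sim2": {"reward_difficult", "delta", "alpha", "cost"},
    "sim3": {"reward_difficult", "delta", "alpha", "cost"},
    "sim4": {"reward_difficult", "delta", "alpha", "cost"},
    "sim5": {"reward", "press_cost"},
}


def _sweep_cell(
    sim: str,
    overrides: Dict[str, float],
    params: ModelParams,
    n_reps: int,
    seed_seq: np.random.SeedSequence,
) -> Dict[str, float]:
    p = params
    for name in ("alpha", "cost"):
        if name in overrides:
            p = p.replace(**{name: overrides[name]})
    reward_difficult = overrides.get("reward_difficult", 2.0)
    delta = overrides.get("delta", 0.8)
    if sim == "sim1":
        res = run_sim1(
            "1b",
            [delta],
            p.replace(n_reps=n_reps),
            rng=seed_seq,
            rewards=(1.0, reward_difficult),
        )
        s = res.summary()
        high = s[s["stimulus"] == 1].iloc[0]
        low = s[s["stimulus"] == 0].iloc[0]
        return {
            "mean_activation_high": float(high["mean_activation"]),
            "mean_activation_low": float(low["mean_activation"]),
            "accuracy": float(0.5 * (high["accuracy"] + low["accuracy"])),
        }
    if sim in ("sim2", "sim3"):
        runner = run_sim2 if sim == "sim2" else run_sim3
        res = runner(
            p, reward_difficult=reward_difficult, delta=delta, rng=seed_seq, n_reps=n_reps
        )
        return {
            "accuracy": res.accuracy,
            "congruency_effect": res.congruency_effect,
            res.contrast_name: res.contrast.value,
        }
    if sim == "sim4":
        out = {}
        children = seed_seq.spawn(4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # off-grid cells may fail the reversal check
            for (barrier, lesion), child in zip(
                [(False, False), (False, True), (True, False), (True, True)], children
            ):
                maze = MazeSpec(
                    barrier=barrier,
                    lesion=lesion,
                    weights_barrier=_default_barrier_weights(delta),
                    reward_hr=reward_difficult,
                )
                res = run_sim4(maze, p, rng=child, n_reps=n_reps)
                tag = ("barrier" if barrier else "nobarrier") + (
                    "_lesion" if lesion else "_intact"
                )
                out[f"pr_hr_{tag}"] = res.pr_hr
        out["interaction"] = (
            out["pr_hr_barrier_intact"] - out["pr_hr_barrier_lesion"]
        ) - (out["pr_hr_nobarrier_intact"] - out["pr_hr_nobarrier_lesion"])
        return out
    if sim == "sim5":
        res = run_sim5(
            params=p,
            rng=seed_seq,
            n_runs=n_reps,
            reward=overrides.get("reward", 2.1),
            press_cost=overrides.get("press_cost", 4.5),
        )
        return {
            "mean_runs": float(res.curve["runs"].mean()),
            "mean_response_rate": float(res.curve["response_rate"].mean()),
        }
    raise ValueError(f"unknown simulation {sim!r}")


def run_sweep(
    sim: str,
    axis1: Tuple[str, Sequence[float]],
    axis2: Tuple[str, Sequence[float]],
    params: Optional[ModelParams] = None,
    n_reps: Optional[int] = None,
    rng=None,
) -> pd.DataFrame:
    """Two-axis parameter sweep of a simulation's headline metrics.

    Axis names come from the simulation's parameter set (e.g.
    ``reward_difficult``, ``delta``, ``alpha``, ``cost``).  Returns a long
    DataFrame with columns ``axis1_name, axis1_value, axis2_name,
    axis2_value, metric_name, metric_value, n_reps``; each cell uses an
    independent seeded substream, so results do not depend on cell order.
    """
    params = params or ModelParams()
    if sim not in _SIM_AXES:
        raise ValueError(f"unknown simulation {sim!r}")
    name1, vals1 = axis1
    name2, vals2 = axis2
    for name in (name1, name2):
        if name not in _SIM_AXES[sim]:
            raise ValueError(f"axis {name!r} not valid for {sim}; choose from {sorted(_SIM_AXES[sim])}")
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if n_reps is None:
        n_reps = 100
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif isinstance(rng, np.random.Generator):
        ss = rng.bit_generator.seed_seq
    elif rng is None:
        ss = np.random.SeedSequence(params.seed)
    else:
        ss = np.random.SeedSequence(int(rng))
    children = ss.spawn(vals1.size * vals2.size)
    rows = []
    k = 0
    for v1 in vals1:
        for v2 in vals2:
            cell = _sweep_cell(sim, {name1: v1, name2: v2}, params, n_reps, children[k])
            k += 1
            for metric, value in cell.items():
                rows.append((name1, v1, name2, v2, metric, value, n_reps))
    return pd.DataFrame(
        rows,
        columns=[
            "axis1_name",
            "axis1_value",
            "axis2_name",
            "axis2_value",
            "metric_name",
            "metric_value",
            "n_reps",
        ],
    )
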