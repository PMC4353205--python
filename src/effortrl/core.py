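"""Core limbic-loop machinery.

The model separates *what to do* (a cortical stimulus->action pathway encoded
by a weight matrix ``w``) from *how hard to try* (a basal-ganglia "limbic
loop" through anterior cingulate cortex, ventral striatum, ventral pallidum
and thalamus that can *boost* the gain of that pathway).

On every trial:

1. ACC picks an option a in {Boost, NoBoost} by a softmax over learned
   Q(state, option) values with gain ``gamma``.
2. The loop converts the option into a multiplicative gain on the cortical
   pathway: ventral striatum activation is ``10*x_Boost + 1*x_NoBoost`` and is
   passed linearly through VP and thalamus back to ACC, so the applied gain is
   ``gain_boost`` (10) when boosting and ``gain_noboost`` (1) otherwise.
3. An overt action k is sampled with probability proportional to
   ``exp(gain * w[stimulus, k])`` — boosting raises the signal-to-noise ratio
   of the task pathway.
4. Reward R is delivered on correct responses; boosting incurs cost ``c``
   regardless of outcome.  Dopaminergic feedback updates the chosen option's
   Q-value (and the state value V) toward the net outcome ``R - c*x_cost``
   with learning rate ``alpha`` (generalized policy iteration; the update is
   Hebbian-local: only the visited state/option moves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "BOOST",
    "NOBOOST",
    "ModelParams",
    "TaskSpec",
    "OptionValueTable",
    "TrialRecord",
    "boost_probability",
    "choose_option",
    "loop_gain",
    "action_probabilities",
    "choose_action",
    "success_probability",
    "update_value",
    "run_trial",
    "lesioned_choice_value",
]

# Option codes. NOBOOST is 0 so a boolean "boosted" flag indexes option axes.
NOBOOST: int = 0
BOOST: int = 1


@dataclass
class ModelParams:
    """Learning and choice parameters of the limbic-loop model.

    Defaults are the baseline operating point used across the congruency and
    effort simulations: learning rate ``alpha=0.5``, option-choice gain
    ``gamma=3``, boost cost ``c=0.2``, and loop gains 10 (boost) / 1 (no
    boost).
    """

    alpha: float = 0.5
    gamma: float = 3.0
    cost: float = 0.2
    gain_boost: float = 10.0
    gain_noboost: float = 1.0
    n_train: int = 150
    n_test: int = 50
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (self.gamma >= 0.0):
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (self.cost >= 0.0):
            raise ValueError(f"cost must be >= 0, got {self.cost}")
        if not (self.gain_boost > self.gain_noboost > 0.0):
            raise ValueError(
                "gains must satisfy gain_boost > gain_noboost > 0, got "
                f"{self.gain_boost} and {self.gain_noboost}"
            )
        for name in ("n_train", "n_test", "n_reps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "ModelParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class TaskSpec:
    """A stimulus->action pathway plus rewards and state-keying rule.

    ``weights`` has one row per stimulus and one column per action; the
    correct action must carry the strictly largest weight in its row (the
    correct response stays more likely than the incorrect one, boosted or
    not).  ``state_key`` names the rule mapping a trial to the state whose
    Q-values govern the boosting decision: ``"stimulus"`` (one boosting state
    per stimulus), ``"context"`` (a single always-active block context unit)
    or ``"delay"`` (tapped delay line, free-operant schedule).
    """

    weights: np.ndarray
    correct_action: np.ndarray
    reward: np.ndarray
    state_key: str = "stimulus"
    schedule: Optional[np.ndarray] = None  # per-stimulus presentation probs

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.correct_action = np.atleast_1d(np.asarray(self.correct_action, dtype=int))
        self.reward = np.atleast_1d(np.asarray(self.reward, dtype=float))
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D (stimulus x action) matrix")
        n_stim, n_act = self.weights.shape
        if self.correct_action.shape != (n_stim,) or self.reward.shape != (n_stim,):
            raise ValueError("correct_action and reward need one entry per stimulus")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(self.reward < 0):
            raise ValueError("rewards must be non-negative")
        if np.any((self.correct_action < 0) | (self.correct_action >= n_act)):
            raise ValueError("correct_action indices out of range")
        if self.state_key not in ("stimulus", "context", "delay"):
            raise ValueError(f"unknown state_key {self.state_key!r}")
        for i in range(n_stim):
            row = self.weights[i]
            k = self.correct_action[i]
            others = np.delete(row, k)
            if others.size and row[k] <= others.max():
                raise ValueError(
                    f"stimulus {i}: correct action {k} must carry the strictly "
                    "largest weight in its row"
                )
        if self.schedule is not None:
            self.schedule = np.asarray(self.schedule, dtype=float)
            if self.schedule.shape != (n_stim,) or not np.isclose(self.schedule.sum(), 1.0):
                raise ValueError("schedule must be a probability vector over stimuli")

    @property
    def n_stimuli(self) -> int:
        return self.weights.shape[0]

    @property
    def n_actions(self) -> int:
        return self.weights.shape[1]


class OptionValueTable:
    """Tabular Q(state, option) and V(state) store; missing entries read 0."""

    def __init__(self) -> None:
        self._q: Dict[Tuple[object, int], float] = {}
        self._v: Dict[object, float] = {}

    def q(self, state: object, option: int) -> float:
        return self._q.get((state, option), 0.0)

    def set_q(self, state: object, option: int, value: float) -> None:
        self._q[(state, option)] = float(value)

    def v(self, state: object) -> float:
        return self._v.get(state, 0.0)

    def set_v(self, state: object, value: float) -> None:
        self._v[state] = float(value)

    def copy(self) -> "OptionValueTable":
        out = OptionValueTable()
        out._q = dict(self._q)
        out._v = dict(self._v)
        return out


@dataclass
class TrialRecord:
    """Everything recorded on one simulated trial."""

    replication: int
    block: object
    trial: int
    state: object
    stimulus: int
    boosted: bool
    acc_gain: float
    action: int
    correct: bool
    reward: float
    cost_incurred: float
    congruency: Optional[str] = None
    prev_congruency: Optional[str] = None


def boost_probability(q_boost: float, q_noboost: float, gamma: float) -> float:
    """Softmax probability of choosing Boost over NoBoost at gain gamma."""
    if not (np.isfinite(q_boost) and np.isfinite(q_noboost)):
        raise ValueError("Q-values must be finite")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    # two-option softmax reduces to a logistic in the value difference
    return float(expit(gamma * (q_boost - q_noboost)))


def choose_option(q_boost: float, q_noboost: float, gamma: float, rand: float) -> int:
    """Sample the Boost/NoBoost option; ``rand`` is a uniform [0,1) draw."""
    return BOOST if rand < boost_probability(q_boost, q_noboost, gamma) else NOBOOST


def loop_gain(
    option: int, gain_boost: float = 10.0, gain_noboost: float = 1.0
) -> float:
    """Gain applied to the task pathway for the chosen option.

    Ventral striatum activation is ``10*x_Boost + 1*x_NoBoost`` and is passed
    linearly through the VP->thalamus double inhibition (net identity), so the
    gain arriving back in ACC is simply ``gain_boost`` or ``gain_noboost``.
    """
    if option not in (BOOST, NOBOOST):
        raise ValueError(f"option must be BOOST or NOBOOST, got {option!r}")
    return float(gain_boost if option == BOOST else gain_noboost)


def action_probabilities(weight_row: np.ndarray, acc_gain: float) -> np.ndarray:
    """Gain-modulated softmax over actions: Pr(k) proportional to exp(g*w_k)."""
    weight_row = np.asarray(weight_row, dtype=float)
    if weight_row.ndim != 1 or weight_row.size == 0:
        raise ValueError("weight_row must be a non-empty vector")
    if not acc_gain > 0:
        raise ValueError("acc_gain must be positive")
    logits = acc_gain * weight_row
    logits -= logits.max()  # gain 10 x weight 5 would overflow otherwise
    p = np.exp(logits)
    return p / p.sum()


def choose_action(weight_row: np.ndarray, acc_gain: float, rand: float) -> int:
    """Sample an action index from the gain-modulated softmax."""
    p = action_probabilities(weight_row, acc_gain)
    return int(np.searchsorted(np.cumsum(p), rand, side="right"))


def success_probability(
    task: TaskSpec, stimulus: int, acc_gain: float
) -> float:
    """Probability of the correct action for a stimulus at a given gain."""
    p = action_probabilities(task.weights[stimulus], acc_gain)
    return float(p[task.correct_action[stimulus]])


def update_value(old: float, reward: float, cost_incurred: float, alpha: float) -> float:
    """Delta-rule update toward the net outcome: old + alpha*(R - cost - old)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    return old + alpha * (reward - cost_incurred - old)


def run_trial(
    state: object,
    stimulus: int,
    task: TaskSpec,
    params: ModelParams,
    tables: OptionValueTable,
    rng: np.random.Generator,
    replication: int = 0,
    block: object = 0,
    trial: int = 0,
) -> TrialRecord:
    """Run one trial: option -> gain -> action -> feedback -> update.

    Updates ``tables`` in place (Q of the chosen option and V of the state,
    both toward the same net outcome) and returns the trial record.
    """
    if not (0 <= stimulus < task.n_stimuli):
        raise KeyError(f"unknown stimulus {stimulus!r}")
    option = choose_option(
        tables.q(state, BOOST), tables.q(state, NOBOOST), params.gamma, rng.random()
    )
    gain = loop_gain(option, params.gain_boost, params.gain_noboost)
    action = choose_action(task.weights[stimulus], gain, rng.random())
    correct = action == task.correct_action[stimulus]
    reward = float(task.reward[stimulus]) if correct else 0.0
    cost_incurred = params.cost if option == BOOST else 0.0
    tables.set_q(
        state,
        option,
        update_value(tables.q(state, option), reward, cost_incurred, params.alpha),
    )
    tables.set_v(
        state, update_value(tables.v(state), reward, cost_incurred, params.alpha)
    )
    return TrialRecord(
        replication=replication,
        block=block,
        trial=trial,
        state=state,
        stimulus=int(stimulus),
        boosted=option == BOOST,
        acc_gain=gain,
        action=action,
        correct=bool(correct),
        reward=reward,
        cost_incurred=cost_incurred,
    )


def lesioned_choice_value(
    tables: OptionValueTable, state: object, lesioned: bool
) -> float:
    """Arm value used at the preference stage.

    The intact model evaluates a state by V(s).  With a dopamine-depleted
    limbic loop boosting is unavailable, so the evaluation collapses to
    Q(s, NoBoost).
    """
    return tables.q(state, NOBOOST) if lesioned else tables.v(state)
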