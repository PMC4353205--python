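"""Normative model of effort allocation.

An agent solving a task succeeds with probability ``effort / (difficulty +
effort)`` — a saturating return on invested effort — and pays a cost that is
linear in effort.  The expected utility of investing a given effort level is
therefore

    U(effort) = r * effort / (d + effort) - c * effort

with reward scale ``r``, cost scale ``c`` and task difficulty ``d``.  The
utility-maximising effort has the closed form

    effort* = max(0, sqrt(d * r / c) - d)

which is decreasing in cost, increasing in reward, and an inverted-U in
difficulty: very easy tasks succeed without effort, very hard tasks are not
worth the attempt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EffortEconomy", "utility", "optimal_effort", "optimal_surface"]


@dataclass(frozen=True)
class EffortEconomy:
    """Reward scale, cost scale and difficulty of a single task.

    Parameters
    ----------
    reward_scale : float
        Reward obtained on success, ``r >= 0``.
    cost_scale : float
        Linear effort cost per unit of effort, ``c > 0``.  A zero cost is
        rejected: optimal effort diverges.
    difficulty : float
        Difficulty ``d > 0``; success probability at effort e is
        ``e / (d + e)``.
    """

    reward_scale: float
    cost_scale: float
    difficulty: float

    def __post_init__(self) -> None:
        if not (self.reward_scale >= 0):
            raise ValueError(f"reward_scale must be >= 0, got {self.reward_scale}")
        if not (self.cost_scale > 0):
            raise ValueError(f"cost_scale must be > 0, got {self.cost_scale}")
        if not (self.difficulty > 0):
            raise ValueError(f"difficulty must be > 0, got {self.difficulty}")


def utility(effort: float, econ: EffortEconomy) -> float:
    """Expected utility ``r*e/(d+e) - c*e`` of investing effort ``e >= 0``."""
    effort = float(effort)
    if effort < 0:
        raise ValueError(f"effort must be non-negative, got {effort}")
    r, c, d = econ.reward_scale, econ.cost_scale, econ.difficulty
    return r * effort / (d + effort) - c * effort


def optimal_effort(econ: EffortEconomy) -> float:
    """Utility-maximising effort level, ``max(0, sqrt(d*r/c) - d)``.

    This is the unique stationary point of :func:`utility` on ``[0, inf)``,
    clamped to zero when even the stationary point has negative effort (the
    utility is then decreasing everywhere on the domain).
    """
    r, c, d = econ.reward_scale, econ.cost_scale, econ.difficulty
    return max(0.0, math.sqrt(d * r / c) - d)


def optimal_surface(
    r_values: Sequence[float],
    c_values: Sequence[float],
    d_values: Sequence[float],
) -> pd.DataFrame:
    """Optimal effort over a full (r, c, d) grid.

    Returns a DataFrame with one row per grid point and columns
    ``r, c, d, optimal_effort, utility_at_optimum``.
    """
    r_values = np.atleast_1d(np.asarray(r_values, dtype=float))
    c_values = np.atleast_1d(np.asarray(c_values, dtype=float))
    d_values = np.atleast_1d(np.asarray(d_values, dtype=float))
    if r_values.size == 0 or c_values.size == 0 or d_values.size == 0:
        raise ValueError("optimal_surface requires non-empty r, c and d grids")
    rows = []
    for r in r_values:
        for c in c_values:
            for d in d_values:
                econ = EffortEconomy(r, c, d)
                e_star = optimal_effort(econ)
                rows.append((r, c, d, e_star, utility(e_star, econ)))
    return pd.DataFrame(
        rows, columns=["r", "c", "d", "optimal_effort", "utility_at_optimum"]
    )
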