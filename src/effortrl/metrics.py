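"""Analysis statistics for simulated trial tables and response-rate curves.

Accuracies and congruency contrasts for the conflict-task simulations, the
softmax preference probability for the T-maze, run counting and the
hyperbolic response-rate fit for the free-operant schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "ContrastResult",
    "HyperbolicFit",
    "accuracy_stats",
    "bootstrap_ci",
    "contrast_from_cells",
    "pc_contrast",
    "sequential_contrast",
    "preference_prob",
    "count_runs",
    "fit_hyperbolic",
]


@dataclass
class ContrastResult:
    """A 2x2 interaction contrast over four cell accuracies.

    ``value = (cells[0] - cells[1]) - (cells[2] - cells[3])`` where the cells
    are grand means over replications; the CI is a percentile bootstrap over
    replications.
    """

    value: float
    cells: Tuple[float, float, float, float]
    cell_names: Tuple[str, str, str, str]
    ci_low: float
    ci_high: float
    n_replications: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_replications,
        }


@dataclass
class HyperbolicFit:
    """Fitted hyperbola z = a1*x / (1 + a2*x) with goodness of fit."""

    a1: float
    a2: float
    r_squared: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a1 * x / (1.0 + self.a2 * x)


def accuracy_stats(
    trials: pd.DataFrame, by: Optional[Sequence[str]] = None
) -> Dict[str, object]:
    """Per-condition accuracy means from a trial table.

    Returns ``{"overall": float, "by_condition": {label: mean or None}, and,
    when a ``congruency`` grouping is present, "congruency_effect"}``.
    Conditions with no trials are reported as ``None`` (missing), never as 0.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    out: Dict[str, object] = {"overall": float(trials["correct"].mean())}
    if by:
        grouped = trials.groupby(list(by), observed=True)["correct"].mean()
        out["by_condition"] = {k: float(v) for k, v in grouped.items()}
    if "congruency" in trials.columns:
        cond = trials.groupby("congruency", observed=True)["correct"].mean()
        acc_c = float(cond["congruent"]) if "congruent" in cond.index else None
        acc_i = float(cond["incongruent"]) if "incongruent" in cond.index else None
        out["acc_congruent"] = acc_c
        out["acc_incongruent"] = acc_i
        out["congruency_effect"] = (
            acc_c - acc_i if acc_c is not None and acc_i is not None else None
        )
    return out


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-replication values."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no finite values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def contrast_from_cells(
    cells: pd.DataFrame,
    cell_names: Sequence[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> ContrastResult:
    """Interaction contrast from per-replication cell accuracies.

    ``cells`` holds one row per replication and one column per cell, ordered
    so the contrast is ``(c0 - c1) - (c2 - c3)``.
    """
    cell_names = tuple(cell_names)
    if len(cell_names) != 4:
        raise ValueError("a 2x2 contrast needs exactly four cells")
    missing = [c for c in cell_names if c not in cells.columns]
    if missing:
        raise ValueError(f"missing contrast cells: {missing}")
    mat = cells[list(cell_names)].to_numpy(dtype=float)
    if np.isnan(mat).any():
        # a replication missing a cell cannot contribute to the contrast
        mat = mat[~np.isnan(mat).any(axis=1)]
    if mat.shape[0] == 0:
        raise ValueError("no replication has all four contrast cells")
    per_rep = (mat[:, 0] - mat[:, 1]) - (mat[:, 2] - mat[:, 3])
    means = mat.mean(axis=0)
    lo, hi = bootstrap_ci(per_rep, n_boot=n_boot, seed=seed)
    return ContrastResult(
        value=float((means[0] - means[1]) - (means[2] - means[3])),
        cells=tuple(float(m) for m in means),
        cell_names=cell_names,
        ci_low=lo,
        ci_high=hi,
        n_replications=mat.shape[0],
    )


def pc_contrast(cells: pd.DataFrame, n_boot: int = 2000, seed: int = 0) -> ContrastResult:
    """Proportion-congruency interaction (MC_c - MC_i) - (MI_c - MI_i).

    Positive values mean the congruency effect is smaller in mostly
    incongruent blocks (proactive control).
    """
    return contrast_from_cells(
        cells, ("MC_c", "MC_i", "MI_c", "MI_i"), n_boot=n_boot, seed=seed
    )


def sequential_contrast(
    cells: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> ContrastResult:
    """Sequential-congruency (Gratton) interaction (pC_c - pC_i) - (pI_c - pI_i).

    Cells are accuracies split by previous x current congruency; first trials
    (no predecessor) are excluded upstream.  Positive values mean the
    congruency effect shrinks after an incongruent trial (reactive control).
    """
    return contrast_from_cells(
        cells, ("pC_c", "pC_i", "pI_c", "pI_i"), n_boot=n_boot, seed=seed
    )


def sequential_cells_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-replication (previous x current) congruency cell accuracies.

    Expects columns ``replication, congruency, prev_congruency, correct``;
    rows without a previous trial must already be dropped or carry NaN.
    """
    t = trials.dropna(subset=["prev_congruency"])
    if t.empty:
        raise ValueError("no trials with a previous-trial congruency label")
    cell_of = {
        ("congruent", "congruent"): "pC_c",
        ("congruent", "incongruent"): "pC_i",
        ("incongruent", "congruent"): "pI_c",
        ("incongruent", "incongruent"): "pI_i",
    }
    labels = list(zip(t["prev_congruency"], t["congruency"]))
    t = t.assign(cell=[cell_of[k] for k in labels])
    cells = t.pivot_table(
        index="replication", columns="cell", values="correct", aggfunc="mean"
    )
    return cells


def preference_prob(value_hr: float, value_lr: float, gamma: float) -> float:
    """Softmax preference for the high-reward arm at choice gain gamma."""
    if not (np.isfinite(value_hr) and np.isfinite(value_lr)):
        raise ValueError("arm values must be finite")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(expit(gamma * (value_hr - value_lr)))


def count_runs(sequence) -> int:
    """Number of maximal constant bouts in a binary respond/withhold sequence.

    A run ends at every alternation, so the count is 1 + the number of
    adjacent unequal pairs: all-identical -> 1, strict alternation -> len.
    """
    seq = np.asarray(sequence)
    if seq.ndim != 1 or seq.size == 0:
        raise ValueError("sequence must be a non-empty 1-D array")
    return int(1 + np.count_nonzero(seq[1:] != seq[:-1]))


def _hyperbola(x: np.ndarray, a1: float, a2: float) -> np.ndarray:
    return a1 * x / (1.0 + a2 * x)


def fit_hyperbolic(x, z) -> HyperbolicFit:
    """Nonlinear least-squares fit of z = a1*x/(1+a2*x) with a1, a2 >= 0.

    Initialised from the best line through the origin (a1 = slope, a2 = 0)
    plus multi-start over a2 in {0, 0.1, 1, 10}.  R^2 is 1 - SS_res/SS_tot
    about the mean of z and may be negative for pathological data; the
    hyperbola has no intercept, so data with a nonzero offset fit poorly by
    design.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape or x.ndim != 1:
        raise ValueError("x and z must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit the hyperbola")
    if np.any(x < 0) or np.any(z < 0):
        raise ValueError("rates must be non-negative")
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("all z values equal; R^2 undefined")
    denom = float(np.sum(x * x))
    slope = float(np.sum(x * z) / denom) if denom > 0 else 1.0
    a1_0 = max(slope, 1e-8)
    best = None
    for a2_0 in (0.0, 0.1, 1.0, 10.0):
        try:
            popt, _ = curve_fit(
                _hyperbola,
                x,
                z,
                p0=[a1_0, max(a2_0, 1e-12)],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ss_res = float(np.sum((z - _hyperbola(x, *popt)) ** 2))
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
    if best is None:
        raise RuntimeError("hyperbolic fit failed to converge from all starts")
    (a1, a2), ss_res = best
    return HyperbolicFit(
        a1=float(a1),
        a2=float(a2),
        r_squared=1.0 - ss_res / ss_tot,
        n_points=int(x.size),
    )
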