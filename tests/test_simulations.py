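"""Experiment protocols: structural properties at reduced replication counts."""

import numpy as np
import pandas as pd
import pytest

from effortrl import (
    MazeSpec,
    ModelParams,
    ScheduleSpec,
    default_p_grid,
    run_sim1,
    run_sim2,
    run_sim3,
    run_sim4,
    run_sim5,
    run_sweep,
)
from effortrl.simulations import conflict_task, sim1_task


# ---------------------------------------------------------------------------
# Sim 1: effort allocation
# ---------------------------------------------------------------------------

def test_sim1_alpha_zero_activation_midpoint():
    """Without learning the options stay at Q=0 and are chosen 50/50, so the
    mean applied gain is (10+1)/2 = 5.5 in expectation."""
    params = ModelParams(alpha=0.0, n_reps=300, seed=5)
    res = run_sim1("1a", [0.2], params)
    act = res.df["mean_activation"].mean()
    assert act == pytest.approx(5.5, abs=0.15)


def test_sim1_zero_cost_reward_graded():
    """With free boosting, activation is reward-graded (higher reward, more
    boosting) and near the boost ceiling for both stimuli."""
    params = ModelParams(n_reps=300, seed=6)
    res = run_sim1("1a", [0.0], params)
    s = res.summary()
    low = s[s["reward"] == 1.5]["mean_activation"].iloc[0]
    high = s[s["reward"] == 2.0]["mean_activation"].iloc[0]
    assert high >= low
    assert high > 8.0


def test_sim1_warns_outside_declared_range():
    params = ModelParams(n_reps=10, seed=1)
    with pytest.warns(UserWarning):
        run_sim1("1a", [1.5], params)


def test_sim1_rejects_unknown_variant():
    with pytest.raises(ValueError):
        run_sim1("1c", [0.1], ModelParams(n_reps=5))


def test_sim1_determinism():
    params = ModelParams(n_reps=50, seed=11)
    a = run_sim1("1a", [0.2, 0.4], params).df
    b = run_sim1("1a", [0.2, 0.4], params).df
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Sims 2 and 3: congruency protocols
# ---------------------------------------------------------------------------

def test_conflict_task_delta_zero_symmetric():
    task = conflict_task(0.0, 1.0, "context")
    # rows are permutations of each other: both stimuli equally easy
    assert sorted(task.weights[0]) == sorted(task.weights[1])


def test_conflict_task_rejects_delta_one():
    with pytest.raises(ValueError):
        conflict_task(1.0, 2.0, "context")


def test_sim2_delta_zero_no_congruency_effect():
    res = run_sim2(ModelParams(seed=21), delta=0.0, n_reps=60)
    assert abs(res.congruency_effect) < 0.02
    assert res.congruency_ci[0] <= 0.0 <= res.congruency_ci[1] or abs(res.congruency_effect) < 0.01


def test_sim2_trial_table_schema():
    res = run_sim2(ModelParams(seed=22), n_reps=5)
    t = res.trials
    assert set(t["block"]) == {"MC", "MI"}
    assert len(t) == 5 * 200 * 2
    # easy stimuli dominate MC blocks and are rare in MI blocks
    frac_easy_mc = (t[t.block == "MC"].stimulus == 0).mean()
    frac_easy_mi = (t[t.block == "MI"].stimulus == 0).mean()
    assert frac_easy_mc > 0.7
    assert frac_easy_mi < 0.3
    # reward/cost bookkeeping matches the trial outcome columns
    correct = t["correct"].to_numpy()
    assert (t["reward"].to_numpy()[~correct] == 0).all()
    assert (t["cost_incurred"].to_numpy() == np.where(t["boosted"], 0.2, 0.0)).all()


def test_sim3_first_trial_excluded_from_contrast():
    res = run_sim3(ModelParams(seed=23), n_reps=5)
    first = res.trials[res.trials.trial == 0]
    assert first["prev_congruency"].isna().all()


def test_sim3_boosts_difficult_more_than_easy():
    """Per-stimulus boost values make boosting follow the difficult stimulus."""
    res = run_sim3(ModelParams(seed=24), n_reps=40)
    t = res.trials[res.trials.trial > 20]
    # proactive keying: boosting follows the PREVIOUS trial's stimulus
    prev_incongruent = t[t.prev_congruency == "incongruent"]["boosted"].mean()
    prev_congruent = t[t.prev_congruency == "congruent"]["boosted"].mean()
    assert prev_incongruent > prev_congruent + 0.1


# ---------------------------------------------------------------------------
# Sim 4: T-maze
# ---------------------------------------------------------------------------

def test_maze_default_satisfies_reversal_condition():
    maze = MazeSpec(barrier=True)
    assert maze.reversal_condition_holds()


def test_maze_reversal_condition_closed_form():
    # oracle: unboosted softmax success of each arm's correct action
    from effortrl import success_probability

    task = MazeSpec(barrier=True).task()
    s_lr = success_probability(task, 0, 1.0)
    s_hr = success_probability(task, 1, 1.0)
    assert 2.0 * s_hr < 1.0 * s_lr
    # and boosting rescues the high-reward arm
    s_hr_boost = success_probability(task, 1, 10.0)
    assert 2.0 * s_hr_boost > 1.0 * s_lr


def test_maze_warns_when_reversal_violated():
    with pytest.warns(UserWarning):
        MazeSpec(barrier=True, reward_hr=10.0)


def test_sim4_symmetric_arms_indifferent():
    maze = MazeSpec(barrier=False, lesion=False, reward_hr=1.0, reward_lr=1.0)
    res = run_sim4(maze, ModelParams(seed=31), n_reps=100)
    assert res.pr_hr == pytest.approx(0.5, abs=0.05)


def test_sim4_full_pattern_small():
    params = ModelParams(seed=32)
    out = {}
    for barrier in (False, True):
        for lesion in (False, True):
            res = run_sim4(MazeSpec(barrier=barrier, lesion=lesion), params, n_reps=60)
            out[(barrier, lesion)] = res.pr_hr
    assert out[(False, False)] > 0.5
    assert out[(False, True)] > 0.5
    assert out[(True, False)] > 0.5
    assert out[(True, True)] < 0.5


# ---------------------------------------------------------------------------
# Sim 5: variable-interval schedule
# ---------------------------------------------------------------------------

def test_schedule_spec_validation():
    with pytest.raises(ValueError):
        ScheduleSpec(p=1.2)
    with pytest.raises(ValueError):
        ScheduleSpec(p=0.5, max_delay=0)
    with pytest.raises(ValueError):
        ScheduleSpec(p=0.5, n_recorded=300)


def test_default_p_grid():
    g = default_p_grid()
    assert len(g) == 51
    assert g[0] == 0.0 and g[-1] == 1.0
    assert np.allclose(np.diff(g), 0.02)


def test_sim5_rate_rises_and_flattens():
    """Response rate is increasing in p and the top half of the curve gains
    less than the bottom half (the flattening the hyperbola captures)."""
    params = ModelParams(seed=41)
    res = run_sim5(params=params, n_runs=40, p_values=[0.0, 0.5, 1.0], reward=2.1)
    z = res.curve.sort_values("p")["response_rate"].to_numpy()
    assert z[0] < z[1] <= z[2] + 0.5
    assert (z[2] - z[1]) < (z[1] - z[0])


def test_sim5_reinforcement_rate_bounded_by_response_rate():
    res = run_sim5(params=ModelParams(seed=42), n_runs=20, p_values=[0.3, 0.9])
    c = res.curve
    assert (c["reinforcement_rate"] <= c["response_rate"] + 1e-9).all()
    assert (c["runs"] >= 1).all() and (c["runs"] <= 50).all()


def test_sim5_run_counts_track_press_cost():
    """No fast-press surcharge -> pressing every step (few runs); a steep
    surcharge -> near-strict alternation (runs near the 50 ceiling)."""
    params = ModelParams(seed=43)
    free = run_sim5(params=params, n_runs=30, p_values=[1.0], reward=2.1, press_cost=0.0)
    steep = run_sim5(params=params, n_runs=30, p_values=[1.0], reward=2.1, press_cost=9.0)
    assert free.curve["runs"].iloc[0] < 5
    assert steep.curve["runs"].iloc[0] > 40


def test_sim5_deterministic_given_seed():
    params = ModelParams(seed=44)
    a = run_sim5(params=params, n_runs=10, p_values=[0.2, 0.8]).curve
    b = run_sim5(params=params, n_runs=10, p_values=[0.2, 0.8]).curve
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def test_sweep_grid_shape_and_schema():
    df = run_sweep(
        "sim2",
        ("reward_difficult", [1.0, 2.0]),
        ("delta", [0.4, 0.8]),
        ModelParams(seed=51),
        n_reps=10,
    )
    cells = df[["axis1_value", "axis2_value"]].drop_duplicates()
    assert len(cells) == 4
    assert set(df.columns) == {
        "axis1_name",
        "axis1_value",
        "axis2_name",
        "axis2_value",
        "metric_name",
        "metric_value",
        "n_reps",
    }
    assert "pc_contrast" in set(df["metric_name"])


def test_sweep_degenerate_cell_matches_sim(baseline):
    """A 1x1 sweep reduces to the underlying simulation's metrics."""
    params = ModelParams(seed=52)
    df = run_sweep("sim3", ("alpha", [0.5]), ("delta", [0.8]), params, n_reps=30)
    sweep_val = df[df.metric_name == "sequential_contrast"]["metric_value"].iloc[0]
    assert np.isfinite(sweep_val)
    assert df["n_reps"].eq(30).all()


def test_sweep_alpha_zero_kills_learned_contrasts():
    df = run_sweep(
        "sim2", ("alpha", [0.0]), ("cost", [0.2]), ModelParams(seed=53), n_reps=40
    )
    pc = df[df.metric_name == "pc_contrast"]["metric_value"].iloc[0]
    assert abs(pc) < 0.03


def test_sweep_unknown_axis_rejected():
    with pytest.raises(ValueError):
        run_sweep("sim2", ("not_an_axis", [1]), ("delta", [0.5]), ModelParams())
    with pytest.raises(ValueError):
        run_sweep("sim9", ("alpha", [0.5]), ("delta", [0.5]), ModelParams())


def test_sweep_sim4_reward_below_lr_reverses_preference():
    """When the 'high reward' arm pays less than the low-reward arm, the
    intact model prefers the easy arm and the lesion interaction vanishes."""
    df = run_sweep(
        "sim4",
        ("reward_difficult", [0.5, 2.0]),
        ("cost", [0.2]),
        ModelParams(seed=54),
        n_reps=40,
    )
    lo = df[(df.axis1_value == 0.5) & (df.metric_name == "interaction")]["metric_value"].iloc[0]
    hi = df[(df.axis1_value == 2.0) & (df.metric_name == "interaction")]["metric_value"].iloc[0]
    pr_hi_lo = df[(df.axis1_value == 0.5) & (df.metric_name == "pr_hr_barrier_intact")]["metric_value"].iloc[0]
    assert hi > lo + 0.1
    assert pr_hi_lo < 0.5  # "HR" arm avoided when it pays less
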