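"""Per-subject scoring of the gamified cognitive tasks.

Turns trial-level tables into the per-participant objective cognition
scores used downstream:

* visual working memory — mean proportion of correctly recalled symbols
  per trial, ``n_correct / (n_correct + n_errors)``, averaged over the
  24 trials of the grid-search task;
* processing speed / cognitive flexibility — mean completion time of the
  A respectively B runs of the trail-making-style task, after censoring
  inattentively slow runs (>= 100 s for A, >= 300 s for B).

Also provides the exact chance-level accuracy of the grid-search task
under uniform random responding, computed by enumerating the absorbing
pick process (no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "TaskScore",
    "ChanceModel",
    "chance_accuracy",
    "score_memory_match",
    "score_star_racer",
    "score_cohort",
]

#: default censoring cut-offs, in seconds (runs at or above are dropped)
CUTOFF_A = 100.0
CUTOFF_B = 300.0


@dataclass(frozen=True)
class TaskScore:
    """One participant's score on one objective measure."""

    participant_id: str
    measure: Literal["visual_working_memory", "cognitive_flexibility", "processing_speed"]
    value: float
    n_units_used: int

    def __post_init__(self) -> None:
        if self.n_units_used < 1:
            raise ValueError("a score must be based on at least one trial/run")
        if self.measure == "visual_working_memory" and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"accuracy out of [0, 1]: {self.value}")
        if self.measure != "visual_working_memory" and self.value <= 0:
            raise ValueError(f"completion time must be positive: {self.value}")


@dataclass(frozen=True)
class ChanceModel:
    """Exact chance-level accuracy for one grid/set-size/lives combination."""

    grid_size: int
    set_size: int
    lives: int
    expected_accuracy: float


def chance_accuracy(grid_size: int, set_size: int, lives: int) -> float:
    """Expected proportion-correct under uniform random guessing.

    The guessing process picks uniformly without replacement among the
    unselected grid cells; a pick is correct with probability
    ``(k - c) / (G - c - e)`` from state ``(c, e)`` (targets found,
    errors made).  The trial absorbs when all ``k`` targets are found or
    all ``lives`` are lost, and the score of a trial is
    ``c / (c + e)`` at absorption.  The expectation is evaluated exactly
    over the finite absorbing Markov chain.

    Parameters
    ----------
    grid_size:
        Number of cells in the search display (20 for the 4 x 5 grid).
    set_size:
        Number of target symbols ``k``.
    lives:
        Number of errors allowed before the trial ends.
    """
    G, k, L = int(grid_size), int(set_size), int(lives)
    if not 1 <= k <= G:
        raise ValueError(f"set size must satisfy 1 <= k <= grid size, got k={k}, G={G}")
    if L < 1:
        raise ValueError(f"lives must be >= 1, got {L}")
    if k + L - 1 > G:
        # from state (k-1, L-1) one more pick must exist
        raise ValueError(
            f"grid can be exhausted before absorption (need k + lives - 1 <= G), "
            f"got k={k}, lives={L}, G={G}"
        )

    @lru_cache(maxsize=None)
    def expected(c: int, e: int) -> float:
        if c == k or e == L:
            return c / (c + e)
        remaining = G - c - e
        p_correct = (k - c) / remaining
        return p_correct * expected(c + 1, e) + (1.0 - p_correct) * expected(c, e + 1)

    return expected(0, 0)


def chance_model(grid_size: int, set_size: int, lives: int) -> ChanceModel:
    return ChanceModel(grid_size, set_size, lives, chance_accuracy(grid_size, set_size, lives))


def score_memory_match(
    trials: pd.DataFrame,
    method: Literal["trial_mean", "pooled"] = "trial_mean",
) -> TaskScore:
    """Score one participant's grid-search memory trials.

    ``trial_mean`` (default) averages the per-trial accuracies
    ``n_correct / (n_correct + n_errors)`` so every trial contributes
    equally regardless of set size; ``pooled`` instead pools counts
    across trials, ``sum(n_correct) / sum(n_correct + n_errors)``.
    """
    if len(trials) == 0:
        raise ValueError("cannot score an empty trial table")
    ids = trials["participant_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected a single participant, got {len(ids)}")
    guesses = trials["n_correct"].to_numpy() + trials["n_errors"].to_numpy()
    if (guesses == 0).any():
        raise ValueError(
            "trial with zero guesses; impossible under the stopping rule"
        )
    if method == "trial_mean":
        value = float(np.mean(trials["n_correct"].to_numpy() / guesses))
    elif method == "pooled":
        value = float(trials["n_correct"].sum() / guesses.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return TaskScore(str(ids[0]), "visual_working_memory", value, len(trials))


def score_star_racer(
    runs: pd.DataFrame,
    cutoff_a: float = CUTOFF_A,
    cutoff_b: float = CUTOFF_B,
) -> dict[str, TaskScore | None]:
    """Score one participant's A/B runs with inattention censoring.

    Runs with completion time at or above the cut-off ("100 or more
    seconds" for A, "300 or more" for B) are excluded; the score is the
    mean of the surviving runs.  If every run of a form is censored the
    form's score is ``None`` (flagged missing rather than imputed).

    Returns a mapping ``{"processing_speed": ..., "cognitive_flexibility": ...}``
    (A and B forms respectively).
    """
    ids = runs["participant_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected a single participant, got {len(ids)}")
    pid = str(ids[0])
    out: dict[str, TaskScore | None] = {}
    for form, cutoff, measure in (
        ("A", cutoff_a, "processing_speed"),
        ("B", cutoff_b, "cognitive_flexibility"),
    ):
        times = runs.loc[runs["form"] == form, "completion_time"].to_numpy(float)
        if len(times) == 0:
            raise ValueError(f"no runs for form {form}")
        kept = times[times < cutoff]
        if len(kept) == 0:
            out[measure] = None
        else:
            out[measure] = TaskScore(pid, measure, float(kept.mean()), int(len(kept)))
    return out


def score_cohort(
    memory_trials: pd.DataFrame,
    star_runs: pd.DataFrame,
    cutoff_a: float = CUTOFF_A,
    cutoff_b: float = CUTOFF_B,
    method: Literal["trial_mean", "pooled"] = "trial_mean",
) -> pd.DataFrame:
    """Score every participant; one row per participant.

    Missing (fully censored) flexibility or speed scores come back as NaN
    with ``n_runs_* = 0``.
    """
    rows = []
    star_by_pid = dict(tuple(star_runs.groupby("participant_id", sort=False)))
    for pid, trials in memory_trials.groupby("participant_id", sort=False):
        wm = score_memory_match(trials, method=method)
        row = {
            "participant_id": pid,
            "visual_working_memory": wm.value,
            "n_memory_trials": wm.n_units_used,
            "processing_speed": np.nan,
            "n_runs_a": 0,
            "cognitive_flexibility_time": np.nan,
            "n_runs_b": 0,
        }
        if pid in star_by_pid:
            scores = score_star_racer(star_by_pid[pid], cutoff_a, cutoff_b)
            ps, cf = scores["processing_speed"], scores["cognitive_flexibility"]
            if ps is not None:
                row["processing_speed"] = ps.value
                row["n_runs_a"] = ps.n_units_used
            if cf is not None:
                row["cognitive_flexibility_time"] = cf.value
                row["n_runs_b"] = cf.n_units_used
        rows.append(row)
    return pd.DataFrame(rows)
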