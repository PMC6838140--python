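"""Go/no-go gain/loss task design: conditions, schedules, probabilistic outcomes.

The task crosses required action (go vs. no-go) with outcome domain (gain
vs. loss avoidance) into four conditions. Each condition is presented
``n_per_condition`` times (60 in the original design, 240 trials total) in a
block-randomized order: every consecutive block of four trials contains each
condition exactly once. Feedback is probabilistic: the correct action yields
the domain's better outcome (+1 in gain, 0 in loss) with probability 0.8 and
the worse outcome otherwise; the incorrect action reverses the contingency.
Outcomes are coded {-1, 0, +1}; the monetary unit is absorbed into the
outcome-impact parameter rho of the learning models.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

__all__ = [
    "Action",
    "Domain",
    "Condition",
    "Schedule",
    "TrialRecord",
    "generate_schedule",
    "sample_outcome",
    "DataError",
]

#: Probability that the correct action delivers the domain's better outcome.
P_CORRECT_BETTER = 0.8


class DataError(ValueError):
    """Malformed trial data (bad schema, outcome outside domain support, ...)."""


class Action(IntEnum):
    NOGO = 0
    GO = 1


class Domain(IntEnum):
    GAIN = 0
    LOSS = 1


class Condition(IntEnum):
    """The four task conditions (also the stimulus identities)."""

    GO_GAIN = 0
    NOGO_GAIN = 1
    GO_AVOID = 2
    NOGO_AVOID = 3

    @property
    def domain(self) -> Domain:
        return Domain.GAIN if self in (Condition.GO_GAIN, Condition.NOGO_GAIN) else Domain.LOSS

    @property
    def correct_action(self) -> Action:
        return Action.GO if self in (Condition.GO_GAIN, Condition.GO_AVOID) else Action.NOGO

    @property
    def label(self) -> str:
        return _CONDITION_LABELS[self]


_CONDITION_LABELS = {
    Condition.GO_GAIN: "go_gain",
    Condition.NOGO_GAIN: "nogo_gain",
    Condition.GO_AVOID: "go_avoid",
    Condition.NOGO_AVOID: "nogo_avoid",
}
CONDITION_FROM_LABEL = {v: k for k, v in _CONDITION_LABELS.items()}
ACTION_FROM_LABEL = {"go": Action.GO, "nogo": Action.NOGO}
ACTION_LABELS = {v: k for k, v in ACTION_FROM_LABEL.items()}

#: (better, worse) coded outcome per domain.
DOMAIN_OUTCOMES = {Domain.GAIN: (1, 0), Domain.LOSS: (0, -1)}


@dataclass(frozen=True)
class TrialRecord:
    """One trial: condition shown, action taken, outcome received.

    ``index`` is 1-based, matching the on-disk CSV convention.
    """

    index: int
    condition: Condition
    action: Action
    outcome: int

    def __post_init__(self) -> None:
        better, worse = DOMAIN_OUTCOMES[self.condition.domain]
        if self.outcome not in (better, worse):
            raise DataError(
                f"trial {self.index}: outcome {self.outcome} outside support "
                f"{{{worse}, {better}}} of {self.condition.label}"
            )


@dataclass(frozen=True)
class Schedule:
    """Ordered condition sequence with block-randomized structure."""

    conditions: tuple[Condition, ...]
    n_per_condition: int

    def __len__(self) -> int:
        return len(self.conditions)

    def validate(self) -> None:
        if len(self.conditions) != 4 * self.n_per_condition:
            raise ValueError("schedule length must be 4 * n_per_condition")
        for b in range(self.n_per_condition):
            block = self.conditions[4 * b : 4 * b + 4]
            if sorted(block) != list(Condition):
                raise ValueError(f"block {b} is not a permutation of the 4 conditions")


def generate_schedule(n_per_condition: int, seed: int) -> Schedule:
    """Build a block-randomized schedule of ``4 * n_per_condition`` trials.

    Each block of four consecutive trials is an independent uniform
    permutation of the four conditions, so every condition appears exactly
    ``n_per_condition`` times. Deterministic given ``seed``.
    """
    if n_per_condition < 1:
        raise ValueError(f"n_per_condition must be >= 1, got {n_per_condition}")
    rng = np.random.default_rng(seed)
    order: list[Condition] = []
    for _ in range(n_per_condition):
        order.extend(Condition(i) for i in rng.permutation(4))
    return Schedule(conditions=tuple(order), n_per_condition=n_per_condition)


def sample_outcome(condition: Condition, action: Action, rng: np.random.Generator) -> int:
    """Sample the coded outcome of taking ``action`` in ``condition``.

    The correct action yields the domain's better outcome with probability
    0.8; the incorrect action yields it with probability 0.2.
    """
    condition = Condition(condition)
    action = Action(action)
    better, worse = DOMAIN_OUTCOMES[condition.domain]
    p_better = P_CORRECT_BETTER if action == condition.correct_action else 1.0 - P_CORRECT_BETTER
    return better if rng.random() < p_better else worse


def session_to_arrays(trials: Sequence[TrialRecord]):
    """Compile a trial sequence into parallel int64 arrays for the fast kernels.

    Returns ``(stim, domain, action, outcome)``. Validates outcome support.
    """
    n = len(trials)
    stim = np.empty(n, dtype=np.int64)
    domain = np.empty(n, dtype=np.int64)
    action = np.empty(n, dtype=np.int64)
    outcome = np.empty(n, dtype=np.int64)
    for i, tr in enumerate(trials):
        cond = Condition(tr.condition)
        better, worse = DOMAIN_OUTCOMES[cond.domain]
        if tr.outcome not in (better, worse):
            raise DataError(
                f"trial {tr.index}: outcome {tr.outcome} outside domain support of {cond.label}"
            )
        stim[i] = int(cond)
        domain[i] = int(cond.domain)
        action[i] = int(Action(tr.action))
        outcome[i] = tr.outcome
    return stim, domain, action, outcome
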