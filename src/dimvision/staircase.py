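"""One-up/two-down adaptive staircase with trial-unit logic.

The staircase adjusts task difficulty from recent outcomes.  Difficulty moves on
an *axis*: log10 target luminance for the detection task (dimmer = harder), the
Weber fraction between the two targets for the discrimination task (smaller
difference = harder).  In both cases smaller axis values are harder, so the
default ``harder_direction`` is -1.

The decision block is the *trial unit*:

* two consecutive correct choices at the same level -> successful unit, one
  step toward harder;
* one incorrect choice, or one correct choice followed by an incorrect choice
  at the same level -> unsuccessful unit, one step toward easier.

A unit therefore contains one or two trials.  A *reversal* is a completed unit
whose outcome differs from the previous completed unit's outcome; its value is
the level at which that unit was run.  The 1-up/2-down rule converges on the
stimulus level yielding sqrt(1/2) ~ 70.7% correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

Side = Literal["left", "right"]
UnitOutcome = Literal["successful", "unsuccessful"]


@dataclass(frozen=True)
class StepSchedule:
    """Step sizes and their switch points, plus the track's bounds.

    ``steps`` are strictly decreasing axis step sizes (log10 units or Weber
    fraction units); the schedule switches from ``steps[i]`` to ``steps[i+1]``
    once the running reversal count reaches ``breakpoints[i]``.  The default
    shape has exactly two decreases, large steps early and the smallest step
    near threshold.
    """

    steps: tuple[float, ...]
    breakpoints: tuple[int, ...]
    start_level: float
    floor_level: float
    ceiling_level: float
    harder_direction: int = -1

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.steps) - 1:
            raise ValueError("need exactly one breakpoint per step decrease")
        if any(s <= 0 for s in self.steps):
            raise ValueError("step sizes must be positive")
        if any(b <= a for a, b in zip(self.steps[1:], self.steps[:-1])) or any(
            self.steps[i + 1] >= self.steps[i] for i in range(len(self.steps) - 1)
        ):
            raise ValueError("step sizes must strictly decrease")
        if any(
            self.breakpoints[i + 1] <= self.breakpoints[i]
            for i in range(len(self.breakpoints) - 1)
        ):
            raise ValueError("breakpoints must strictly increase")
        if not (self.floor_level < self.start_level <= self.ceiling_level):
            raise ValueError("require floor_level < start_level <= ceiling_level")
        if self.harder_direction not in (-1, 1):
            raise ValueError("harder_direction must be -1 or +1")

    def step_size(self, n_reversals: int) -> float:
        """Step size in force after ``n_reversals`` recorded reversals."""
        idx = sum(1 for b in self.breakpoints if n_reversals >= b)
        return self.steps[idx]

    @property
    def smallest_step(self) -> float:
        return self.steps[-1]


def detection_schedule(
    anchor_log10: float,
    steps: tuple[float, ...] = (0.4, 0.2, 0.1),
    breakpoints: tuple[int, ...] = (2, 4),
    start_above: float = 1.0,
    span: float = 1.5,
) -> StepSchedule:
    """Detection-task schedule on the log10-luminance axis.

    The track starts ``start_above`` log units above the anchor (an a-priori
    guess at threshold, so sessions begin well above it) and is clamped to
    ``anchor +- span``.
    """
    return StepSchedule(
        steps=steps,
        breakpoints=breakpoints,
        start_level=anchor_log10 + start_above,
        floor_level=anchor_log10 - span,
        ceiling_level=anchor_log10 + span,
        harder_direction=-1,
    )


def discrimination_schedule(
    steps: tuple[float, ...] = (0.2, 0.1, 0.05),
    breakpoints: tuple[int, ...] = (2, 4),
    start_level: float = 0.9,
) -> StepSchedule:
    """Discrimination-task schedule on the Weber-fraction axis.

    The negative target starts far below the fixed positive reference (large
    Weber fraction, easy) and moves toward it; k is clamped to [0, 1].
    """
    return StepSchedule(
        steps=steps,
        breakpoints=breakpoints,
        start_level=start_level,
        floor_level=0.0,
        ceiling_level=1.0,
        harder_direction=-1,
    )


@dataclass(frozen=True)
class StoppingRule:
    """Session termination: hard cap at ``max_trials``; may stop earlier once at
    least ``reversals_at_smallest_step`` reversals have been recorded while the
    smallest step was in force (a proxy for steady-state performance), but never
    before ``min_trials``."""

    min_trials: int = 38
    max_trials: int = 100
    reversals_at_smallest_step: int = 8


@dataclass
class UnitEvent:
    """Emitted when a trial completes a trial unit."""

    outcome: UnitOutcome
    trial_indices: tuple[int, ...]  # 1-based indices of the unit's trials
    level: float  # level at which the unit was run
    reversal: bool
    new_level: float


@dataclass
class StaircaseState:
    """Mutable track state; replayable from outcome sequences."""

    current_level: float
    pending_trial_index: Optional[int] = None  # unresolved first correct at level
    last_unit_outcome: Optional[UnitOutcome] = None
    reversal_indices: list[int] = field(default_factory=list)
    reversal_values: list[float] = field(default_factory=list)
    reversals_at_smallest_step: int = 0
    trial_index: int = 0  # trials consumed so far
    finished: bool = False

    @property
    def direction(self) -> Optional[str]:
        if self.last_unit_outcome is None:
            return None
        return "harder" if self.last_unit_outcome == "successful" else "easier"


def new_state(schedule: StepSchedule) -> StaircaseState:
    return StaircaseState(current_level=schedule.start_level)


def update(
    state: StaircaseState,
    correct: bool,
    schedule: StepSchedule,
    stopping: Optional[StoppingRule] = None,
) -> Optional[UnitEvent]:
    """Consume one trial outcome; mutate the track and return the unit event, if any.

    Raises if the staircase has already finished.  With ``stopping=None`` the
    track never self-terminates (used for long-run convergence studies).
    """
    if state.finished:
        raise RuntimeError("staircase already finished; cannot update")
    state.trial_index += 1
    t = state.trial_index

    event: Optional[UnitEvent] = None
    if correct and state.pending_trial_index is None:
        state.pending_trial_index = t  # open unit: await second trial at this level
    else:
        if correct:
            outcome: UnitOutcome = "successful"
            indices = (state.pending_trial_index, t)
        elif state.pending_trial_index is not None:
            outcome = "unsuccessful"
            indices = (state.pending_trial_index, t)
        else:
            outcome = "unsuccessful"
            indices = (t,)
        state.pending_trial_index = None

        is_reversal = (
            state.last_unit_outcome is not None
            and outcome != state.last_unit_outcome
        )
        level = state.current_level
        step = schedule.step_size(len(state.reversal_values))
        if is_reversal:
            state.reversal_indices.append(t)
            state.reversal_values.append(level)
            if step == schedule.smallest_step:
                state.reversals_at_smallest_step += 1
        state.last_unit_outcome = outcome

        sign = schedule.harder_direction if outcome == "successful" else -schedule.harder_direction
        new_level = float(
            np.clip(level + sign * step, schedule.floor_level, schedule.ceiling_level)
        )
        state.current_level = new_level
        event = UnitEvent(
            outcome=outcome,
            trial_indices=tuple(i for i in indices if i is not None),
            level=level,
            reversal=is_reversal,
            new_level=new_level,
        )

    if stopping is not None:
        if t >= stopping.max_trials:
            state.finished = True
        elif (
            t >= stopping.min_trials
            and state.reversals_at_smallest_step >= stopping.reversals_at_smallest_step
        ):
            state.finished = True
    return event


def fellows_sides(n_trials: int, rng: np.random.Generator) -> list[Side]:
    """Semi-random left/right assignment with Fellows-style constraints.

    Each block of 10 trials holds exactly 5 left and 5 right (a final partial
    block is as balanced as possible), and no side repeats more than 3 times in
    a row anywhere in the sequence.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    out: list[Side] = []
    pos = 0
    while pos < n_trials:
        m = min(10, n_trials - pos)
        n_left = m // 2
        n_right = m - n_left
        if m % 2 == 1 and rng.random() < 0.5:
            n_left, n_right = n_right, n_left
        block = ["left"] * n_left + ["right"] * n_right
        for _ in range(10_000):
            perm = list(rng.permutation(block))
            if _max_run(out[-3:] + perm) <= 3:
                out.extend(perm)
                break
        else:  # pragma: no cover - constraint is always satisfiable for block<=10
            raise RuntimeError("could not satisfy side-sequence constraints")
        pos += m
    return out


def _max_run(seq: list[str]) -> int:
    best = run = 0
    prev = None
    for s in seq:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best


def convergence_probability(n_up: int, n_down: int) -> float:
    """Asymptotic probability correct targeted by a 1-up/n-down rule.

    The track is in equilibrium where a step down (n_down consecutive corrects)
    is as likely as a step up, i.e. p**n_down = 1/2.  Rules with n_up > 1 have
    no such closed form and are not supported.
    """
    if n_up < 1 or n_down < 1:
        raise ValueError("n_up and n_down must be >= 1")
    if n_up != 1:
        raise NotImplementedError("only 1-up/n-down rules are supported")
    return 0.5 ** (1.0 / n_down)


@dataclass
class TrialRecord:
    """One behavioural trial, the atom of the pipeline's interchange format."""

    session_id: str
    subject_id: str
    experiment: int
    level_id: int
    trial_index: int
    task: Literal["detection", "discrimination"]
    positive_luminance: float
    negative_luminance: float
    positive_side: Side
    chosen_side: Side
    correct: bool
    trial_unit: Literal["successful", "unsuccessful", "open"]
    response_time: float
    inter_trial_time: float
    multi_entry: bool = False

    def __post_init__(self) -> None:
        if self.correct != (self.chosen_side == self.positive_side):
            raise ValueError("correct must equal (chosen_side == positive_side)")
        if self.task == "detection" and self.negative_luminance != 0.0:
            raise ValueError("detection task requires a plain-black negative stimulus")


@dataclass
class TrialLog:
    """A session's trial sequence plus its identifying metadata."""

    session_id: str
    subject_id: str
    experiment: int
    level_id: int
    task: Literal["detection", "discrimination"]
    records: list[TrialRecord] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)
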