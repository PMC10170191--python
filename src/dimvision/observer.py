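"""Simulated 2AFC observer and session/study generators.

The generator stands in for the behavioural data: a stochastic observer with a
psychometric function drives the adaptive staircase, producing trial logs with
the statistical structure the analysis pipeline assumes (4 subjects x 4 light
levels x 3 sessions for the detection experiment; the unbalanced 40-session
design for the discrimination experiment; response times with median ~1 s and
inter-trial times with median ~8 s).

Stimulus-strength axes match the staircase: log10 target luminance (cd m^-2)
for detection, Weber fraction for discrimination.  All randomness flows from
explicit seeds; a master seed fans out to sessions via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .staircase import (
    StepSchedule,
    StoppingRule,
    TrialLog,
    TrialRecord,
    fellows_sides,
    new_state,
    update,
)

Task = Literal["detection", "discrimination"]


@dataclass(frozen=True)
class PsychometricObserver:
    """Generative model of a bird's choice behaviour in a 2AFC task.

    Probability of a correct choice at stimulus strength ``x``::

        p(x) = gamma + (1 - gamma - lapse) * logistic(beta * (x - alpha))

    ``alpha`` locates the function on the strength axis (log10 luminance for
    detection, Weber fraction for discrimination); ``beta`` > 0 is the slope;
    ``gamma`` is the guess rate (0.5 for 2AFC); ``lapse`` bounds performance
    away from 1 at easy stimuli.
    """

    alpha: float
    beta: float
    gamma: float = 0.5
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if not 0.0 <= self.gamma < 1.0 - self.lapse:
            raise ValueError("gamma must be in [0, 1 - lapse)")

    def probability_correct(self, stimulus_strength: float) -> float:
        span = 1.0 - self.gamma - self.lapse
        return self.gamma + span * expit(self.beta * (stimulus_strength - self.alpha))

    def percent_point(self, p: float) -> float:
        """Stimulus strength at which probability correct equals ``p``."""
        span = 1.0 - self.gamma - self.lapse
        f = (p - self.gamma) / span
        if not 0.0 < f < 1.0:
            raise ValueError(f"p={p} outside the attainable range")
        return self.alpha + logit(f) / self.beta

    @classmethod
    def from_percent_point(
        cls,
        p: float,
        strength: float,
        beta: float,
        gamma: float = 0.5,
        lapse: float = 0.02,
    ) -> "PsychometricObserver":
        """Observer whose ``p``-correct point sits exactly at ``strength``.

        Convenient for placing the staircase's convergence point (70.7% for
        1-up/2-down) at a chosen threshold.
        """
        span = 1.0 - gamma - lapse
        f = (p - gamma) / span
        alpha = strength - logit(f) / beta
        return cls(alpha=alpha, beta=beta, gamma=gamma, lapse=lapse)


def stimulus_strength(
    task: Task, positive_luminance: float, negative_luminance: float
) -> float:
    """Map a stimulus pair to the observer's strength axis."""
    if task == "detection":
        if positive_luminance <= 0:
            raise ValueError("detection target luminance must be positive")
        return math.log10(positive_luminance)
    if task == "discrimination":
        if positive_luminance <= 0 or not 0 <= negative_luminance <= positive_luminance:
            raise ValueError("require 0 <= negative <= positive with positive > 0")
        return (positive_luminance - negative_luminance) / positive_luminance
    raise ValueError(f"unknown task {task!r}")


def simulate_choice(
    observer: PsychometricObserver,
    positive_luminance: float,
    negative_luminance: float,
    rng: np.random.Generator,
    task: Task = "detection",
) -> bool:
    """One Bernoulli choice at the strength implied by the stimulus pair."""
    p = observer.probability_correct(
        stimulus_strength(task, positive_luminance, negative_luminance)
    )
    return bool(rng.random() < p)


@dataclass(frozen=True)
class ResponseTimeModel:
    """Log-normal response times (s).

    ``median`` sets the log-normal location; ``sigma_log`` the log-scale spread
    (default matched to the reported first/third quartiles).  Trials belonging
    to successful trial units are sped up by ``success_speedup`` (fractional;
    the effect is small, on the order of 10^-2 s, so the timing analysis has
    realistic signal).  A small fraction ``multi_entry_prob`` of trials are
    flagged as multiple-entry and have inflated times; the analysis excludes
    them from response-time summaries.
    """

    median: float = 1.17
    sigma_log: float = 0.40
    success_speedup: float = 0.05
    multi_entry_prob: float = 0.03
    multi_entry_factor: float = 3.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.median * np.exp(self.sigma_log * rng.standard_normal(n))


@dataclass(frozen=True)
class InterTrialModel:
    """Right-skewed (gamma) inter-trial times (s) with a configurable median."""

    median: float = 8.33
    shape: float = 4.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        scale = self.median / stats.gamma.ppf(0.5, self.shape)
        return rng.gamma(self.shape, scale, size=n)


@dataclass(frozen=True)
class SessionPlan:
    """Everything needed to simulate one staircase session."""

    session_id: str
    subject_id: str
    experiment: int
    level_id: int
    task: Task
    rng_seed: int
    positive_luminance: Optional[float] = None  # fixed reference, discrimination only
    min_trials: int = 38
    max_trials: int = 100
    response_time_model: ResponseTimeModel = ResponseTimeModel()
    inter_trial_model: InterTrialModel = InterTrialModel()

    def __post_init__(self) -> None:
        if not 1 <= self.min_trials <= self.max_trials:
            raise ValueError("require 1 <= min_trials <= max_trials")
        if self.task == "discrimination" and self.positive_luminance is None:
            raise ValueError("discrimination plans need a positive_luminance")


def generate_session(
    plan: SessionPlan,
    observer: PsychometricObserver,
    schedule: StepSchedule,
    stopping: Optional[StoppingRule] = None,
) -> TrialLog:
    """Run the staircase against the observer and emit a full trial log."""
    rng = np.random.default_rng(plan.rng_seed)
    if stopping is None:
        stopping = StoppingRule(min_trials=plan.min_trials, max_trials=plan.max_trials)
    sides = fellows_sides(plan.max_trials, rng)
    state = new_state(schedule)
    rt_model = plan.response_time_model

    records: list[TrialRecord] = []
    unit_labels: dict[int, str] = {}
    while not state.finished:
        level = state.current_level
        if plan.task == "detection":
            pos_lum, neg_lum = 10.0**level, 0.0
        else:
            i_plus = float(plan.positive_luminance)
            pos_lum = i_plus
            neg_lum = i_plus * (1.0 - level)  # level is the Weber fraction
        correct = simulate_choice(observer, pos_lum, neg_lum, rng, plan.task)
        event = update(state, correct, schedule, stopping)
        t = state.trial_index
        if event is not None:
            for i in event.trial_indices:
                unit_labels[i] = event.outcome

        positive_side = sides[t - 1]
        chosen_side = positive_side if correct else ("left" if positive_side == "right" else "right")
        rt = float(rt_model.draw(1, rng)[0])
        multi_entry = bool(rng.random() < rt_model.multi_entry_prob)
        if multi_entry:
            rt *= rt_model.multi_entry_factor
        itt = float(plan.inter_trial_model.draw(1, rng)[0])
        records.append(
            TrialRecord(
                session_id=plan.session_id,
                subject_id=plan.subject_id,
                experiment=plan.experiment,
                level_id=plan.level_id,
                trial_index=t,
                task=plan.task,
                positive_luminance=pos_lum,
                negative_luminance=neg_lum,
                positive_side=positive_side,
                chosen_side=chosen_side,
                correct=correct,
                trial_unit="open",
                response_time=rt,
                inter_trial_time=itt,
                multi_entry=multi_entry,
            )
        )

    for rec in records:
        label = unit_labels.get(rec.trial_index, "open")
        rec.trial_unit = label
        if label == "successful":
            rec.response_time *= 1.0 - rt_model.success_speedup

    return TrialLog(
        session_id=plan.session_id,
        subject_id=plan.subject_id,
        experiment=plan.experiment,
        level_id=plan.level_id,
        task=plan.task,
        records=records,
    )


def generate_study(config, master_seed: int) -> list[TrialLog]:
    """Simulate the full synthetic study (both experiments) from a StudyConfig.

    The master seed fans out deterministically: one ``SeedSequence`` child per
    subject (its per-experiment threshold offsets), then one per session.
    Defaults yield 48 detection sessions and 40 discrimination sessions,
    matching the study's balanced and unbalanced designs.
    """
    from .config import StudyConfig  # local import to avoid a cycle

    if not isinstance(config, StudyConfig):
        raise TypeError("config must be a StudyConfig")
    ss = np.random.SeedSequence(master_seed)
    subj_ss, sess_ss = ss.spawn(2)

    subjects = config.subjects
    offsets: dict[tuple[str, int], float] = {}
    for child, subj in zip(subj_ss.spawn(len(subjects)), subjects):
        r = np.random.default_rng(child)
        offsets[(subj, 1)] = float(r.normal(0.0, config.detection_subject_sd))
        offsets[(subj, 2)] = float(r.normal(0.0, config.discrimination_subject_sd))

    logs: list[TrialLog] = []
    plans = config.session_table()
    children = sess_ss.spawn(len(plans))
    lum_by_level = {lv.level_id: lv.exp2_positive_luminance for lv in config.light_levels}
    for child, (subj, experiment, level_id, session_no) in zip(children, plans):
        seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        session_id = f"exp{experiment}_{subj}_L{level_id}_s{session_no}"
        if experiment == 1:
            target = config.detection_target_log10[level_id] + offsets[(subj, 1)]
            observer = PsychometricObserver.from_percent_point(
                config.tracked_proportion,
                target,
                beta=config.detection_slope,
                lapse=config.lapse,
            )
            schedule = config.detection_schedule(level_id)
            plan = SessionPlan(
                session_id=session_id,
                subject_id=subj,
                experiment=1,
                level_id=level_id,
                task="detection",
                rng_seed=seed,
                min_trials=config.exp1_min_trials,
                max_trials=config.exp1_max_trials,
                response_time_model=config.exp1_response_time,
                inter_trial_model=config.exp1_inter_trial,
            )
        else:
            target = float(
                np.clip(
                    config.discrimination_target_weber[level_id] + offsets[(subj, 2)],
                    0.02,
                    0.98,
                )
            )
            observer = PsychometricObserver.from_percent_point(
                config.tracked_proportion,
                target,
                beta=config.discrimination_slope,
                lapse=config.lapse,
            )
            schedule = config.discrimination_schedule()
            plan = SessionPlan(
                session_id=session_id,
                subject_id=subj,
                experiment=2,
                level_id=level_id,
                task="discrimination",
                rng_seed=seed,
                positive_luminance=lum_by_level[level_id],
                min_trials=config.exp2_min_trials,
                max_trials=config.exp2_max_trials,
                response_time_model=config.exp2_response_time,
                inter_trial_model=config.exp2_inter_trial,
            )
        logs.append(generate_session(plan, observer, schedule))
    return logs
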