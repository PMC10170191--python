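"""Reversal-averaged threshold estimation and Weber fractions.

A session's threshold is the arithmetic mean of the stimulus values at the
reversals falling within the final window of trials (default 20 choices).  If
that count is odd, the earliest in-window reversal is dropped so successful and
unsuccessful trial units get equal weight.  Reversals are re-derived here from
the logged outcomes and stimulus values — never trusted from the controller —
so deposited logs and simulated logs go through the identical path.

Detection thresholds are absolute luminances (cd m^-2); discrimination
thresholds are Weber fractions k = (I+ - I-) / I+ against the session's fixed
positive reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photometry import LightLevel
from .staircase import TrialLog


class EstimationError(ValueError):
    """Raised when a session carries too few reversals for a threshold."""


@dataclass(frozen=True)
class WeberFraction:
    """k = dI / I+ of the discrimination task (0 for identical stimuli)."""

    delta_i: float
    i_plus: float

    @property
    def k(self) -> float:
        return self.delta_i / self.i_plus


def weber_fraction(i_plus: float, i_neg: float) -> WeberFraction:
    """Weber fraction between a positive reference and a dimmer negative target."""
    if i_plus <= 0:
        raise ValueError("positive luminance must be > 0")
    if not 0 <= i_neg <= i_plus:
        raise ValueError("require 0 <= negative luminance <= positive luminance")
    return WeberFraction(delta_i=i_plus - i_neg, i_plus=i_plus)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Per-session reversal-averaged threshold with its window metadata."""

    session_id: str
    threshold: float  # cd m^-2 (detection) or Weber fraction (discrimination)
    reversal_values_used: tuple[float, ...]
    n_reversals_used: int
    window_start_trial: int
    dropped_first_reversal: bool


def _stimulus_value(record) -> float:
    """The reversal-value axis: target luminance for detection, negative-target
    luminance for discrimination (the moving stimulus in each task)."""
    return (
        record.positive_luminance
        if record.task == "detection"
        else record.negative_luminance
    )


def detect_reversals(trial_log: TrialLog) -> list[tuple[int, float]]:
    """Re-derive reversal points from a trial log's outcomes and stimulus values.

    Trials are grouped into trial units by the staircase rules (two consecutive
    corrects at one stimulus value; an incorrect closes a unit immediately); a
    reversal is a completed unit whose outcome differs from the previous
    completed unit's, tagged with the trial index realising the flip and the
    stimulus value at which the unit was run.
    """
    reversals: list[tuple[int, float]] = []
    pending_value = None
    last_outcome = None
    for rec in trial_log:
        value = _stimulus_value(rec)
        if rec.correct and pending_value is None:
            pending_value = value
            continue
        if rec.correct and not np.isclose(value, pending_value, rtol=1e-9, atol=0.0):
            # defensive: a level change mid-unit restarts the unit
            pending_value = value
            continue
        outcome = "successful" if rec.correct else "unsuccessful"
        unit_value = value if pending_value is None else pending_value
        pending_value = None
        if last_outcome is not None and outcome != last_outcome:
            reversals.append((rec.trial_index, unit_value))
        last_outcome = outcome
    return reversals


def estimate_threshold(trial_log: TrialLog, window: int = 20) -> ThresholdEstimate:
    """Reversal-averaged threshold over the last ``window`` choices.

    Averages the stimulus values at reversals whose trial index lies within the
    final ``window`` trials; an odd count drops the earliest in-window reversal.
    Raises :class:`EstimationError` with a diagnostic if fewer than two
    reversals fall inside the window.
    """
    n = trial_log.n_trials
    window_start = max(1, n - window + 1)
    in_window = [
        (t, v) for t, v in detect_reversals(trial_log) if t >= window_start
    ]
    if len(in_window) < 2:
        raise EstimationError(
            f"session {trial_log.session_id!r}: {len(in_window)} reversal(s) in the "
            f"last {window} of {n} trials; need at least 2"
        )
    dropped = len(in_window) % 2 == 1
    if dropped:
        in_window = in_window[1:]
    values = tuple(v for _, v in in_window)
    return ThresholdEstimate(
        session_id=trial_log.session_id,
        threshold=float(np.mean(values)),
        reversal_values_used=values,
        n_reversals_used=len(values),
        window_start_trial=window_start,
        dropped_first_reversal=dropped,
    )


def session_weber_threshold(
    trial_log: TrialLog, light: LightLevel, window: int = 20
) -> ThresholdEstimate:
    """Discrimination-session threshold expressed as a Weber fraction.

    The reversal-averaged negative-target luminance is converted against the
    level's fixed positive reference; because I+ is constant within a session,
    averaging per-reversal fractions and converting the averaged luminance are
    identical.
    """
    if trial_log.task != "discrimination":
        raise ValueError("session_weber_threshold requires a discrimination-task log")
    if trial_log.level_id != light.level_id:
        raise ValueError("light level does not match the session's level_id")
    est = estimate_threshold(trial_log, window=window)
    i_plus = light.exp2_positive_luminance
    k_values = tuple(weber_fraction(i_plus, v).k for v in est.reversal_values_used)
    return ThresholdEstimate(
        session_id=est.session_id,
        threshold=float(np.mean(k_values)),
        reversal_values_used=k_values,
        n_reversals_used=est.n_reversals_used,
        window_start_trial=est.window_start_trial,
        dropped_first_reversal=est.dropped_first_reversal,
    )


def threshold_table(
    trial_logs: list[TrialLog],
    light_levels: list[LightLevel],
    window: int = 20,
) -> pd.DataFrame:
    """Per-session threshold table consumed by the mixed-model analysis.

    Columns: session_id, subject_id, experiment, level_id, threshold (cd m^-2
    for detection sessions, Weber fraction for discrimination sessions),
    n_reversals_used, window_start_trial, dropped_first_reversal, n_trials.
    """
    by_level = {lv.level_id: lv for lv in light_levels}
    rows = []
    for log in trial_logs:
        if log.task == "detection":
            est = estimate_threshold(log, window=window)
        else:
            est = session_weber_threshold(log, by_level[log.level_id], window=window)
        rows.append(
            {
                "session_id": log.session_id,
                "subject_id": log.subject_id,
                "experiment": log.experiment,
                "level_id": log.level_id,
                "threshold": est.threshold,
                "n_reversals_used": est.n_reversals_used,
                "window_start_trial": est.window_start_trial,
                "dropped_first_reversal": est.dropped_first_reversal,
                "n_trials": log.n_trials,
            }
        )
    return pd.DataFrame(rows)
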