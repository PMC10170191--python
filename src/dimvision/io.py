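"""Trial-log and results I/O.

Trial logs travel as header-bearing comma-delimited UTF-8 text with '.'
decimals, one row per trial, so archives stay diffable.  The experiment column
carries the task: experiment 1 is detection (plain-black negative stimulus),
experiment 2 is discrimination.  Reading validates structure (columns, side
labels, per-session trial-index contiguity, correctness consistency) and
reports offending rows by line number.

A best-effort adapter maps externally deposited tables into this format via a
user-supplied column mapping; the core pipeline never depends on an external
schema.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd

from .staircase import TrialLog, TrialRecord

TRIAL_LOG_COLUMNS = [
    "session_id",
    "subject_id",
    "experiment",
    "level_id",
    "trial_index",
    "positive_luminance_cd_m2",
    "negative_luminance_cd_m2",
    "positive_side",
    "chosen_side",
    "correct",
    "trial_unit_outcome",
    "response_time_s",
    "inter_trial_time_s",
    "multi_entry_flag",
]

_TASK_BY_EXPERIMENT = {1: "detection", 2: "discrimination"}


class TrialLogParseError(ValueError):
    """Malformed trial-log file; message carries line numbers / session ids."""


def trial_logs_to_frame(logs: Iterable[TrialLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for rec in log:
            rows.append(
                {
                    "session_id": rec.session_id,
                    "subject_id": rec.subject_id,
                    "experiment": rec.experiment,
                    "level_id": rec.level_id,
                    "trial_index": rec.trial_index,
                    "positive_luminance_cd_m2": rec.positive_luminance,
                    "negative_luminance_cd_m2": rec.negative_luminance,
                    "positive_side": rec.positive_side,
                    "chosen_side": rec.chosen_side,
                    "correct": rec.correct,
                    "trial_unit_outcome": rec.trial_unit,
                    "response_time_s": rec.response_time,
                    "inter_trial_time_s": rec.inter_trial_time,
                    "multi_entry_flag": rec.multi_entry,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_logs(logs: Iterable[TrialLog], path) -> None:
    # %.17g guarantees binary round-trip of the float columns through text
    trial_logs_to_frame(logs).to_csv(path, index=False, float_format="%.17g")


def trial_logs_from_frame(df: pd.DataFrame) -> list[TrialLog]:
    """Validate a trial-log frame and assemble per-session TrialLog objects."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogParseError(f"missing columns: {', '.join(missing)}")
    bad_side = df[
        ~df["positive_side"].isin(["left", "right"])
        | ~df["chosen_side"].isin(["left", "right"])
    ]
    if len(bad_side):
        lines = (bad_side.index + 2).tolist()  # +2: header and 1-based
        raise TrialLogParseError(f"unknown side labels at line(s) {lines[:10]}")
    bad_exp = df[~df["experiment"].isin([1, 2])]
    if len(bad_exp):
        raise TrialLogParseError(
            f"experiment must be 1 or 2; bad line(s) {(bad_exp.index + 2).tolist()[:10]}"
        )

    logs = []
    for session_id, grp in df.groupby("session_id", sort=False):
        grp = grp.sort_values("trial_index")
        idx = grp["trial_index"].to_numpy()
        if idx[0] != 1 or (idx[1:] - idx[:-1] != 1).any():
            raise TrialLogParseError(
                f"session {session_id!r}: trial_index not contiguous from 1"
            )
        experiment = int(grp["experiment"].iloc[0])
        task = _TASK_BY_EXPERIMENT[experiment]
        records = []
        for line, row in zip(grp.index + 2, grp.itertuples(index=False)):
            correct = _as_bool(row.correct)
            if correct != (row.chosen_side == row.positive_side):
                raise TrialLogParseError(
                    f"line {line}: 'correct' inconsistent with the side columns"
                )
            records.append(
                TrialRecord(
                    session_id=str(row.session_id),
                    subject_id=str(row.subject_id),
                    experiment=experiment,
                    level_id=int(row.level_id),
                    trial_index=int(row.trial_index),
                    task=task,
                    positive_luminance=float(row.positive_luminance_cd_m2),
                    negative_luminance=float(row.negative_luminance_cd_m2),
                    positive_side=row.positive_side,
                    chosen_side=row.chosen_side,
                    correct=correct,
                    trial_unit=row.trial_unit_outcome,
                    response_time=float(row.response_time_s),
                    inter_trial_time=float(row.inter_trial_time_s),
                    multi_entry=_as_bool(row.multi_entry_flag),
                )
            )
        logs.append(
            TrialLog(
                session_id=str(session_id),
                subject_id=records[0].subject_id,
                experiment=experiment,
                level_id=records[0].level_id,
                task=task,
                records=records,
            )
        )
    return logs


def read_trial_log(path) -> list[TrialLog]:
    """Read and validate a trial-log file into per-session TrialLog objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    return trial_logs_from_frame(df)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("true", "1", "yes")
    return bool(x)


def adapt_external_table(
    df: pd.DataFrame,
    column_mapping: Mapping[str, str],
    constants: Optional[Mapping[str, object]] = None,
) -> list[TrialLog]:
    """Map an externally deposited trial table into the native trial-log format.

    ``column_mapping`` maps native column names to the external table's column
    names; ``constants`` supplies native columns the external table lacks
    (e.g. a fixed experiment number).  The mapping is configuration, not code:
    external schemas vary and are not hard-wired here.
    """
    out = pd.DataFrame(index=df.index)
    for native, external in column_mapping.items():
        if native not in TRIAL_LOG_COLUMNS:
            raise KeyError(f"unknown native column {native!r}")
        if external not in df.columns:
            raise TrialLogParseError(f"external table lacks column {external!r}")
        out[native] = df[external]
    for native, value in (constants or {}).items():
        out[native] = value
    return trial_logs_from_frame(out)
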