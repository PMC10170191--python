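"""Declarative study configuration: light levels, step schedules, observer and
timing defaults, session counts, seeds and analysis options.

Defaults encode the study conditions: per-level detection thresholds of 0.825,
0.110, 0.136 and 0.106 cd m^-2, discrimination Weber fractions of 0.45, 0.42,
0.54 and 0.41, response-time medians of 1.17 s (detection) and 0.98 s
(discrimination) and inter-trial medians of 8.33 s and 7.79 s; 4 subjects x 4
light levels x 3 sessions in experiment 1, and the unbalanced 40-session
design of experiment 2 (subjects 2 and 4 have fewer sessions).

The config round-trips through YAML for archival (`to_yaml`/`from_yaml`) and a
short hash ties result files to the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from . import photometry, staircase
from .observer import InterTrialModel, ResponseTimeModel

#: Back-transformed per-level detection thresholds (cd m^-2) used as the
#: generator's population means.
DETECTION_TARGETS_CD_M2 = {1: 0.825, 2: 0.110, 3: 0.136, 4: 0.106}

#: Per-level Weber-fraction thresholds used as the generator's population means.
DISCRIMINATION_TARGETS_WEBER = {1: 0.45, 2: 0.42, 3: 0.54, 4: 0.41}

#: Experiment-2 session counts per subject and level (subject 2 skips level 4;
#: subject 4 has one level-3 session and skips level 4), totalling 40.
EXP2_SESSIONS = {
    "bird1": {1: 3, 2: 3, 3: 3, 4: 3},
    "bird2": {1: 3, 2: 3, 3: 3, 4: 0},
    "bird3": {1: 3, 2: 3, 3: 3, 4: 3},
    "bird4": {1: 3, 2: 3, 3: 1, 4: 0},
}


@dataclass
class StudyConfig:
    subjects: tuple[str, ...] = ("bird1", "bird2", "bird3", "bird4")
    light_levels: list[photometry.LightLevel] = field(
        default_factory=photometry.default_light_levels
    )

    # observer model
    detection_target_log10: dict[int, float] = field(
        default_factory=lambda: {
            k: math.log10(v) for k, v in DETECTION_TARGETS_CD_M2.items()
        }
    )
    discrimination_target_weber: dict[int, float] = field(
        default_factory=lambda: dict(DISCRIMINATION_TARGETS_WEBER)
    )
    detection_subject_sd: float = 0.08  # between-bird SD, log10 cd m^-2
    discrimination_subject_sd: float = 0.05  # between-bird SD, Weber units
    detection_slope: float = 8.0  # logistic slope per log10 unit
    discrimination_slope: float = 10.0  # logistic slope per Weber unit
    lapse: float = 0.02
    tracked_proportion: float = 0.5 ** 0.5  # 1-up/2-down convergence point

    # staircase
    detection_steps: tuple[float, ...] = (0.4, 0.2, 0.1)
    discrimination_steps: tuple[float, ...] = (0.2, 0.1, 0.05)
    step_breakpoints: tuple[int, ...] = (2, 4)
    exp1_sessions_per_cell: int = 3
    exp1_min_trials: int = 38
    exp1_max_trials: int = 100
    exp2_min_trials: int = 35
    exp2_max_trials: int = 100
    exp2_sessions: dict[str, dict[int, int]] = field(
        default_factory=lambda: {s: dict(d) for s, d in EXP2_SESSIONS.items()}
    )

    # timing
    exp1_response_time: ResponseTimeModel = field(
        default_factory=lambda: ResponseTimeModel(median=1.17, sigma_log=0.40)
    )
    exp2_response_time: ResponseTimeModel = field(
        default_factory=lambda: ResponseTimeModel(median=0.98, sigma_log=0.32)
    )
    exp1_inter_trial: InterTrialModel = field(
        default_factory=lambda: InterTrialModel(median=8.33)
    )
    exp2_inter_trial: InterTrialModel = field(
        default_factory=lambda: InterTrialModel(median=7.79)
    )

    # analysis options
    window: int = 20
    transform: str = "log10"
    adjust: str = "holm"
    master_seed: int = 1400

    def detection_schedule(self, level_id: int) -> staircase.StepSchedule:
        """Detection staircase anchored at the level's a-priori threshold."""
        anchor = self.detection_target_log10[level_id]
        return staircase.detection_schedule(
            anchor, steps=self.detection_steps, breakpoints=self.step_breakpoints
        )

    def discrimination_schedule(self) -> staircase.StepSchedule:
        return staircase.discrimination_schedule(
            steps=self.discrimination_steps, breakpoints=self.step_breakpoints
        )

    def session_table(self) -> list[tuple[str, int, int, int]]:
        """Ordered (subject, experiment, level, session_no) tuples for the study."""
        plans = []
        for subj in self.subjects:
            for level in sorted(lv.level_id for lv in self.light_levels):
                for s in range(1, self.exp1_sessions_per_cell + 1):
                    plans.append((subj, 1, level, s))
        for subj in self.subjects:
            per_level = self.exp2_sessions.get(subj, {})
            for level in sorted(per_level):
                for s in range(1, per_level[level] + 1):
                    plans.append((subj, 2, level, s))
        return plans

    # ---- serialization ----

    def to_dict(self) -> dict:
        d = asdict(self)
        d["light_levels"] = photometry.light_level_table(self.light_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["subjects"] = tuple(d.get("subjects", cls().subjects))
        if "light_levels" in d:
            d["light_levels"] = photometry.light_levels_from_table(d["light_levels"])
        for key in ("detection_target_log10", "discrimination_target_weber"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        if "exp2_sessions" in d:
            d["exp2_sessions"] = {
                s: {int(k): int(v) for k, v in per.items()}
                for s, per in d["exp2_sessions"].items()
            }
        for key in ("detection_steps", "discrimination_steps", "step_breakpoints"):
            if key in d:
                d[key] = tuple(d[key])
        for key, model in (
            ("exp1_response_time", ResponseTimeModel),
            ("exp2_response_time", ResponseTimeModel),
            ("exp1_inter_trial", InterTrialModel),
            ("exp2_inter_trial", InterTrialModel),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = model(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Short stable digest tying output files to their configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
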