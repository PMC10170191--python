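"""Estimate per-session thresholds by reversal averaging.

Reads results/trial_logs.csv, re-derives the reversals of each staircase from
its logged outcomes, averages the reversal values of the last 20 choices (even
count, earliest dropped if needed) and writes one threshold per session —
absolute luminance (cd m^-2) for detection, Weber fraction for discrimination —
to results/thresholds.csv.
"""

from pathlib import Path

import dimvision as dv
from dimvision import io, pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = dv.StudyConfig()
    logs = io.read_trial_log(RESULTS / "trial_logs.csv")
    table = pipeline.estimate(logs, config)
    out = RESULTS / "thresholds.csv"
    table.to_csv(out, index=False)
    print(f"estimated {len(table)} session thresholds -> {out}")
    print(table.groupby(["experiment", "level_id"])["threshold"]
          .agg(["mean", "std"]).round(4))


if __name__ == "__main__":
    main()
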