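"""Minimal threshold-vs-light-level figure.

Plots per-session thresholds (one marker per bird) with the back-transformed
model estimates and 95% CIs overlaid, one panel per experiment, to
results/figures/thresholds.png.  Requires matplotlib.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from dimvision import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "thresholds.csv")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, exp, ylabel, logy in (
        (axes[0], 1, "detection threshold (cd m$^{-2}$)", True),
        (axes[1], 2, "Weber fraction", False),
    ):
        ana = pipeline.analyze_thresholds(table, exp)
        df = table[table["experiment"] == exp]
        for subj, grp in df.groupby("subject_id"):
            ax.scatter(grp["level_id"], grp["threshold"], s=12, alpha=0.5,
                       label=subj)
        est = pd.DataFrame([
            {"level": int(e.label[1]), "point": e.point,
             "lo": e.lower, "hi": e.upper} for e in ana.estimates
        ])
        ax.errorbar(est["level"], est["point"],
                    yerr=[est["point"] - est["lo"], est["hi"] - est["point"]],
                    fmt="ko", capsize=3, label="model estimate")
        if logy:
            ax.set_yscale("log")
        ax.set_xticks([1, 2, 3, 4])
        ax.set_xlabel("light level")
        ax.set_ylabel(ylabel)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    outdir = RESULTS / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "thresholds.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
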