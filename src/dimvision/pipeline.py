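"""High-level analysis steps shared by the CLI, the analysis scripts and tests.

Each function is a thin, deterministic composition of the core modules:
simulate a study, estimate per-session thresholds, compare light levels with
the random-intercept LMM, and analyse the time intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import mixedmodel, threshold
from .config import StudyConfig
from .mixedmodel import LMMFit, ModelSpec
from .observer import generate_study
from .staircase import TrialLog


def simulate(config: StudyConfig, seed: Optional[int] = None) -> list[TrialLog]:
    """Synthesize the full study (both experiments) from the config's defaults."""
    return generate_study(config, config.master_seed if seed is None else seed)


def estimate(logs: list[TrialLog], config: StudyConfig) -> pd.DataFrame:
    """Per-session reversal-averaged threshold table."""
    return threshold.threshold_table(
        logs, config.light_levels, window=config.window
    )


def _prep_threshold_data(table: pd.DataFrame, experiment: int) -> pd.DataFrame:
    df = table[table["experiment"] == experiment].copy()
    if df.empty:
        raise ValueError(f"no sessions for experiment {experiment}")
    df["light_level"] = "L" + df["level_id"].astype(int).astype(str)
    return df


@dataclass
class ThresholdAnalysis:
    """Light-level comparison of per-session thresholds for one experiment."""

    experiment: int
    full: LMMFit
    reduced: LMMFit
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    estimates: list  # EstimateWithCI per light level, natural scale
    pairwise: pd.DataFrame
    n_sessions: int


def analyze_thresholds(
    table: pd.DataFrame,
    experiment: int,
    transform: str = "log10",
    adjust: str = "holm",
) -> ThresholdAnalysis:
    """Fit full (light level fixed) vs reduced LMMs, LRT, estimates, contrasts.

    Both models carry the subject random intercept; the response (absolute
    luminance threshold for detection, Weber fraction for discrimination) is
    transformed per ``transform`` and the per-level estimates are mapped back.
    """
    df = _prep_threshold_data(table, experiment)
    full_spec = ModelSpec(
        response="threshold",
        fixed_terms=("light_level",),
        grouping_factor="subject_id",
        response_transform=transform,
    )
    reduced_spec = ModelSpec(
        response="threshold",
        fixed_terms=(),
        grouping_factor="subject_id",
        response_transform=transform,
    )
    full = mixedmodel.fit_lmm(df, full_spec)
    reduced = mixedmodel.fit_lmm(df, reduced_spec)
    stat, dof, p = mixedmodel.likelihood_ratio_test(full, reduced)
    estimates = mixedmodel.back_transform_estimates(full, "light_level")
    pairwise = mixedmodel.pairwise_comparisons(full, "light_level", adjust=adjust)
    return ThresholdAnalysis(
        experiment=experiment,
        full=full,
        reduced=reduced,
        lrt_statistic=stat,
        lrt_df=dof,
        lrt_p=p,
        estimates=estimates,
        pairwise=pairwise,
        n_sessions=len(df),
    )


def trial_frame(logs: list[TrialLog]) -> pd.DataFrame:
    """Per-trial analysis frame with factor columns for the timing models."""
    rows = []
    for log in logs:
        for rec in log:
            rows.append(
                {
                    "session_id": rec.session_id,
                    "subject_id": rec.subject_id,
                    "experiment": rec.experiment,
                    "light_level": f"L{rec.level_id}",
                    "trial_unit": rec.trial_unit,
                    "response_time": rec.response_time,
                    "inter_trial_time": rec.inter_trial_time,
                    "multi_entry": rec.multi_entry,
                }
            )
    return pd.DataFrame(rows)


#: Candidate fixed-effect structures for the response-time model, from the
#: intercept-only null up to the full model with both interactions.
RT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "null": (),
    "unit": ("trial_unit",),
    "unit+level": ("trial_unit", "light_level"),
    "unit+level+itt": ("trial_unit", "light_level", "inter_trial_time"),
    "unit*level": ("trial_unit", "light_level", "light_level:trial_unit"),
    "full": (
        "inter_trial_time",
        "light_level",
        "trial_unit",
        "inter_trial_time:trial_unit",
        "light_level:trial_unit",
    ),
}


@dataclass
class TimingAnalysis:
    experiment: int
    summaries: pd.DataFrame
    aic_table: pd.DataFrame
    best_model: str
    best_fit: LMMFit
    null_fit: LMMFit
    lrt_statistic: float
    lrt_df: int
    lrt_p: float


def analyze_times(logs: list[TrialLog], experiment: int) -> TimingAnalysis:
    """Response-time model selection by AIC plus an LRT of the best model
    against the null, on inverse-transformed response times.

    Multiple-entry trials and trials in an open (uncompleted) trial unit are
    excluded from the model data; the medians/quartiles come from
    :func:`mixedmodel.summarize_times` under its own exclusion rule.
    """
    logs_e = [lg for lg in logs if lg.experiment == experiment]
    if not logs_e:
        raise ValueError(f"no sessions for experiment {experiment}")
    summaries = mixedmodel.summarize_times(logs_e)
    df = trial_frame(logs_e)
    model_df = df[~df["multi_entry"] & df["trial_unit"].isin(["successful", "unsuccessful"])]

    fits: dict[str, LMMFit] = {}
    rows = []
    for name, terms in RT_CANDIDATES.items():
        spec = ModelSpec(
            response="response_time",
            fixed_terms=terms,
            grouping_factor="subject_id",
            response_transform="inverse",
        )
        fit = mixedmodel.fit_lmm(model_df, spec)
        fits[name] = fit
        rows.append(
            {
                "model": name,
                "n_params": fit.n_params,
                "loglik": fit.loglik,
                "aic": mixedmodel.aic(fit),
            }
        )
    aic_table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    best_model = str(aic_table.loc[0, "model"])
    best_fit = fits[best_model]
    null_fit = fits["null"]
    if best_model == "null":
        stat, dof, p = 0.0, 0, 1.0
    else:
        stat, dof, p = mixedmodel.likelihood_ratio_test(best_fit, null_fit)
    return TimingAnalysis(
        experiment=experiment,
        summaries=summaries,
        aic_table=aic_table,
        best_model=best_model,
        best_fit=best_fit,
        null_fit=null_fit,
        lrt_statistic=stat,
        lrt_df=dof,
        lrt_p=p,
    )


def report_text(
    det: ThresholdAnalysis,
    disc: ThresholdAnalysis,
    det_times: TimingAnalysis,
    disc_times: TimingAnalysis,
    config_hash: str = "",
) -> str:
    """Human-readable combined summary of a full study analysis."""
    lines = []
    if config_hash:
        lines.append(f"config: {config_hash}")
    for ana, name, unit in (
        (det, "Detection thresholds", "cd m^-2"),
        (disc, "Discrimination thresholds", "Weber fraction"),
    ):
        lines.append(f"\n== {name} (n = {ana.n_sessions} sessions) ==")
        lines.append(
            f"light-level effect: chi2_{ana.lrt_df} = {ana.lrt_statistic:.1f}, "
            f"p = {ana.lrt_p:.3g}"
        )
        for est in ana.estimates:
            lines.append(
                f"  {est.label}: {est.point:.3f} {unit} "
                f"[{est.lower:.3f}, {est.upper:.3f}]"
            )
    for ana, name in ((det_times, "experiment 1"), (disc_times, "experiment 2")):
        s = ana.summaries.iloc[0]
        lines.append(f"\n== Time intervals, {name} ==")
        lines.append(
            f"  response time median {s['response_time_median']:.2f} s "
            f"(Q1-Q3 {s['response_time_q1']:.2f}-{s['response_time_q3']:.2f}), "
            f"n = {int(s['n_response_time'])}"
        )
        lines.append(
            f"  inter-trial median {s['inter_trial_median']:.2f} s "
            f"(Q1-Q3 {s['inter_trial_q1']:.2f}-{s['inter_trial_q3']:.2f})"
        )
        lines.append(
            f"  best RT model by AIC: {ana.best_model}; LRT vs null "
            f"chi2_{ana.lrt_df} = {ana.lrt_statistic:.1f}, p = {ana.lrt_p:.3g}"
        )
    return "\n".join(lines) + "\n"
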