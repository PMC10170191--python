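"""Analyse response times and inter-trial times.

Summarises medians and quartiles per experiment (multiple-entry trials are
excluded from response times only), then selects the response-time model by
AIC among candidates from the intercept-only null up to the full model
(inter-trial time, light level, trial-unit outcome and the two interactions),
on inverse-transformed response times with a bird random intercept, and tests
the winner against the null with a likelihood-ratio test.  Writes
results/exp{1,2}_time_summaries.csv and results/exp{1,2}_rt_aic.csv.
"""

from pathlib import Path

from dimvision import io, pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    logs = io.read_trial_log(RESULTS / "trial_logs.csv")
    for exp in (1, 2):
        ana = pipeline.analyze_times(logs, exp)
        s = ana.summaries.iloc[0]
        print(f"\nexperiment {exp}: median response time "
              f"{s['response_time_median']:.2f} s "
              f"(Q1-Q3 {s['response_time_q1']:.2f}-{s['response_time_q3']:.2f}, "
              f"n = {int(s['n_response_time'])}); median inter-trial time "
              f"{s['inter_trial_median']:.2f} s "
              f"(Q1-Q3 {s['inter_trial_q1']:.2f}-{s['inter_trial_q3']:.2f})")
        print(ana.aic_table.round(1).to_string(index=False))
        print(f"best model: {ana.best_model}; LRT vs null "
              f"chi2_{ana.lrt_df} = {ana.lrt_statistic:.1f}, p = {ana.lrt_p:.3g}")
        ana.summaries.to_csv(RESULTS / f"exp{exp}_time_summaries.csv", index=False)
        ana.aic_table.to_csv(RESULTS / f"exp{exp}_rt_aic.csv", index=False)


if __name__ == "__main__":
    main()
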