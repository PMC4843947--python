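"""Case-control comparison of connectivity entropy on a synthetic cohort.

Simulates a cohort with designed group effects (early-stage patients:
wider secondary / narrower tertiary connectivity distributions;
late-stage: everything narrower, tertiary most), runs the full
pipeline, and prints the residualized group comparisons and
entropy-symptom correlations.
"""

from fcentropy import SimulationConfig, generate_cohort, run_study

cfg = SimulationConfig(n_controls=17, n_early=17, n_late=17)
cohort = generate_cohort(cfg, seed=1)
study = run_study(cohort.table, cohort.streamlines, cohort.timeseries)

report = study["report"]
cols = ["duration_stratum", "stratum", "cohen_d", "direction", "p_value", "symptom_r"]
print(report[cols].round(3).to_string(index=False))
print()
print("direction = sign of (patient mean - control mean) after removing")
print("age, sex and dose; Cohen's d is the standardized magnitude.")
agree = study["consensus_agreement"]
print(
    f"\nconsensus path classes agree between groups on "
    f"{agree.n_agreed}/{agree.n_pairs} pairs ({100 * agree.fraction:.1f}%)"
)
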