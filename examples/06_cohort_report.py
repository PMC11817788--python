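"""Cohort-level pipeline: spared versus impaired seizures.

Generates a mixed cohort (half spared-type, half impaired-type profiles),
runs every per-session analysis, and prints the aggregated group
statistics: period ANOVAs with Bonferroni-corrected baseline contrasts
and the spared-vs-impaired Mann-Whitney comparisons of ictal delta power
and ACh change.
"""

from ictal import SimConfig, generate_cohort, run_pipeline

cohort = generate_cohort(
    SimConfig(seed=1, signals=("ofc_lfp", "photo")), n_sessions=12, mixture_weight=0.5
)
report = run_pipeline([s for s, _ in cohort], event_spectra=False)

print("seizure classes:", report.summary["seizure_class_counts"])
cols = ["metric", "grouping", "groups", "mean", "p_corrected", "significant"]
rows = report.comparisons[
    report.comparisons["grouping"].isin(["baseline-vs-ictal", "spared-vs-impaired"])
]
print(rows[cols].to_string(index=False))
print("impaired seizures carry more ictal delta power and a larger ACh drop.")
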