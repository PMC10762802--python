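"""Full pipeline on a small simulated cohort: traces in, session means out.

Simulates raw 220-Hz recordings for a few participants across the three
sessions (natural, weighted helmet, natural again), runs filtering,
segmentation, event detection and QC, and compares the recovered session
means with the injected ground truth.
"""

from gazeshift import process_cohort, simulate_cohort

participants, truth = simulate_cohort(n_per_group=3, seed=1)
table, reports = process_cohort(participants)

large = truth[truth.amplitude_deg.isin([75.0, 80.0])]
injected = large.groupby("session")["true_ratio_pct"].mean()
recovered = table.groupby("session")["mean_ratio_pct"].mean()

print("session        injected   recovered   (head-oscillation ratio, %)")
for session in ("unweighted1", "weighted", "unweighted2"):
    print(f"{session:12s}   {injected[session]:7.2f}   {recovered[session]:9.2f}")
retained = sum(r.n_retained for r in reports.values()) / len(reports)
print(f"mean retained trials/session: {retained:.1f} of 43")
# The weighted session oscillates most; the second unweighted session least
# (learning), and the pipeline recovers the injected means within a few %.
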