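"""Temporal state metrics and permutation group comparison.

Simulates a 7-vs-8 cohort in which the case group's state 2 is stickier,
computes the four per-subject temporal measures from the true state paths,
and runs the 10,000-permutation group test with BH-FDR correction. The
injected state should surface with the largest occupancy difference.
"""

from netdyn import CohortSpec, compare_all, group_summary, make_ground_truth, simulate_cohort
from netdyn.experiments import cohort_metrics_from_paths

truth = make_ground_truth(n_states=4, n_parcels=8, self_persistence=0.9,
                          separation=3.0, seed=3)
cohort = simulate_cohort(truth, CohortSpec(n_subjects_per_group=(7, 8),
                                           samples_per_subject=21_600,
                                           group_effect={2: 0.05}, seed=3))
metrics = cohort_metrics_from_paths(cohort)
labels = dict(zip(cohort.subject_ids, cohort.group_labels))

summary = group_summary(metrics, labels)
print("control-minus-case fractional-occupancy differences (percentage points):")
for _, row in summary.iterrows():
    print(f"  state {int(row.state)}: {row.fractional_occupancy_diff:+.2f}")

report = compare_all(metrics, labels, n_permutations=10_000, seed=0, q=0.05)
fo = report[report.measure == "fractional_occupancy"]
print("\npermutation test, fractional occupancy (10,000 relabellings, BH at q=0.05):")
for _, row in fo.iterrows():
    flag = " *" if row.significant else ""
    print(f"  state {int(row.state)}: diff {row.observed_diff:+.2f}, "
          f"p {row.p:.4f}, adjusted {row.p_adjusted:.4f}{flag}")
print("(state 2 is the perturbed one: its negative difference means the case "
      "group occupies it more; occupancies sum to 100 %, so the other states "
      "show compensatory positive differences)")
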