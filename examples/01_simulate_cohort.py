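"""Simulate a two-group cohort with known state dynamics.

Builds a sticky 8-state ground truth over 38 parcels (250 ms expected state
lifetime at 40 Hz), perturbs one state's self-transition probability in the
case group, and prints how that shifts the chain's long-run occupancy.
"""

import numpy as np

from netdyn import CohortSpec, make_ground_truth, perturb_transitions, simulate_cohort

truth = make_ground_truth(n_states=8, n_parcels=38, self_persistence=0.9,
                          separation=3.0, seed=0)
print(f"expected state lifetime: {1 / (1 - 0.9):.0f} samples "
      f"= {1000 / (1 - 0.9) / truth.sampling_rate:.0f} ms at {truth.sampling_rate:g} Hz")

effect = {4: 0.05}  # case group dwells longer in state 4
case_truth = perturb_transitions(truth, effect)
pi_a, pi_b = truth.stationary_distribution(), case_truth.stationary_distribution()
print(f"state 4 long-run occupancy: control {100 * pi_a[4]:.2f} % "
      f"vs case {100 * pi_b[4]:.2f} % "
      f"(injected self-transition +{effect[4]:.2f})")

cohort = simulate_cohort(truth, CohortSpec(n_subjects_per_group=(7, 8),
                                           samples_per_subject=21_600,
                                           group_effect=effect, seed=0))
print(f"cohort: {len(cohort.subject_ids)} subjects, "
      f"each {cohort.envelopes[0].shape[0]} parcels x "
      f"{cohort.envelopes[0].shape[1]} envelope samples (9 min at 40 Hz); "
      "true state paths retained for recovery scoring")
emp = np.bincount(cohort.true_paths[-1], minlength=8) / 21_600
print(f"last case subject's empirical occupancy of state 4: {100 * emp[4]:.2f} %")
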