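"""Regional gene expression and network dynamics, end to end.

Simulates a graded-effect cohort over 68 parcels (one per cortical
expression region), couples a synthetic expression vector to the injected
effect profile, scores each state's spatial map by the top-20-region
expression sum against a 10,000-draw random-subset null, and rank-correlates
the per-state expression p-values with the group-difference p-values.
A strongly positive rho recovers the built-in coupling.
"""

from netdyn import RunConfig, run_pipeline
from netdyn.synthetic import graded_group_effect

config = RunConfig(
    n_states=8, n_parcels=68, samples_per_subject=21_600,
    n_subjects_per_group=(7, 8), group_effect=graded_group_effect(8),
    expression_coupling=1.0, expression_noise_sd=0.0,
    decode_mode="true_paths", n_permutations=10_000,
    n_null_iterations=10_000, seed=0,
)
report = run_pipeline(config)

print("per-state expression score (top-20-region sum) and p vs random subsets:")
for _, row in report["expression_results"].iterrows():
    print(f"  state {int(row.state)}: score {row.score:+7.2f}, p {row.p:.4f}")

print("\nSpearman association between expression p and group-difference p:")
for _, row in report["association"].iterrows():
    print(f"  {row.measure:>22s}: rho {row.rho:+.3f}, p {row.p:.4f}")
print("(positive rho: states with stronger injected group effects carry "
      "higher expression — the coupling the generator built in)")
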