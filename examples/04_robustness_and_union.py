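"""Leave-one-out robustness and the union of perturbed interactions.

Reruns a pathway's full analysis with each case sample removed to check the
stability of its significance call, then unions the best sub-pathway's
interactions over significant conditions to measure what share of the
pathway is ever implicated.
"""

from subpert import (
    AnnealParams,
    ScreenConfig,
    SyntheticConfig,
    generate_dataset,
    leave_one_out_robustness,
    perturbed_interaction_union,
    restrict_to_measured,
    run_screen,
)

config = SyntheticConfig(
    n_genes=12, n_edges=18, planted_edge_fraction=0.3, effect_size=2.5,
    n_case=8, n_control=8, n_background_genes=10, seed=4,
)
ds = generate_dataset(config)
screen_config = ScreenConfig(
    case_label="case", control_label="control",
    anneal=AnnealParams(iteration_multiplier=50), k_permutations=100, seed=3,
)

record = leave_one_out_robustness(ds.pathway, ds.expression, ds.labels, screen_config)
print(
    f"significant on full data: {record.significant_full}; "
    f"agreement over {config.n_case} leave-one-out reruns: "
    f"{record.agreement_fraction:.2f}"
)

results = run_screen([ds.pathway], ds.expression, ds.labels, screen_config)
measured = restrict_to_measured(ds.pathway, ds.expression)
count, fraction = perturbed_interaction_union(results, measured, p_threshold=0.05)
print(
    f"union of perturbed interactions: {count}/{measured.n_interactions} "
    f"({100 * fraction:.0f}% of measured interactions)"
)
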