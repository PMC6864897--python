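"""Characterize a detected sub-network against the six-division atlas
partition.

Classifies each link of a component as isocoupled (within one supraordinate
division) or anisocoupled (between divisions), tabulates the division-pair
spatial profile, ranks the most significant links and computes per-subject
mean sub-network connectivity.
"""

from connectome_nbs import (
    GroundTruth,
    NBSSettings,
    SimulationConfig,
    classify_links,
    load_default_partition,
    lobe_pair_distribution,
    pearson_connectome,
    run_nbs,
    simulate_cohort,
    subnetwork_mean_connectivity,
    top_fraction_links,
)

partition = load_default_partition()  # 116 atlas labels -> 6 divisions

# plant a distributed cross-division network on the full 116-node atlas:
# four frontal hubs coupled to temporal, parietal, occipital, cingulate
# and subcortical targets, plus two frontal-frontal links
edges = frozenset({(2, 80), (2, 57), (2, 43), (2, 71),
                   (6, 84), (6, 60), (6, 49), (6, 77),
                   (22, 85), (22, 65), (22, 31), (22, 108),
                   (23, 81), (23, 67), (23, 37), (23, 41),
                   (2, 6), (22, 23)})
truth = GroundTruth(planted_edges=edges, effect_size=0.35)
cfg = SimulationConfig(n_subjects_per_group=30, n_nodes=116, n_frames=150,
                       baseline_correlation=0.0, motion_spike_rate=0.0,
                       seed=13)
bundles, _, design = simulate_cohort(cfg, truth)
matrices = [pearson_connectome(b) for b in bundles]
result = run_nbs(matrices, design, NBSSettings(n_permutations=200, seed=2))

comp = result.components[0]
print(f"detected component: {comp.extent} links, p_FWE = {comp.p_fwe:.3f}")

cls = classify_links(comp, partition)
print(f"isocoupled {cls.iso_percent:.1f}% vs "
      f"anisocoupled {cls.aniso_percent:.1f}%")

pairs = lobe_pair_distribution(cls)
print("top division pairs:")
print(pairs.head(5).to_string(index=False))

top = top_fraction_links(result.edge_stats, comp, fraction=0.10)
print(f"top-10% links ({len(top)}): "
      f"{[(partition.labels[i], partition.labels[j]) for i, j in top[:3]]}")

scores = subnetwork_mean_connectivity(matrices, comp)
by_group = scores.merge(design.table, on="subject_id").groupby("group")
print(by_group["score"].mean().round(3).to_string())
# The low-expression group's mean sub-network connectivity exceeds the
# high-expression group's: the planted hyperconnectivity, as a per-subject
# summary ready for follow-up tests.
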