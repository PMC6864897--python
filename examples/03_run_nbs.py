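"""Detect a group-differing sub-network with network-based statistics.

Edge-wise GLM (weight ~ group + age + sex + site + protocol), suprathreshold
component extraction at p <= .005, and a permutation null of the maximal
component extent yielding a family-wise-error-corrected p per component.
"""

from connectome_nbs import (
    GroundTruth,
    NBSSettings,
    SimulationConfig,
    default_planted_edges,
    pearson_connectome,
    run_nbs,
    simulate_cohort,
)

truth = GroundTruth(planted_edges=default_planted_edges(20, 10),
                    effect_size=0.3)
cfg = SimulationConfig(n_subjects_per_group=30, n_nodes=20, n_frames=150,
                       motion_spike_rate=0.0, seed=11)
bundles, _, design = simulate_cohort(cfg, truth)
matrices = [pearson_connectome(b) for b in bundles]

result = run_nbs(matrices, design,
                 NBSSettings(threshold_p=0.005, n_permutations=500, seed=1))

print(f"null max-extent distribution: "
      f"median {int(sorted(result.null_distribution)[250])}, "
      f"max {result.null_distribution.max()}")
for k, comp in enumerate(result.components):
    print(f"component {k}: {comp.extent} links over {len(comp.nodes)} "
          f"nodes, p_FWE = {comp.p_fwe:.4f}, "
          f"{comp.direction_summary:.0%} of links higher in L")

found = set(result.components[0].edges)
planted = set(truth.planted_edges)
print(f"overlap with planted edges: Jaccard = "
      f"{len(found & planted) / len(found | planted):.2f}")
# A small p_FWE with a Jaccard near 1 means the procedure recovered the
# planted hyperconnected component almost exactly.
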