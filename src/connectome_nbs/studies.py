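"""Simulation studies: error calibration and parameter recovery.

Each study generates synthetic cohorts with known ground truth, pushes them
through the same code paths a real analysis would use, and summarizes how
often the inference behaves as designed: the family-wise error rate of the
cluster test under the global null, the recovery of a planted hyperconnected
component at the reference effect size, the type-I error of the genotype x
sex interaction test, and the sign recovery of a planted brain-behavior
loading by partial correlation.

All studies derive their per-replicate seeds from a single master seed, so
results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .association import interaction_test, partial_correlation
from .connectome import pearson_connectome
from .nbs import NBSComponent, NBSSettings, run_nbs
from .netchar import subnetwork_mean_connectivity
from .simulate import (
    REFERENCE_BEHAVIORAL_LOADING,
    REFERENCE_EFFECT_SIZE,
    GroundTruth,
    SimulationConfig,
    default_planted_edges,
    simulate_cohort,
)

__all__ = [
    "fwe_calibration",
    "planted_recovery",
    "interaction_type1_error",
    "loading_sign_recovery",
]


def _seeds(master_seed: int, n: int, stream: int) -> np.ndarray:
    """n per-replicate seeds below 2**31, derived from one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, stream]))
    return rng.integers(0, 2**31 - 1, size=n)


def fwe_calibration(
    n_cohorts: int = 200,
    n_nodes: int = 20,
    n_subjects_per_group: int = 30,
    n_frames: int = 120,
    n_permutations: int = 99,
    threshold_p: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the cluster test under the global null.

    Simulates effect-free cohorts, runs the full NBS procedure on their
    Pearson connectomes, and reports the fraction of cohorts whose largest
    component reaches ``p_fwe <= alpha``. Under correct FWE control this
    fraction is ~alpha.

    The default initial threshold here is .05 rather than the analysis
    default .005: at .005 a 20-node null graph has ~1 expected
    suprathreshold edge, so maximal extents collapse onto {0, 1, 2} and the
    permutation p inherits strong tie-induced conservatism (the test stays
    valid but its rejection rate sits well below alpha, telling us about
    discreteness rather than calibration). A denser threshold keeps the
    null component-size distribution non-degenerate; FWE control of the
    max-statistic procedure is a property at any fixed threshold.
    """
    cohort_seeds = _seeds(seed, n_cohorts, stream=1)
    nbs_seeds = _seeds(seed, n_cohorts, stream=2)
    hits = 0
    min_ps = []
    for cs, ns in zip(cohort_seeds, nbs_seeds):
        cfg = SimulationConfig(
            n_subjects_per_group=n_subjects_per_group, n_nodes=n_nodes,
            n_frames=n_frames, motion_spike_rate=0.0, seed=int(cs))
        bundles, _, design = simulate_cohort(cfg, GroundTruth.null())
        mats = [pearson_connectome(b) for b in bundles]
        res = run_nbs(mats, design,
                      NBSSettings(threshold_p=threshold_p,
                                  n_permutations=n_permutations,
                                  seed=int(ns)))
        min_ps.append(res.min_p_fwe)
        if res.min_p_fwe <= alpha:
            hits += 1
    return {
        "fwe_rate": hits / n_cohorts,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
        "min_p_fwe": min_ps,
    }


def planted_recovery(
    n_cohorts: int = 20,
    n_nodes: int = 20,
    n_subjects_per_group: int = 30,
    n_frames: int = 150,
    n_planted_edges: int = 10,
    effect_size: float = REFERENCE_EFFECT_SIZE,
    n_permutations: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of a planted hyperconnected component.

    For each cohort, reports whether the largest detected component is
    FWE-significant and its edge-set Jaccard overlap with the planted edges.
    """
    planted = default_planted_edges(n_nodes, n_planted_edges)
    truth = GroundTruth(planted_edges=planted, effect_size=effect_size)
    cohort_seeds = _seeds(seed, n_cohorts, stream=3)
    nbs_seeds = _seeds(seed, n_cohorts, stream=4)
    jaccards, significant = [], []
    for cs, ns in zip(cohort_seeds, nbs_seeds):
        cfg = SimulationConfig(
            n_subjects_per_group=n_subjects_per_group, n_nodes=n_nodes,
            n_frames=n_frames, motion_spike_rate=0.0, seed=int(cs))
        bundles, _, design = simulate_cohort(cfg, truth)
        mats = [pearson_connectome(b) for b in bundles]
        res = run_nbs(mats, design,
                      NBSSettings(n_permutations=n_permutations,
                                  seed=int(ns)))
        if res.components:
            top = res.components[0]
            found = set(top.edges)
            jaccards.append(
                len(found & planted) / len(found | planted))
            significant.append(top.p_fwe <= alpha)
        else:
            jaccards.append(0.0)
            significant.append(False)
    jaccards = np.asarray(jaccards)
    significant = np.asarray(significant)
    recovered = (jaccards >= 0.5) & significant
    return {
        "recovery_rate": float(recovered.mean()),
        "detection_rate": float(significant.mean()),
        "mean_jaccard": float(jaccards.mean()),
        "jaccards": jaccards.tolist(),
        "n_cohorts": n_cohorts,
        "effect_size": effect_size,
    }


def interaction_type1_error(
    n_replicates: int = 200,
    n_nodes: int = 8,
    n_subjects_per_group: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the genotype x sex interaction test.

    Under the null generator (no planted effect, no sex-specific effect) the
    rejection rate at ``alpha`` should match ``alpha``. Scores are the mean
    structural connectivity over a fixed small edge set.
    """
    component = NBSComponent(
        edges=sorted(default_planted_edges(n_nodes, 4)),
        direction_summary=1.0)
    rep_seeds = _seeds(seed, n_replicates, stream=5)
    rejections = 0
    for rs in rep_seeds:
        cfg = SimulationConfig(
            n_subjects_per_group=n_subjects_per_group, n_nodes=n_nodes,
            n_frames=16, seed=int(rs))
        _, structurals, design = simulate_cohort(cfg, GroundTruth.null())
        scores = subnetwork_mean_connectivity(structurals, component)
        res = interaction_test(scores, design)
        if res.p <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}


def loading_sign_recovery(
    n_replicates: int = 100,
    n_nodes: int = 10,
    n_subjects_per_group: int = 30,
    loading: float = REFERENCE_BEHAVIORAL_LOADING,
    behavioral: str = "erq_reappraisal",
    seed: int = 0,
) -> dict:
    """Sign recovery of a planted brain-behavior loading.

    The generator loads a behavioral score on the standardized mean
    planted-edge structural connectivity; partial correlation (controlling
    age, sex, site) should recover the loading's sign.
    """
    planted = default_planted_edges(n_nodes, 5)
    component = NBSComponent(edges=sorted(planted), direction_summary=1.0)
    truth = GroundTruth(planted_edges=planted, effect_size=0.0)
    rep_seeds = _seeds(seed, n_replicates, stream=6)
    correct = 0
    rs_list = []
    for rs in rep_seeds:
        cfg = SimulationConfig(
            n_subjects_per_group=n_subjects_per_group, n_nodes=n_nodes,
            n_frames=16, seed=int(rs),
            behavioral_loading={behavioral: loading})
        _, structurals, design = simulate_cohort(cfg, truth)
        scores = subnetwork_mean_connectivity(structurals, component)
        res = partial_correlation(scores, behavioral, design)
        rs_list.append(res.r)
        if np.sign(res.r) == np.sign(loading):
            correct += 1
    return {"sign_recovery_rate": correct / n_replicates,
            "mean_partial_r": float(np.mean(rs_list)),
            "loading": loading,
            "n_replicates": n_replicates}
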