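import numpy as np
import pandas as pd
import pytest

from connectome_nbs import (
    CohortDesign,
    ConnectivityMatrix,
    GroundTruth,
    SimulationConfig,
    TimeSeriesBundle,
    default_planted_edges,
    pearson_connectome,
    simulate_cohort,
)


def make_design(
    n_per_group: int = 15,
    seed: int = 0,
    male_frac: tuple[float, float] = (0.5, 0.5),
) -> CohortDesign:
    """Small balanced design table for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, frac in zip(("H", "L"), male_frac):
        n_male = int(round(n_per_group * frac))
        for k in range(n_per_group):
            rows.append({
                "subject_id": f"sub-{label}{k:03d}",
                "group": label,
                "age": float(rng.normal(33, 10)),
                "sex": "M" if k < n_male else "F",
                "site": f"site{rng.integers(3) + 1}",
                "protocol": f"prot{rng.integers(2) + 1}",
            })
    return CohortDesign(pd.DataFrame(rows))


def random_functional_matrices(
    design: CohortDesign, n_nodes: int = 10, seed: int = 0
) -> list[ConnectivityMatrix]:
    """Independent random correlation-like matrices, one per subject."""
    rng = np.random.default_rng(seed)
    out = []
    for sid in design.subject_ids:
        w = np.tanh(rng.normal(0.1, 0.3, size=(n_nodes, n_nodes)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        out.append(ConnectivityMatrix(weights=w, modality="functional",
                                      subject_id=sid))
    return out


def make_bundle(
    signals: np.ndarray,
    modality: str = "rest",
    tr: float = 2.0,
    motion: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
    seed: int = 0,
) -> TimeSeriesBundle:
    """Wrap a signal matrix with benign motion/nuisance traces."""
    n = signals.shape[0]
    rng = np.random.default_rng(seed)
    if motion is None:
        motion = np.cumsum(rng.normal(0, 1e-3, size=(n, 6)), axis=0)
    if nuisance is None:
        nuisance = rng.standard_normal((n, 2))
        nuisance_names = ["wm", "csf"]
    return TimeSeriesBundle(
        signals=signals, motion=motion, nuisance=nuisance,
        nuisance_names=nuisance_names or [], sampling_interval=tr,
        modality=modality,
    )


@pytest.fixture(scope="session")
def null_cohort_small():
    """One motion-free null cohort (12 nodes, 15+15 subjects)."""
    cfg = SimulationConfig(n_subjects_per_group=15, n_nodes=12,
                           n_frames=100, motion_spike_rate=0.0, seed=7)
    return simulate_cohort(cfg, GroundTruth.null())


@pytest.fixture(scope="session")
def planted_cohort():
    """Reference planted-effect cohort (20 nodes, 30+30, effect 0.3)."""
    cfg = SimulationConfig(n_subjects_per_group=30, n_nodes=20,
                           n_frames=150, motion_spike_rate=0.0, seed=11)
    truth = GroundTruth(planted_edges=default_planted_edges(20, 10),
                        effect_size=0.3)
    bundles, structurals, design = simulate_cohort(cfg, truth)
    return bundles, structurals, design, truth


def pearson_stack(bundles) -> list[ConnectivityMatrix]:
    return [pearson_connectome(b) for b in bundles]
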