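"""Delimited-text cohort layout and result writers.

A cohort directory holds one sub-directory per subject plus cohort-level
tables::

    cohort/
      design.csv                  subject_id, group, covariates, behavioral
      truth.json                  planted ground truth (synthetic cohorts)
      cohort.json                 sampling interval, modality, node labels
      subjects/<id>/timeseries.tsv   frames x nodes, node-label header
      subjects/<id>/motion.tsv       frames x 6
      subjects/<id>/nuisance.tsv     frames x k, named columns
      subjects/<id>/structural.tsv   nodes x nodes streamline counts

All files are tab- or comma-delimited text: inspectable, diff-able and
language-portable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortDesign, ConnectivityMatrix, TimeSeriesBundle
from .nbs import EdgeStatMap, NBSComponent, NBSResult
from .simulate import GroundTruth

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_truth",
    "write_connectome",
    "read_matrix_tsv",
    "write_edge_table",
    "file_digest",
]


def _node_labels(n: int, labels: list[str] | None) -> list[str]:
    return labels if labels is not None else [f"node{i:03d}" for i in range(n)]


def write_cohort(
    out_dir,
    bundles: list[TimeSeriesBundle],
    structurals: list[ConnectivityMatrix],
    design: CohortDesign,
    truth: GroundTruth | None = None,
    node_labels: list[str] | None = None,
) -> Path:
    """Write a cohort to the on-disk layout. Returns the cohort root."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    n_nodes = bundles[0].n_nodes
    labels = _node_labels(n_nodes, node_labels)
    design.table.to_csv(root / "design.csv", index=False)
    meta = {
        "sampling_interval": bundles[0].sampling_interval,
        "modality": bundles[0].modality,
        "node_labels": labels,
    }
    (root / "cohort.json").write_text(json.dumps(meta, indent=2))
    if truth is not None:
        (root / "truth.json").write_text(json.dumps({
            "planted_edges": sorted(list(e) for e in truth.planted_edges),
            "effect_size": truth.effect_size,
            "null_cohort": truth.null_cohort,
        }, indent=2))
    by_id = {m.subject_id: m for m in structurals}
    for b in bundles:
        sdir = root / "subjects" / b.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(b.signals, columns=labels).to_csv(
            sdir / "timeseries.tsv", sep="\t", index=False)
        pd.DataFrame(
            b.motion,
            columns=["trans_x", "trans_y", "trans_z",
                     "rot_x", "rot_y", "rot_z"],
        ).to_csv(sdir / "motion.tsv", sep="\t", index=False)
        pd.DataFrame(b.nuisance, columns=b.nuisance_names).to_csv(
            sdir / "nuisance.tsv", sep="\t", index=False)
        struct = by_id.get(b.subject_id)
        if struct is not None:
            pd.DataFrame(struct.weights.astype(int), columns=labels).to_csv(
                sdir / "structural.tsv", sep="\t", index=False)
    return root


def read_truth(cohort_dir) -> GroundTruth | None:
    path = Path(cohort_dir) / "truth.json"
    if not path.exists():
        return None
    raw = json.loads(path.read_text())
    return GroundTruth(
        planted_edges=frozenset(tuple(e) for e in raw["planted_edges"]),
        effect_size=raw["effect_size"],
        null_cohort=raw["null_cohort"],
    )


def read_cohort(
    cohort_dir,
) -> tuple[list[TimeSeriesBundle], list[ConnectivityMatrix], CohortDesign]:
    """Read a cohort directory back into memory (order follows design.csv)."""
    root = Path(cohort_dir)
    design = CohortDesign(pd.read_csv(root / "design.csv"))
    meta = json.loads((root / "cohort.json").read_text())
    bundles, structurals = [], []
    for sid in design.subject_ids:
        sdir = root / "subjects" / str(sid)
        signals = pd.read_csv(sdir / "timeseries.tsv", sep="\t")
        motion = pd.read_csv(sdir / "motion.tsv", sep="\t")
        nuis = pd.read_csv(sdir / "nuisance.tsv", sep="\t")
        bundles.append(TimeSeriesBundle(
            signals=signals.to_numpy(float),
            motion=motion.to_numpy(float),
            nuisance=nuis.to_numpy(float),
            nuisance_names=list(nuis.columns),
            sampling_interval=meta["sampling_interval"],
            modality=meta["modality"],
            subject_id=str(sid),
        ))
        spath = sdir / "structural.tsv"
        if spath.exists():
            w = pd.read_csv(spath, sep="\t").to_numpy(float)
            structurals.append(ConnectivityMatrix(
                weights=np.maximum(w, w.T), modality="structural",
                subject_id=str(sid)))
    return bundles, structurals, design


def write_connectome(matrix: ConnectivityMatrix, path) -> None:
    fmt = "%d" if matrix.modality == "structural" else "%.10g"
    np.savetxt(path, matrix.weights, delimiter="\t", fmt=fmt)


def read_matrix_tsv(path) -> np.ndarray:
    """Read a headerless or headered node x node TSV matrix."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float)


def write_edge_table(
    stats_map: EdgeStatMap,
    components: list[NBSComponent],
    path,
) -> pd.DataFrame:
    """Write edges.tsv: node_i, node_j, F, p, direction, component_id.

    Component ids are 0-based into the extent-sorted component list; edges
    outside every component carry -1. Node indices are 0-based positions in
    the atlas label list.
    """
    comp_of = {}
    for cid, comp in enumerate(components):
        for e in comp.edges:
            comp_of[e] = cid
    df = pd.DataFrame({
        "node_i": [e[0] for e in stats_map.edges],
        "node_j": [e[1] for e in stats_map.edges],
        "F": stats_map.f_stat,
        "p": stats_map.p_value,
        "direction": stats_map.direction.astype(int),
        "component_id": [comp_of.get(e, -1) for e in stats_map.edges],
    })
    df.to_csv(path, sep="\t", index=False)
    return df


def file_digest(path) -> str:
    """SHA-256 of a file's bytes (for run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
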