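"""Top-level pipeline driver: validate -> connectomes -> NBS ->
characterization -> associations, with a reproducibility manifest.

All randomness flows from the single config seed through named substreams,
so re-running a config reproduces every output bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import interaction_test, partial_correlation
from .connectome import build_functional_connectome, ingest_structural
from .datatypes import (
    BEHAVIORAL_COLUMNS,
    DESIGN_REQUIRED,
    CohortDesign,
    SubjectExcludedError,
)
from .io import file_digest, read_cohort, write_connectome, write_edge_table
from .nbs import NBSSettings, run_nbs
from .netchar import (
    LobePartition,
    classify_links,
    lobe_pair_distribution,
    load_default_partition,
    subnetwork_mean_connectivity,
    top_fraction_links,
)

__all__ = ["PipelineConfig", "validate_cohort", "run_pipeline"]

log = logging.getLogger("connectome_nbs")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    cohort_dir: str
    out_dir: str
    modalities: tuple[str, ...] = ("rest",)
    threshold_p: float = 0.005
    n_permutations: int = 5000
    seed: int = 0
    fd_threshold: float = 0.5
    max_flagged_fraction: float = 0.10
    fisher_z: bool = True
    add_one_p: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "site", "protocol")
    atlas_path: str | None = None
    top_fraction: float = 0.10

    def __post_init__(self) -> None:
        self.modalities = tuple(self.modalities)
        self.covariates = tuple(self.covariates)
        allowed = {"faces", "nback", "rest", "structural"}
        bad = set(self.modalities) - allowed
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        if not Path(self.cohort_dir).is_dir():
            raise ValueError(f"cohort_dir {self.cohort_dir!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def nbs_settings(self) -> NBSSettings:
        return NBSSettings(
            threshold_p=self.threshold_p,
            n_permutations=self.n_permutations,
            seed=self.seed,
            fisher_z=self.fisher_z,
            add_one_p=self.add_one_p,
            covariates=self.covariates,
        )


def validate_cohort(cohort_dir) -> dict:
    """Machine-readable structural QC of a cohort directory.

    Checks layout completeness, design-table integrity and dimensional
    consistency. Returns ``{"passed": bool, "failures": [...],
    "n_subjects": int}``.
    """
    root = Path(cohort_dir)
    failures: list[str] = []
    n_subjects = 0
    design_path = root / "design.csv"
    if not design_path.exists():
        return {"passed": False, "failures": ["design.csv missing"],
                "n_subjects": 0}
    table = pd.read_csv(design_path)
    for col in DESIGN_REQUIRED:
        if col not in table.columns:
            failures.append(f"design.csv missing column {col!r}")
    if not failures:
        try:
            CohortDesign(table)
        except ValueError as exc:
            failures.append(f"design invalid: {exc}")
    if not (root / "cohort.json").exists():
        failures.append("cohort.json missing")
        return {"passed": False, "failures": failures, "n_subjects": 0}
    meta = json.loads((root / "cohort.json").read_text())
    n_nodes = len(meta.get("node_labels", []))
    subject_ids = (list(table["subject_id"].astype(str))
                   if "subject_id" in table.columns else [])
    n_subjects = len(subject_ids)
    for sid in subject_ids:
        sdir = root / "subjects" / sid
        if not sdir.is_dir():
            failures.append(f"subject {sid}: directory missing")
            continue
        for fname in ("timeseries.tsv", "motion.tsv", "nuisance.tsv"):
            if not (sdir / fname).exists():
                failures.append(f"subject {sid}: {fname} missing")
        ts_path = sdir / "timeseries.tsv"
        if ts_path.exists():
            ts = pd.read_csv(ts_path, sep="\t")
            if n_nodes and ts.shape[1] != n_nodes:
                failures.append(
                    f"subject {sid}: {ts.shape[1]} nodes, expected {n_nodes}")
            if ts.shape[0] < 8:
                failures.append(f"subject {sid}: fewer than 8 frames")
            if ts.isna().any().any():
                failures.append(f"subject {sid}: missing signal values")
        mot_path = sdir / "motion.tsv"
        if mot_path.exists():
            mot = pd.read_csv(mot_path, sep="\t")
            if mot.shape[1] != 6:
                failures.append(
                    f"subject {sid}: motion has {mot.shape[1]} columns, "
                    "expected 6")
        st_path = sdir / "structural.tsv"
        if st_path.exists():
            w = pd.read_csv(st_path, sep="\t").to_numpy(float)
            if w.shape[0] != w.shape[1]:
                failures.append(f"subject {sid}: structural not square")
            elif (w < 0).any():
                failures.append(f"subject {sid}: negative streamline counts")
    return {"passed": not failures, "failures": failures,
            "n_subjects": n_subjects}


def _partition(config: PipelineConfig) -> LobePartition:
    if config.atlas_path:
        return LobePartition.from_tsv(config.atlas_path)
    return load_default_partition()


def _run_modality(
    config: PipelineConfig,
    modality: str,
    bundles,
    structurals,
    design: CohortDesign,
    out_dir: Path,
    n_nodes: int,
) -> dict:
    """One modality end to end; returns its manifest entry."""
    out_dir.mkdir(parents=True, exist_ok=True)
    qc_rows = []
    matrices = []
    if modality == "structural":
        for m in structurals:
            matrices.append(ingest_structural(m.weights, m.subject_id))
            qc_rows.append({"subject_id": m.subject_id,
                            "flagged_fraction": np.nan,
                            "excluded": False, "zero_variance_nodes": ""})
    else:
        for b in bundles:
            zero_var: list[int] = []
            try:
                mat, fdser = build_functional_connectome(
                    b, fd_threshold=config.fd_threshold,
                    max_flagged_fraction=config.max_flagged_fraction,
                    qc_log=zero_var)
            except SubjectExcludedError as exc:
                log.warning("excluding %s: %s", b.subject_id, exc)
                from .connectome import compute_fd
                fdser = compute_fd(b.motion, threshold=config.fd_threshold)
                qc_rows.append({
                    "subject_id": b.subject_id,
                    "flagged_fraction": fdser.flagged_fraction,
                    "excluded": True, "zero_variance_nodes": ""})
                continue
            matrices.append(mat)
            qc_rows.append({
                "subject_id": b.subject_id,
                "flagged_fraction": fdser.flagged_fraction,
                "excluded": False,
                "zero_variance_nodes": ";".join(map(str, zero_var))})
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out_dir / "qc.csv", index=False)
    kept = {m.subject_id for m in matrices}
    sub_design = design.subset(
        design.table["subject_id"].astype(str).isin(kept).to_numpy())
    for m in matrices:
        write_connectome(
            m, out_dir / f"connectome_{m.subject_id}.tsv")

    result = run_nbs(matrices, sub_design, config.nbs_settings())
    result.to_json(out_dir / "nbs_result.json")
    write_edge_table(result.edge_stats, result.components,
                     out_dir / "edges.tsv")

    entry: dict = {
        "modality": modality,
        "n_subjects": len(matrices),
        "n_excluded": int(qc["excluded"].sum()) if len(qc) else 0,
        "components": [
            {"extent": c.extent, "p_fwe": c.p_fwe} for c in result.components
        ],
    }
    if not result.components:
        return entry

    comp = result.components[0]
    partition = _partition(config)
    if n_nodes == len(partition):
        classification = classify_links(comp, partition)
        classification.table.to_csv(out_dir / "classification.tsv",
                                    sep="\t", index=False)
        pairs = lobe_pair_distribution(classification)
        pairs.to_csv(out_dir / "lobe_pairs.tsv", sep="\t", index=False)
        entry["iso_percent"] = classification.iso_percent
        entry["aniso_percent"] = classification.aniso_percent
    top = top_fraction_links(result.edge_stats, comp,
                             fraction=config.top_fraction)
    pd.DataFrame(top, columns=["node_i", "node_j"]).to_csv(
        out_dir / "top_links.tsv", sep="\t", index=False)
    scores = subnetwork_mean_connectivity(matrices, comp)
    scores.to_csv(out_dir / "subnetwork_scores.csv", index=False)

    assoc_rows = []
    try:
        res = interaction_test(scores, sub_design)
        assoc_rows.append(res)
    except ValueError as exc:
        log.warning("interaction test skipped: %s", exc)
    for beh in BEHAVIORAL_COLUMNS:
        if beh in sub_design.table.columns:
            try:
                assoc_rows.append(
                    partial_correlation(scores, beh, sub_design))
            except ValueError as exc:
                log.warning("partial correlation %s skipped: %s", beh, exc)
    if assoc_rows:
        pd.DataFrame([
            {"name": a.name, "stat_name": a.stat_name,
             "statistic": a.statistic, "r": a.r, "p": a.p, "n": a.n,
             "covariates": "+".join(a.covariates)}
            for a in assoc_rows
        ]).to_csv(out_dir / "associations.csv", index=False)
    entry["largest_component_p_fwe"] = comp.p_fwe
    return entry


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured modality and write a run manifest.

    The manifest records the settings, package version, input digests and
    output digests; re-running the same config reproduces identical digests.
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report = validate_cohort(config.cohort_dir)
    if not report["passed"]:
        raise ValueError(
            f"cohort validation failed: {report['failures']}")
    bundles, structurals, design = read_cohort(config.cohort_dir)
    n_nodes = bundles[0].n_nodes if bundles else (
        structurals[0].n_nodes if structurals else 0)
    manifest: dict = {
        "version": __version__,
        "settings": {
            "cohort_dir": str(config.cohort_dir),
            "modalities": list(config.modalities),
            "threshold_p": config.threshold_p,
            "n_permutations": config.n_permutations,
            "seed": config.seed,
            "fd_threshold": config.fd_threshold,
            "max_flagged_fraction": config.max_flagged_fraction,
            "fisher_z": config.fisher_z,
            "add_one_p": config.add_one_p,
            "covariates": list(config.covariates),
        },
        "inputs": {
            "design.csv": file_digest(
                Path(config.cohort_dir) / "design.csv")},
        "modalities": {},
    }
    for modality in config.modalities:
        log.info("running modality %s", modality)
        try:
            entry = _run_modality(
                config, modality, bundles, structurals, design,
                out_root / modality, n_nodes)
        except Exception as exc:
            raise RuntimeError(f"stage {modality!r} failed: {exc}") from exc
        manifest["modalities"][modality] = entry
    outputs = {}
    for path in sorted(out_root.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            outputs[str(path.relative_to(out_root))] = file_digest(path)
    manifest["outputs"] = outputs
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
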