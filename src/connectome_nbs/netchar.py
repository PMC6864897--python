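"""Characterization of a detected sub-network.

Given a significant component and the six-division lobe partition of the
atlas (frontal, parietal, occipital, temporal, cingulate, subcortical),
classify each link as isocoupled (both endpoints in the same division) or
anisocoupled (endpoints in different divisions), tabulate the division-pair
spatial profile, rank the most significant links, and compute per-subject
mean sub-network connectivity scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import ceil

import numpy as np
import pandas as pd

from .datatypes import ConnectivityMatrix
from .nbs import EdgeStatMap, NBSComponent

__all__ = [
    "DIVISIONS",
    "LobePartition",
    "LinkClassification",
    "load_default_partition",
    "classify_links",
    "lobe_pair_distribution",
    "top_fraction_links",
    "subnetwork_mean_connectivity",
]

DIVISIONS = frozenset(
    {"frontal", "parietal", "occipital", "temporal", "cingulate",
     "subcortical"}
)


@dataclass
class LobePartition:
    """Ordered mapping of atlas node labels to the six supraordinate
    divisions. Node order defines the node indices used by components."""

    labels: list[str]
    divisions: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.divisions):
            raise ValueError("labels and divisions must align")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate node labels in partition")
        bad = set(self.divisions) - DIVISIONS
        if bad:
            raise ValueError(f"unknown division labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def division_of(self, node: int) -> str:
        return self.divisions[node]

    @classmethod
    def from_tsv(cls, path) -> "LobePartition":
        df = pd.read_csv(path, sep="\t")
        if not {"node_label", "division"}.issubset(df.columns):
            raise ValueError(
                "partition table needs 'node_label' and 'division' columns")
        return cls(labels=list(df["node_label"]),
                   divisions=list(df["division"]))


def load_default_partition() -> LobePartition:
    """The bundled 116-node atlas partition.

    The six divisions are standard; assignment of individual regions to them
    is partly conventional: cerebellum and vermis, the basal ganglia and
    thalamus, insula, hippocampus, parahippocampal gyrus and amygdala are
    assigned to "subcortical", fusiform and the temporal poles to
    "temporal". Supply a custom TSV via :meth:`LobePartition.from_tsv` to
    override.
    """
    ref = resources.files("connectome_nbs.data") / "aal116_lobes.tsv"
    with resources.as_file(ref) as path:
        return LobePartition.from_tsv(path)


@dataclass
class LinkClassification:
    """Per-edge iso/aniso labels and the summary percentages."""

    table: pd.DataFrame  # edge, node_i, node_j, division_i, division_j, iso
    iso_percent: float
    aniso_percent: float

    @property
    def n_edges(self) -> int:
        return len(self.table)


def classify_links(
    component: NBSComponent, partition: LobePartition
) -> LinkClassification:
    """Label every component edge iso- or anisocoupled.

    An edge is isocoupled when both endpoints fall in the same supraordinate
    division; percentages are taken over the component extent.
    """
    rows = []
    n = len(partition)
    for (i, j) in component.edges:
        if i >= n or j >= n:
            raise ValueError(
                f"node {max(i, j)} not present in the lobe partition "
                f"({n} nodes)")
        di, dj = partition.division_of(i), partition.division_of(j)
        rows.append({
            "node_i": i, "node_j": j,
            "label_i": partition.labels[i], "label_j": partition.labels[j],
            "division_i": di, "division_j": dj,
            "division_pair": "-".join(sorted((di, dj))),
            "iso": di == dj,
        })
    table = pd.DataFrame(rows)
    iso = 100.0 * table["iso"].mean() if len(table) else 0.0
    return LinkClassification(table=table, iso_percent=float(iso),
                              aniso_percent=float(100.0 - iso))


def lobe_pair_distribution(
    classification: LinkClassification,
) -> pd.DataFrame:
    """Counts and percentages of component edges per unordered division
    pair, plus the fraction of anisocoupled edges touching each division.

    Returns a table with columns ``division_pair, count, percent, iso`` and
    attrs ``aniso_touch_percent`` mapping each division to the percentage of
    anisocoupled edges with at least one endpoint there.
    """
    t = classification.table
    if t.empty:
        out = pd.DataFrame(
            columns=["division_pair", "count", "percent", "iso"])
        out.attrs["aniso_touch_percent"] = {}
        return out
    grouped = (
        t.groupby(["division_pair", "iso"], as_index=False)
        .size().rename(columns={"size": "count"})
    )
    grouped["percent"] = 100.0 * grouped["count"] / len(t)
    grouped = grouped.sort_values(
        ["count", "division_pair"], ascending=[False, True]
    ).reset_index(drop=True)[["division_pair", "count", "percent", "iso"]]
    aniso = t[~t["iso"]]
    touch = {}
    for div in sorted(DIVISIONS):
        if len(aniso):
            hit = ((aniso["division_i"] == div)
                   | (aniso["division_j"] == div)).mean()
            touch[div] = 100.0 * float(hit)
        else:
            touch[div] = 0.0
    grouped.attrs["aniso_touch_percent"] = touch
    return grouped


def top_fraction_links(
    stats_map: EdgeStatMap,
    component: NBSComponent,
    fraction: float = 0.10,
) -> list[tuple[int, int]]:
    """The most significant ``ceil(fraction * extent)`` component links.

    Edges are ranked by ascending uncorrected p, ties broken by descending F
    and then by lexicographic node pair; the count uses ceiling so a
    nonempty component always contributes at least one link.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    stat_of = {
        e: (p, f) for e, p, f in
        zip(stats_map.edges, stats_map.p_value, stats_map.f_stat)
    }
    missing = [e for e in component.edges if e not in stat_of]
    if missing:
        raise ValueError(f"component edges missing from the statistic map: "
                         f"{missing[:5]}")
    ranked = sorted(
        component.edges,
        key=lambda e: (stat_of[e][0], -stat_of[e][1], e),
    )
    return ranked[: ceil(fraction * component.extent)]


def subnetwork_mean_connectivity(
    matrices: list[ConnectivityMatrix],
    component: NBSComponent,
) -> pd.DataFrame:
    """Per-subject mean raw edge weight over the component's edge set.

    Raw connectivity values (Pearson r or streamline counts) are averaged —
    no Fisher transform — since the scores feed descriptive plots and
    follow-up association tests on the connectivity scale.
    """
    if not component.edges:
        raise ValueError("component has no edges")
    rows = np.array([e[0] for e in component.edges])
    cols = np.array([e[1] for e in component.edges])
    out = []
    for m in matrices:
        if rows.max() >= m.n_nodes:
            raise ValueError("component edges exceed matrix dimension")
        out.append({
            "subject_id": m.subject_id,
            "score": float(m.weights[rows, cols].mean()),
            "modality": m.modality,
        })
    return pd.DataFrame(out)
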