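"""Food-by-food error-correlation network.

Participants who misjudge one food tend to misjudge related foods the same
way (underestimate broccoli, underestimate cauliflower).  This module builds
the food-by-food Pearson correlation matrix of per-participant percent errors,
thresholds it into an undirected graph (edge distance = 1 - r), and extracts
clusters by average-linkage agglomerative clustering on that distance.

Correlations default to percent error eta rather than raw kcal error, so that
the shared signal is proportional bias rather than food size; pass
``measure="e"`` to switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FoodGraph",
    "error_correlation_matrix",
    "build_graph",
    "cluster_foods",
]

#: Minimum participants answering both foods for a correlation to be defined.
MIN_COMMON_PARTICIPANTS = 3


@dataclass
class FoodGraph:
    """Thresholded correlation graph plus cluster labels."""

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]  # (a, b, correlation, distance)
    clusters: dict[str, int] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, r, d in self.edges:
            g.add_edge(a, b, correlation=r, distance=d)
        for node, label in self.clusters.items():
            if node in g:
                g.nodes[node]["cluster"] = int(label)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["source", "target", "correlation", "distance"]
        )

    def write_clusters_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: int(v) for k, v in self.clusters.items()},
                       indent=2, sort_keys=True) + "\n"
        )


def error_correlation_matrix(
    metrics: pd.DataFrame, measure: str = "eta"
) -> pd.DataFrame:
    """Symmetric food-by-food Pearson correlation of per-participant errors.

    Entry (j, j') correlates the chosen error measure across the participants
    who answered both foods; pairs with fewer than
    :data:`MIN_COMMON_PARTICIPANTS` common participants are left missing (and
    later excluded from the graph).  Diagonal is 1.  Rows/columns are sorted
    by food_id, so the matrix is invariant to row ordering of the input.
    """
    if measure not in {"eta", "e"}:
        raise ValueError(f"measure must be 'eta' or 'e', got {measure!r}")
    wide = metrics.pivot_table(
        index="participant_id", columns="food_id", values=measure, aggfunc="mean"
    )
    corr = wide.corr(method="pearson", min_periods=MIN_COMMON_PARTICIPANTS)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def build_graph(matrix: pd.DataFrame, threshold: float = 0.3) -> FoodGraph:
    """Edges between food pairs with correlation >= threshold.

    Negative and missing correlations never produce edges.  Edge distance is
    ``1 - r``, so strongly correlated foods sit close together.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    foods = list(matrix.index)
    edges = []
    for i, a in enumerate(foods):
        for b in foods[i + 1 :]:
            r = matrix.loc[a, b]
            if pd.notna(r) and r >= threshold:
                edges.append((a, b, float(r), float(1.0 - r)))
    return FoodGraph(nodes=foods, edges=edges)


def cluster_foods(
    matrix: pd.DataFrame, distance_cut: float = 0.7
) -> dict[str, int]:
    """Average-linkage clustering on correlation distance ``1 - r``.

    The dendrogram is cut at ``distance_cut`` (default 0.7, i.e. foods join a
    cluster while their average correlation stays above 0.3).  Missing
    correlations are treated as zero correlation (distance 1), so a food with
    no defined correlations becomes a singleton.  Labels are renumbered 0..K-1
    in food order; singleton clusters are allowed.
    """
    foods = list(matrix.index)
    if len(foods) == 1:
        return {foods[0]: 0}
    dist = 1.0 - matrix.to_numpy(dtype=float)
    dist = np.where(np.isnan(dist), 1.0, dist)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=distance_cut, criterion="distance")
    relabel: dict[int, int] = {}
    labels = {}
    for food, lab in zip(foods, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        labels[food] = relabel[lab]
    return labels
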