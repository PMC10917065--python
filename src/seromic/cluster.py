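"""Log2/unit-SD scaling and agglomerative clustering of immune features.

Feature rows (antibody isotypes/subclasses and lectins) are floored at a
small epsilon, log2-transformed and divided by their standard deviation —
scaling without centering, so values stay positive — then clustered with
correlation distance and average linkage by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

LOG_FLOOR_EPSILON = 1.0


def log2_scale(matrix: pd.DataFrame, epsilon: float = LOG_FLOOR_EPSILON,
               center: bool = False) -> pd.DataFrame:
    """Floor at epsilon, log2-transform, and scale each row to unit SD.

    Rows that are constant after the transform cannot be scaled; they are
    dropped with a logged list.  With ``center=True`` rows are z-scored
    instead (centered before scaling).
    """
    if matrix.empty:
        raise ValueError("cannot scale an empty matrix")
    v = np.log2(matrix.clip(lower=epsilon).to_numpy(dtype=float))
    sd = v.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = list(matrix.index[constant])
        log.warning("log2_scale: dropping %d constant feature(s): %s", len(dropped), dropped)
    v = v[~constant]
    sd = sd[~constant]
    if center:
        v = v - v.mean(axis=1, keepdims=True)
    out = v / sd[:, None]
    return pd.DataFrame(out, index=matrix.index[~constant], columns=matrix.columns)


@dataclass
class ClusterResult:
    """Agglomerative clustering of the rows of a scaled matrix."""

    scaled_matrix: pd.DataFrame
    linkage_matrix: np.ndarray  # scipy linkage encoding: (n_leaves - 1) merges
    leaf_order: list[int]
    labels: list[str]
    distance_metric: str
    linkage_method: str

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def cophenetic_distance(self, a: str, b: str) -> float:
        return float(self.cophenetic_matrix().loc[a, b])

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            kids = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            return f"({kids}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hcluster(scaled: pd.DataFrame, distance: str = "correlation",
             linkage: str = "average") -> ClusterResult:
    """Hierarchically cluster matrix rows.

    Deterministic for a fixed row order; scipy breaks merge ties by the
    smallest cluster index.
    """
    if len(scaled) < 2:
        raise ValueError("hcluster needs at least two features")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    d = pdist(scaled.to_numpy(dtype=float), metric=distance)
    d = np.clip(d, 0.0, None)  # correlation distance can go -eps numerically
    z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        scaled_matrix=scaled,
        linkage_matrix=z,
        leaf_order=[int(i) for i in order],
        labels=list(scaled.index),
        distance_metric=distance,
        linkage_method=linkage,
    )
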