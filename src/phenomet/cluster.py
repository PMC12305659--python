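"""Spearman/Ward hierarchical clustering with positive-control gating.

Fingerprints are compared by Spearman correlation distance (1 - rho) and
agglomerated with Ward linkage via the generalized Lance-Williams update
(Ward is formally Euclidean; applying it to a correlation distance matrix
follows common screening practice and is deliberate here).  The tree is
cut at the lowest height at which all positive-control replicates fall in
a single cluster ("contiguous clustering" of the positive control); flat
clusters at that height are the phenotype clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "spearman_distance",
    "ward_cluster",
    "gate_clusters",
    "heatmap_export",
]


@dataclass
class Dendrogram:
    """Agglomeration tree: scipy linkage matrix plus leaf ids."""

    linkage: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.ids[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    gate_height: float


def spearman_distance(fingerprints: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between rows; values in [0, 2].

    A constant fingerprint has undefined rank correlation; its distances
    are set to 1 (logged) and its self-distance stays 0.
    """
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 fingerprints")
    if fingerprints.shape[1] < 3:
        raise ValueError("fingerprints must have length >= 3")
    X = fingerprints.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    if constant.any():
        logger.info(
            "constant fingerprints %s: Spearman undefined, distance set to 1",
            list(fingerprints.index[constant]),
        )
    rho = fingerprints.T.corr(method="spearman").to_numpy()
    rho = np.nan_to_num(rho, nan=0.0)
    D = 1.0 - rho
    D[constant, :] = 1.0
    D[:, constant] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(D, index=fingerprints.index, columns=fingerprints.index)


def ward_cluster(distances: pd.DataFrame) -> Dendrogram:
    """Ward agglomeration of a precomputed distance matrix."""
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    return Dendrogram(linkage=Z, ids=list(distances.index))


def gate_clusters(tree: Dendrogram, positive_ids: set[str]) -> ClusterAssignment:
    """Flat clusters at the lowest height uniting all positive controls.

    Scans merges in height order with union-find; the gate height is the
    height of the first merge after which every id in ``positive_ids``
    shares one cluster.  Identical replicates gate at height 0.
    """
    ids = tree.ids
    missing = sorted(set(positive_ids) - set(ids))
    if missing:
        raise ValueError(f"positive ids not in tree: {missing}")
    if len(positive_ids) < 2:
        raise ValueError("need at least 2 positive-control replicates")

    index = {name: i for i, name in enumerate(ids)}
    pos = {index[p] for p in positive_ids}
    n = len(ids)
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    gate = None
    for k, (a, b, height, _) in enumerate(tree.linkage):
        ra, rb = find(int(a)), find(int(b))
        parent[ra] = parent[rb] = n + k
        if len({find(p) for p in pos}) == 1:
            gate = float(height)
            break
    assert gate is not None  # the root unites everything
    labels_arr = hierarchy.fcluster(tree.linkage, t=gate, criterion="distance")
    labels = {name: int(lab) for name, lab in zip(ids, labels_arr)}
    if len({labels[p] for p in positive_ids}) != 1:
        raise AssertionError("positive controls not contiguous at gate height")
    return ClusterAssignment(labels=labels, gate_height=gate)


def heatmap_export(
    fingerprints: pd.DataFrame,
    assignment: ClusterAssignment,
    tree: Dendrogram,
    path: str | Path,
    positive_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Dendrogram-ordered heatmap (PNG) plus its CSV twin.

    Rows follow dendrogram leaf order; the diverging color scale is
    centered at 0; a sidebar encodes cluster membership.  Returns the
    ordered matrix that was plotted (also written as ``<path>.csv``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    missing = set(fingerprints.index) - set(assignment.labels)
    if missing:
        raise ValueError(f"assignment does not cover fingerprints: {sorted(missing)}")
    order = [i for i in tree.leaf_order if i in fingerprints.index]
    mat = fingerprints.loc[order]
    path = Path(path)
    mat.to_csv(path.with_suffix(path.suffix + ".csv"))

    vmax = float(np.abs(mat.to_numpy()).max()) or 1.0
    fig, (ax_side, ax) = plt.subplots(
        1, 2, figsize=(max(6, mat.shape[1] * 0.08), max(4, mat.shape[0] * 0.12)),
        gridspec_kw={"width_ratios": [1, 30]}, constrained_layout=True,
    )
    clusters = np.array([[assignment.labels[i]] for i in order])
    ax_side.imshow(clusters, aspect="auto", cmap="tab20", interpolation="nearest")
    ax_side.set_xticks([])
    ax_side.set_yticks(range(len(order)))
    marks = {i for i in (positive_ids or set())}
    ax_side.set_yticklabels([f"*{i}" if i in marks else i for i in order], fontsize=4)
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_yticks([])
    ax.set_xticks([])
    fig.colorbar(im, ax=ax, shrink=0.6, label="HistDiff score")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return mat
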