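"""Per-feature bioactivity scores and the bipartite sample-feature network.

Each LC-MS feature is scored from the bioactivity fingerprints (values in
[0, 1]) of the extracts containing it:

* activity score — strength: mean over containing extracts of the mean of
  the squared fingerprint values (a flag switches to the literal sum over
  extracts);
* cluster score — consistency: mean pairwise Pearson correlation between
  the containing extracts' fingerprints (singleton containment scores 1).

Features passing both thresholds (defaults 0.03 / 0.5) become circle
nodes of a bipartite graph whose square nodes are the samples containing
them; communities are found by seeded modularity (Louvain) optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureScores",
    "detect_presence",
    "activity_score",
    "cluster_score",
    "score_features",
    "build_network",
    "detect_communities",
    "export_network",
    "read_bioactivity_profiles",
    "write_bioactivity_profiles",
]


@dataclass
class FeatureScores:
    """activity/cluster scores and containment per scored feature."""

    scores: pd.DataFrame  # index = feature id; columns activity_score, cluster_score
    containing: dict[str, set[str]]


def detect_presence(table: pd.DataFrame, min_intensity: float = 0.0) -> dict[str, set[str]]:
    """Feature id -> set of samples with intensity strictly above threshold."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    mask = table.to_numpy(dtype=float) > min_intensity
    cols = np.asarray(table.columns)
    return {fid: set(cols[row]) for fid, row in zip(table.index, mask)}


def _check_profiles(profiles: pd.DataFrame) -> None:
    vals = profiles.to_numpy(dtype=float)
    if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
        raise ValueError("bioactivity fingerprints must lie in [0, 1]")


def activity_score(
    feature: str,
    profiles: pd.DataFrame,
    presence: dict[str, set[str]],
    mode: str = "mean",
) -> float:
    """Phenotype strength of a feature over its containing extracts.

    ``mode='mean'`` (default) averages the per-extract mean of squares so
    the score stays in [0, 1]; ``mode='sum'`` is the literal sum over
    extracts.
    """
    containing = sorted(presence.get(feature, set()) & set(profiles.index))
    if not containing:
        raise ValueError(f"feature {feature!r} contained in no profiled sample")
    per_extract = [float(np.mean(np.square(profiles.loc[s].to_numpy(dtype=float))))
                   for s in containing]
    if mode == "mean":
        return float(np.mean(per_extract))
    if mode == "sum":
        return float(np.sum(per_extract))
    raise ValueError(f"unknown activity mode {mode!r}")


def cluster_score(
    feature: str,
    profiles: pd.DataFrame,
    presence: dict[str, set[str]],
    singleton_score: float = 1.0,
) -> float:
    """Phenotype consistency: mean pairwise Pearson r of containing extracts."""
    containing = sorted(presence.get(feature, set()) & set(profiles.index))
    if not containing:
        raise ValueError(f"feature {feature!r} contained in no profiled sample")
    if len(containing) == 1:
        return float(singleton_score)
    X = profiles.loc[containing].to_numpy(dtype=float)
    sd = X.std(axis=1)
    rs = []
    for i in range(len(containing)):
        for j in range(i + 1, len(containing)):
            if sd[i] == 0.0 or sd[j] == 0.0:
                logger.info("constant fingerprint in pair (%s, %s); r set to 0",
                            containing[i], containing[j])
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(X[i], X[j])[0, 1]))
    return float(np.mean(rs))


def score_features(
    table: pd.DataFrame,
    profiles: pd.DataFrame,
    min_intensity: float = 0.0,
    activity_mode: str = "mean",
    singleton_score: float = 1.0,
) -> FeatureScores:
    """Score every feature of an aligned table; absent features are skipped."""
    _check_profiles(profiles)
    presence = detect_presence(table, min_intensity)
    samples = set(profiles.index)
    rows, containing = {}, {}
    for fid in table.index:
        members = presence[fid] & samples
        if not members:
            logger.info("feature %s absent from all profiled samples; skipped", fid)
            continue
        containing[fid] = members
        rows[fid] = {
            "activity_score": activity_score(fid, profiles, presence, activity_mode),
            "cluster_score": cluster_score(fid, profiles, presence, singleton_score),
        }
    scores = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=["activity_score", "cluster_score"])
    return FeatureScores(scores=scores, containing=containing)


def build_network(
    scores: FeatureScores,
    min_activity: float = 0.03,
    min_cluster: float = 0.5,
) -> nx.Graph:
    """Bipartite graph of features passing both thresholds and their samples.

    Sample nodes carry ``kind='sample'`` (squares), features
    ``kind='feature'`` (circles) with their scores; feature node ``size``
    is proportional to activity score.  Samples containing no retained
    feature are excluded.
    """
    if not -1.0 <= min_cluster <= 1.0:
        raise ValueError("min_cluster must lie in [-1, 1]")
    if min_activity < 0:
        raise ValueError("min_activity must be >= 0")
    G = nx.Graph()
    for fid, row in scores.scores.iterrows():
        if row["activity_score"] >= min_activity and row["cluster_score"] >= min_cluster:
            G.add_node(fid, kind="feature", bipartite=1,
                       activity_score=float(row["activity_score"]),
                       cluster_score=float(row["cluster_score"]),
                       size=float(row["activity_score"]))
            for s in sorted(scores.containing[fid]):
                G.add_node(s, kind="sample", bipartite=0)
                G.add_edge(s, fid)
    return G


def detect_communities(net: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Seeded modularity (Louvain) partition; labels indexed deterministically."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    communities = nx.community.louvain_communities(net, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels = {}
    for k, members in enumerate(communities):
        for node in members:
            labels[node] = k
    nx.set_node_attributes(net, labels, "community")
    return labels


def export_network(net: nx.Graph, out_dir: str | Path, stem: str = "network") -> None:
    """Write GraphML plus nodes/edges CSV twins."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net, out / f"{stem}.graphml")
    nodes = pd.DataFrame(
        [{"id": n, **attrs} for n, attrs in sorted(net.nodes(data=True))]
    )
    nodes.to_csv(out / f"{stem}_nodes.csv", index=False)
    edges = pd.DataFrame(
        [{"source": min(u, v), "target": max(u, v)} for u, v in net.edges()]
    )
    if len(edges):
        edges = edges.sort_values(["source", "target"], ignore_index=True)
    edges.to_csv(out / f"{stem}_edges.csv", index=False)


def read_bioactivity_profiles(path: str | Path) -> pd.DataFrame:
    """Bioactivity CSV: first column sample id, remaining profile values in [0,1]."""
    df = pd.read_csv(path, index_col=0)
    _check_profiles(df)
    return df


def write_bioactivity_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    _check_profiles(profiles)
    profiles.to_csv(path, index_label="sample")
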