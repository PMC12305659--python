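"""Fast correlation-based filtering with symmetrical uncertainty.

Continuous feature columns are discretized by equal-frequency binning
before any entropy is computed; symmetrical uncertainty is
2*I(X;Y) / (H(X)+H(Y)) with natural-log entropies (the normalization
cancels the base).  Selection follows the predominant-feature search:
rank features by SU against the class, discard those below the
threshold, then walk the ranking and remove every lower-ranked feature
whose SU with an already-kept feature is at least its SU with the class.
Ties in the ranking break lexicographically on feature id so the result
is reproducible regardless of input column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelection",
    "discretize",
    "symmetrical_uncertainty",
    "fcbf",
]


@dataclass
class FeatureSelection:
    """Ordered selected features and their class relevances."""

    selected: list[str]
    su_with_class: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate feature ids in selection")


def discretize(x: np.ndarray | pd.Series, n_bins: int = 5) -> np.ndarray:
    """Equal-frequency discretization into integer codes.

    Constant vectors collapse to a single code; duplicate quantile edges
    are merged, so the realized bin count may be below ``n_bins``.
    """
    x = np.asarray(x)
    if x.dtype.kind in "OUSb" or np.unique(x).size <= n_bins:
        return pd.factorize(x, sort=True)[0]
    codes = pd.qcut(x.astype(float), q=n_bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px @ py))
    return float(np.nansum(terms))


def symmetrical_uncertainty(x, y, n_bins: int = 5, discretized: bool = False) -> float:
    """SU(X, Y) = 2*I(X;Y) / (H(X)+H(Y)), in [0, 1].

    Inputs are discretized first unless ``discretized`` is set.  A constant
    vector has zero entropy; SU is then defined as 0 (logged).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not discretized:
        x = discretize(x, n_bins)
        y = discretize(y, n_bins)
    hx, hy = _entropy(x), _entropy(y)
    if hx == 0.0 or hy == 0.0:
        logger.info("constant vector in SU computation; SU defined as 0")
        return 0.0
    su = 2.0 * _mutual_information(x, y) / (hx + hy)
    # clip tiny negative rounding noise
    return float(min(1.0, max(0.0, su)))


def fcbf(
    profiles: pd.DataFrame,
    class_labels: pd.Series | np.ndarray,
    su_threshold: float = 0.0,
    n_bins: int = 5,
) -> FeatureSelection:
    """Predominant-feature selection on a samples x features matrix.

    Features with SU(feature, class) below ``su_threshold`` (or exactly 0,
    which covers constant/invariant features) are dropped; then any feature
    predominated by a higher-ranked kept feature — pairwise SU >= its class
    SU — is removed.
    """
    labels = np.asarray(class_labels)
    if labels.shape[0] != profiles.shape[0]:
        raise ValueError("class_labels length must match number of samples")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes for relevance ranking")
    if not (0.0 <= su_threshold < 1.0):
        raise ValueError("su_threshold must lie in [0, 1)")

    codes = {f: discretize(profiles[f].to_numpy(), n_bins) for f in profiles.columns}
    y = discretize(labels, n_bins)
    su_class = {
        f: symmetrical_uncertainty(codes[f], y, discretized=True)
        for f in profiles.columns
    }
    # rank: decreasing relevance, lexicographic id on ties
    ranked = sorted(
        (f for f in profiles.columns if su_class[f] >= su_threshold and su_class[f] > 0),
        key=lambda f: (-su_class[f], f),
    )
    selected: list[str] = []
    for f in ranked:
        predominated = any(
            symmetrical_uncertainty(codes[g], codes[f], discretized=True) >= su_class[f]
            for g in selected
        )
        if not predominated:
            selected.append(f)
    return FeatureSelection(selected=selected, su_with_class=su_class)
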