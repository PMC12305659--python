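"""Well-level HistDiff normalization and phenotype-strength scoring.

Converts per-well cell-by-feature tables into a single signed score per
feature by comparing the treated-well histogram against the histogram of
pooled vehicle-control cells, then summarizes each well as the Euclidean
norm of its score vector (the per-sample phenotype-strength score) and
applies the vehicle-based activity filter.

HistDiff scoring rule
---------------------
For each feature, treated and pooled-control values are binned on a common
grid spanning their joint range.  Both histograms are (optionally) smoothed
with a small Gaussian kernel and renormalized to unit mass.  The score is

    sum_b (h_trt(b) - h_ctl(b)) * s(b)

where ``s(b)`` is +1 for bins above the median of the pooled (treated +
control) values, -1 below it, and 0 for the bin containing the median.
Identical distributions score 0; a treated distribution shifted entirely
above (below) the control scores +2 (-2); |score| <= 2 always.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "WellProfile",
    "histdiff_normalize",
    "profile_plate",
    "sample_cp_score",
    "cp_scores",
    "activity_filter",
    "fingerprint_normalize",
]


@dataclass
class WellProfile:
    """Signed HistDiff score vector for one well."""

    well: str
    scores: pd.Series  # index = feature ids, values = signed HistDiff scores

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError(f"non-finite HistDiff scores in well {self.well}")


def _feature_score(
    treated: np.ndarray,
    control: np.ndarray,
    n_bins: int,
    smoothing: float,
) -> float:
    lo = min(treated.min(), control.min())
    hi = max(treated.max(), control.max())
    if lo == hi:  # constant feature in both pools
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    h_trt = np.histogram(treated, bins=edges)[0].astype(float)
    h_ctl = np.histogram(control, bins=edges)[0].astype(float)
    if smoothing > 0:
        h_trt = gaussian_filter1d(h_trt, smoothing, mode="constant")
        h_ctl = gaussian_filter1d(h_ctl, smoothing, mode="constant")
    h_trt /= h_trt.sum()
    h_ctl /= h_ctl.sum()
    med = np.median(np.concatenate([treated, control]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sign = np.sign(centers - med)
    # the bin holding the median gets sign 0 via np.sign only on exact
    # equality; force it for the containing bin so the rule is symmetric
    idx = np.searchsorted(edges, med, side="right") - 1
    if 0 <= idx < n_bins:
        sign[idx] = 0.0
    return float(np.sum((h_trt - h_ctl) * sign))


def histdiff_normalize(
    treated: pd.DataFrame,
    vehicle_pool: list[pd.DataFrame] | pd.DataFrame,
    n_bins: int = 32,
    smoothing: float = 1.0,
    well: str = "?",
) -> WellProfile:
    """Score a treated well against pooled vehicle-control cells.

    Parameters
    ----------
    treated : cells x features table for the treated well.
    vehicle_pool : one table or a list of tables of vehicle-control cells;
        pooled by row concatenation.
    n_bins : number of histogram bins on the common grid (>= 8).
    smoothing : Gaussian kernel width in bins; 0 disables smoothing.
    well : well address used in error messages and the returned profile.
    """
    if isinstance(vehicle_pool, pd.DataFrame):
        vehicle_pool = [vehicle_pool]
    if not vehicle_pool or all(len(v) == 0 for v in vehicle_pool):
        raise ValueError("vehicle pool is empty")
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    if len(treated) == 0:
        raise ValueError(f"treated cell table for well {well} is empty")
    control = pd.concat(vehicle_pool, axis=0)
    missing = set(treated.columns) ^ set(control.columns)
    if missing:
        raise ValueError(f"feature mismatch between treated and control: {sorted(missing)}")
    control = control[treated.columns]

    scores = {}
    for feat in treated.columns:
        t = treated[feat].to_numpy(dtype=float)
        c = control[feat].to_numpy(dtype=float)
        if t.min() == t.max() == c.min() == c.max():
            logger.info("constant feature %r in well %s: HistDiff score set to 0", feat, well)
            scores[feat] = 0.0
        else:
            scores[feat] = _feature_score(t, c, n_bins, smoothing)
    return WellProfile(well=well, scores=pd.Series(scores, dtype=float))


def profile_plate(
    cell_tables: dict[str, pd.DataFrame],
    vehicle_wells: list[str],
    n_bins: int = 32,
    smoothing: float = 1.0,
) -> pd.DataFrame:
    """HistDiff-normalize every non-vehicle well of a plate.

    Returns a wells x features frame of signed scores.  ``vehicle_wells``
    names the wells pooled as the control reference; they are not profiled.
    """
    pool = [cell_tables[w] for w in vehicle_wells if w in cell_tables]
    if not pool:
        raise ValueError("no vehicle wells found among the cell tables")
    rows = {}
    for well, table in cell_tables.items():
        if well in vehicle_wells:
            continue
        rows[well] = histdiff_normalize(table, pool, n_bins, smoothing, well=well).scores
    return pd.DataFrame(rows).T


@dataclass
class SampleCPScore:
    sample: str
    score: float
    concentration: float | None = None


def sample_cp_score(profile: WellProfile | pd.Series, root: bool = True) -> float:
    """Phenotype-strength score: Euclidean norm of the HistDiff profile.

    ``root=False`` returns the plain sum of squares instead.
    """
    values = profile.scores if isinstance(profile, WellProfile) else profile
    arr = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("profile contains non-finite values")
    ss = float(np.sum(arr * arr))
    return float(np.sqrt(ss)) if root else ss


def cp_scores(profiles: pd.DataFrame, root: bool = True) -> pd.Series:
    """Per-row phenotype-strength scores of a wells/samples x features frame."""
    return profiles.apply(lambda row: sample_cp_score(row, root=root), axis=1)


def activity_filter(
    scores: pd.Series,
    vehicle_scores: pd.Series,
    stat: str = "max",
    quantile: float = 0.95,
) -> list[str]:
    """Samples whose score strictly exceeds the vehicle reference statistic.

    Samples at or below the reference are removed.  ``stat`` selects the
    reference: ``max`` (default, conservative), ``median``, or ``quantile``
    (with ``quantile`` giving the level).
    """
    if len(vehicle_scores) == 0:
        raise ValueError("need at least one vehicle score")
    if stat == "max":
        ref = float(vehicle_scores.max())
    elif stat == "median":
        ref = float(vehicle_scores.median())
    elif stat == "quantile":
        ref = float(vehicle_scores.quantile(quantile))
    else:
        raise ValueError(f"unknown vehicle statistic {stat!r}")
    return [s for s, v in scores.items() if v > ref]


def fingerprint_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Map |HistDiff| values to [0, 1] per feature across samples.

    Produces the bioactivity fingerprints consumed by the networking stage.
    Constant features map to 0.
    """
    mag = profiles.abs()
    lo = mag.min(axis=0)
    span = mag.max(axis=0) - lo
    span = span.replace(0.0, np.inf)  # constant columns -> 0 after division
    return (mag - lo) / span
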