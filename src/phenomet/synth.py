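"""Synthetic plates, LC-MS feature tables and reference libraries.

Every generator takes an explicit seed and is deterministic.  Planted
ground truth (which treatments carry a phenotype, which MS features
co-occur with them) is carried alongside the data so downstream stages
can be tested for signal recovery without any external data.

Plate geometry follows the screening convention: a full 384-well plate
(rows A-P, columns 1-24) with the outer rows A/B/O/P and columns 1/24
reserved for vehicle controls, a positive-control serial dilution, and
sample treatments in 2-fold, four-step dilution series.  A compact
96-well (8 x 12) variant with the same border design is provided for
desk-scale runs.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "PlateMap",
    "GroundTruth",
    "standard_layout",
    "compact_layout",
    "default_ground_truth",
    "generate_plate",
    "generate_ms_features",
    "generate_reference_library",
    "concentration_scale",
    "write_plate_map",
    "read_plate_map",
    "write_cell_tables",
    "read_cell_tables",
    "write_ground_truth",
    "read_ground_truth",
]

POSITIVE_CONTROL = "latrunculin_B"


@dataclass(frozen=True)
class WellRole:
    """Role of one well: vehicle, positive_control or sample."""

    kind: str
    treatment_id: str = ""
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("vehicle", "positive_control", "sample"):
            raise ValueError(f"unknown well kind {self.kind!r}")
        if self.kind == "vehicle" and self.concentration is not None:
            raise ValueError("vehicle wells carry no concentration")
        if self.kind != "vehicle" and self.concentration is None:
            raise ValueError(f"{self.kind} well needs a concentration")


@dataclass
class PlateMap:
    plate_id: str
    n_rows: int
    n_cols: int
    wells: dict[str, WellRole] = field(default_factory=dict)

    @property
    def addresses(self) -> list[str]:
        rows = string.ascii_uppercase[: self.n_rows]
        return [f"{r}{c:02d}" for r in rows for c in range(1, self.n_cols + 1)]

    def validate(self) -> None:
        expected = set(self.addresses)
        for addr in self.wells:
            if addr not in expected:
                raise ValueError(f"unknown well address {addr!r}")
        missing = expected - set(self.wells)
        if missing:
            raise ValueError(f"unassigned well addresses: {sorted(missing)[:5]} ...")

    def wells_of_kind(self, kind: str) -> list[str]:
        return [a for a, r in self.wells.items() if r.kind == kind]

    def sample_id(self, addr: str) -> str:
        role = self.wells[addr]
        return f"{role.treatment_id}@{role.concentration:g}"


def _border(n_rows: int, n_cols: int, double_rows: bool = True) -> set[str]:
    rows = string.ascii_uppercase[:n_rows]
    edge = (rows[0], rows[1], rows[-2], rows[-1]) if double_rows else (rows[0], rows[-1])
    out = set()
    for r in edge:
        out |= {f"{r}{c:02d}" for c in range(1, n_cols + 1)}
    for r in rows:
        out |= {f"{r}01", f"{r}{n_cols:02d}"}
    return out


def _layout(
    plate_id: str,
    n_rows: int,
    n_cols: int,
    double_rows: bool,
    treatments: list[str],
    top_concentration: float,
    n_dilutions: int,
    positive_top: float,
    n_positive_dilutions: int,
) -> PlateMap:
    pm = PlateMap(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols)
    border = _border(n_rows, n_cols, double_rows)
    interior = [a for a in pm.addresses if a not in border]

    concs = [top_concentration / 2**i for i in range(n_dilutions)]
    pos_concs = [positive_top / 2**i for i in range(n_positive_dilutions)]
    slots = [(POSITIVE_CONTROL, c) for c in pos_concs]
    slots += [(t, c) for t in treatments for c in concs]
    if len(slots) > len(interior):
        raise ValueError(
            f"{len(slots)} treatment wells do not fit in {len(interior)} interior wells"
        )
    for addr in border:
        pm.wells[addr] = WellRole(kind="vehicle")
    for addr, (tid, conc) in zip(interior, slots):
        kind = "positive_control" if tid == POSITIVE_CONTROL else "sample"
        pm.wells[addr] = WellRole(kind=kind, treatment_id=tid, concentration=conc)
    for addr in interior[len(slots):]:
        pm.wells[addr] = WellRole(kind="vehicle")
    pm.validate()
    return pm


def standard_layout(
    treatments: list[str],
    top_concentration: float = 200.0,
    n_dilutions: int = 4,
    positive_top: float = 10.0,
    n_positive_dilutions: int = 4,
    plate_id: str = "plate1",
) -> PlateMap:
    """Full 384-well layout (rows A/B/O/P and columns 1/24 are vehicle)."""
    return _layout(plate_id, 16, 24, True, treatments, top_concentration,
                   n_dilutions, positive_top, n_positive_dilutions)


def compact_layout(
    treatments: list[str],
    top_concentration: float = 200.0,
    n_dilutions: int = 4,
    positive_top: float = 10.0,
    n_positive_dilutions: int = 4,
    plate_id: str = "plate1",
) -> PlateMap:
    """96-well (8 x 12) desk-scale layout with a single vehicle border."""
    return _layout(plate_id, 8, 12, False, treatments, top_concentration,
                   n_dilutions, positive_top, n_positive_dilutions)


@dataclass
class GroundTruth:
    """Planted effects and MS-feature linkage.

    phenotype_effects maps treatment -> per-feature effect in baseline-SD
    units; moa_class groups treatments sharing a phenotype (-1 = inactive);
    effect_scale_K is the half-saturation constant of the concentration
    response; active_ms_features maps planted feature id -> containing
    extracts, filled in by :func:`generate_ms_features`.
    """

    phenotype_effects: dict[str, np.ndarray]
    moa_class: dict[str, int]
    effect_scale_K: float = 50.0
    active_ms_features: dict[str, set[str]] = field(default_factory=dict)

    def active_treatments(self) -> list[str]:
        return [t for t, c in self.moa_class.items() if c >= 0 and t != POSITIVE_CONTROL]

    def class_groups(self) -> dict[int, list[str]]:
        groups: dict[int, list[str]] = {}
        for t in self.active_treatments():
            groups.setdefault(self.moa_class[t], []).append(t)
        return groups


def concentration_scale(concentration: float, K: float) -> float:
    """Monotone saturating dose scaling c / (c + K) in [0, 1)."""
    return concentration / (concentration + K)


def default_ground_truth(
    treatments: list[str],
    n_features: int,
    n_moa_classes: int = 3,
    n_affected: int = 20,
    effect_sd: float = 3.0,
    active_fraction: float = 0.5,
    effect_jitter: float = 0.5,
    effect_scale_K: float = 50.0,
    seed: int = 0,
) -> GroundTruth:
    """Plant class-shared sparse effect vectors on a fraction of treatments.

    Each active treatment's effect is its class centroid plus dense
    per-treatment jitter (SD ``effect_jitter``), so class members are
    strongly but not perfectly redundant.  Inactive treatments have an
    exactly zero effect.
    """
    rng = np.random.default_rng(seed)
    n_active = int(round(active_fraction * len(treatments)))
    centroids = {}
    for cls in range(n_moa_classes):
        idx = rng.choice(n_features, size=min(n_affected, n_features), replace=False)
        vec = np.zeros(n_features)
        vec[idx] = effect_sd * rng.choice([-1.0, 1.0], size=len(idx))
        centroids[cls] = vec
    effects: dict[str, np.ndarray] = {}
    moa: dict[str, int] = {}
    for i, t in enumerate(treatments):
        if i < n_active:
            cls = i % n_moa_classes
            effects[t] = centroids[cls] + effect_jitter * rng.standard_normal(n_features)
            moa[t] = cls
        else:
            effects[t] = np.zeros(n_features)
            moa[t] = -1
    # positive control: its own strong phenotype, distinct class label
    pos = np.zeros(n_features)
    idx = rng.choice(n_features, size=min(n_affected, n_features), replace=False)
    pos[idx] = 2 * effect_sd * rng.choice([-1.0, 1.0], size=len(idx))
    effects[POSITIVE_CONTROL] = pos
    moa[POSITIVE_CONTROL] = n_moa_classes
    return GroundTruth(phenotype_effects=effects, moa_class=moa,
                       effect_scale_K=effect_scale_K)


def _baseline_params(n_features: int, rng: np.random.Generator,
                     heavy_tail_fraction: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    loc = rng.uniform(1.0, 10.0, size=n_features)
    scale = rng.uniform(0.5, 2.0, size=n_features)
    heavy = rng.random(n_features) < heavy_tail_fraction
    return loc, scale, heavy


def generate_plate(
    layout: PlateMap,
    n_features: int,
    n_cells_per_well: int,
    effects: GroundTruth,
    seed: int,
    heavy_tail_fraction: float = 0.2,
    wells: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], PlateMap]:
    """Draw cell-level feature tables for every well of the layout.

    Vehicle wells sample a per-feature baseline (normal, or Student-t with
    4 df for a heavy-tail fraction of features); treated wells add
    ``effect * concentration_scale(c) * baseline_sd``.  Per-well cell
    counts are Poisson around ``n_cells_per_well``.
    """
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    if n_cells_per_well < 10:
        raise ValueError("n_cells_per_well must be >= 10")
    layout.validate()
    for t, vec in effects.phenotype_effects.items():
        if len(vec) != n_features:
            raise ValueError(f"effect vector for {t!r} has length {len(vec)} != {n_features}")
    rng = np.random.default_rng(seed)
    loc, scale, heavy = _baseline_params(n_features, rng, heavy_tail_fraction)
    feat_names = [f"f{j:04d}" for j in range(n_features)]

    targets = wells if wells is not None else sorted(layout.wells)
    tables: dict[str, pd.DataFrame] = {}
    for addr in targets:
        if addr not in layout.wells:
            raise ValueError(f"unknown well address {addr!r}")
        role = layout.wells[addr]
        n_cells = max(10, rng.poisson(n_cells_per_well))
        base = rng.standard_normal((n_cells, n_features))
        t_draw = rng.standard_t(4, size=(n_cells, n_features)) / np.sqrt(2.0)
        base[:, heavy] = t_draw[:, heavy]
        values = loc + scale * base
        if role.kind != "vehicle":
            eff = effects.phenotype_effects.get(role.treatment_id)
            if eff is None:
                raise ValueError(f"no planted effect for treatment {role.treatment_id!r}")
            shift = eff * concentration_scale(role.concentration, effects.effect_scale_K)
            values = values + scale * shift
        tables[addr] = pd.DataFrame(values, columns=feat_names)
    return tables, layout


def generate_ms_features(
    samples: list[str],
    n_features: int,
    link: GroundTruth,
    seed: int,
    n_active: int | None = None,
    false_presence_rate: float = 0.02,
    background_cardinality: int = 4,
    rt_range: tuple[float, float] = (0.0, 11.0),
    mz_range: tuple[float, float] = (50.0, 1500.0),
) -> pd.DataFrame:
    """Aligned LC-MS feature table (rows = features "rt_mz", cols = samples).

    Planted active features are present in every extract of one phenotype
    class; all features additionally appear in unrelated samples at
    ``false_presence_rate``.  Background features occupy a uniform draw of
    ``background_cardinality`` samples.  Planted memberships are recorded
    in ``link.active_ms_features``.
    """
    rng = np.random.default_rng(seed)
    groups = [g for g in link.class_groups().values() if len(g) >= 2]
    if n_active is None:
        n_active = 3 * len(groups)
    if not groups and n_active > 0:
        raise ValueError("ground truth has no phenotype class with >= 2 samples")
    if n_features < n_active:
        raise ValueError(f"n_features={n_features} < number of active features {n_active}")

    rts = np.sort(rng.uniform(*rt_range, size=n_features))
    mzs = rng.uniform(*mz_range, size=n_features)
    ids = [f"{rt:.2f}_{mz:.4f}" for rt, mz in zip(rts, mzs)]
    sample_set = set(samples)

    presence = np.zeros((n_features, len(samples)), dtype=bool)
    col = {s: i for i, s in enumerate(samples)}
    link.active_ms_features = {}
    for k in range(n_active):
        members = [s for s in groups[k % len(groups)] if s in sample_set]
        if len(members) < 2:
            raise ValueError("each active MS feature needs >= 2 containing samples")
        for s in members:
            presence[k, col[s]] = True
        link.active_ms_features[ids[k]] = set(members)
    for k in range(n_active, n_features):
        picks = rng.choice(len(samples), size=min(background_cardinality, len(samples)),
                           replace=False)
        presence[k, picks] = True
    if false_presence_rate > 0:
        presence |= rng.random(presence.shape) < false_presence_rate

    intensity = np.where(
        presence, rng.lognormal(mean=11.0, sigma=1.0, size=presence.shape), 0.0
    )
    return pd.DataFrame(intensity, index=ids, columns=samples)


def generate_reference_library(
    n_compounds: int,
    n_moa_classes: int,
    seed: int,
    n_features: int = 50,
    within_class_noise: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Known-function reference fingerprints drawn around class centroids.

    Returns (fingerprints: compounds x features, class labels).
    """
    if n_compounds < n_moa_classes:
        raise ValueError("need n_compounds >= n_moa_classes")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_moa_classes, n_features)) * 2.0
    labels = np.arange(n_compounds) % n_moa_classes
    rng.shuffle(labels)
    fp = centroids[labels] + within_class_noise * rng.standard_normal(
        (n_compounds, n_features)
    )
    ids = [f"ref{c:04d}" for c in range(n_compounds)]
    cols = [f"f{j:04d}" for j in range(n_features)]
    return (pd.DataFrame(fp, index=ids, columns=cols),
            pd.Series(labels, index=ids, name="moa_class"))


# ---------------------------------------------------------------------------
# file formats

def write_plate_map(pm: PlateMap, path: str | Path) -> None:
    rows = [
        {"well": a, "kind": r.kind, "treatment_id": r.treatment_id,
         "concentration": "" if r.concentration is None else r.concentration}
        for a, r in sorted(pm.wells.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_map(path: str | Path, plate_id: str = "plate1") -> PlateMap:
    df = pd.read_csv(path, dtype={"well": str, "kind": str, "treatment_id": str})
    wells = {}
    for _, row in df.iterrows():
        conc = row.get("concentration")
        conc = None if pd.isna(conc) or conc == "" else float(conc)
        tid = row["treatment_id"] if isinstance(row["treatment_id"], str) else ""
        wells[row["well"]] = WellRole(kind=row["kind"], treatment_id=tid,
                                      concentration=conc)
    n_rows = max(string.ascii_uppercase.index(a[0]) for a in wells) + 1
    n_cols = max(int(a[1:]) for a in wells)
    return PlateMap(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols, wells=wells)


def write_cell_tables(tables: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Single long-format CSV: column ``well`` then one column per feature."""
    frames = []
    for well, tab in sorted(tables.items()):
        t = tab.copy()
        t.insert(0, "well", well)
        frames.append(t)
    pd.concat(frames, axis=0, ignore_index=True).to_csv(path, index=False)


def read_cell_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    return {
        str(well): grp.drop(columns="well").reset_index(drop=True)
        for well, grp in df.groupby("well", sort=True)
    }


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "phenotype_effects": {t: v.tolist() for t, v in gt.phenotype_effects.items()},
        "moa_class": gt.moa_class,
        "effect_scale_K": gt.effect_scale_K,
        "active_ms_features": {k: sorted(v) for k, v in gt.active_ms_features.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        phenotype_effects={t: np.asarray(v, dtype=float)
                           for t, v in payload["phenotype_effects"].items()},
        moa_class={t: int(c) for t, c in payload["moa_class"].items()},
        effect_scale_K=float(payload["effect_scale_K"]),
        active_ms_features={k: set(v) for k, v in payload["active_ms_features"].items()},
    )
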