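"""End-to-end orchestration: synthetic data -> profiles -> selection ->
clustering -> feature scores -> bioactivity network.

Every stage is a pure function of its inputs and the config; a run
directory collects all stage outputs plus a provenance manifest (config
hash, seeds, library versions).  Re-running with the same config
reproduces all CSV outputs byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, cluster, featsel, histdiff, network, synth

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "layout": "compact",           # compact (96-well) | standard (384-well)
        "n_treatments": 12,
        "n_features": 100,
        "n_cells_per_well": 200,
        "n_moa_classes": 3,
        "n_affected": 20,
        "effect_sd": 3.0,
        "effect_jitter": 0.5,
        "active_fraction": 0.5,
        "heavy_tail_fraction": 0.2,
        "top_concentration": 200.0,
        "n_ms_features": 60,
        "n_active_ms": 12,
        "false_presence_rate": 0.005,
        "background_cardinality": 4,
    },
    "histdiff": {
        "n_bins": 32,
        "smoothing": 1.0,
        "vehicle_pool_fraction": 0.5,  # held-out remainder yields vehicle CP scores
        "cp_root": True,               # sqrt(sum of squares); False = plain sum
        "vehicle_stat": "max",         # max | median | quantile
        "vehicle_quantile": 0.95,
    },
    "featsel": {
        "su_threshold": 0.0,
        "n_bins": 5,
        "class_mode": "active",        # active | control
        "min_fingerprint_features": 24,  # pad FCBF output with top-SU features
    },
    "network": {
        "min_activity": 0.03,
        "min_cluster": 0.5,
        "min_intensity": 0.0,
        "activity_mode": "mean",       # mean | sum (literal reading)
        "singleton_score": 1.0,
    },
    "annotate": {
        "compound_db": None,           # CSV path; skipped when absent
        "tol_ppm": 10.0,
        "electron_correction": False,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def validate_config(config: dict | None) -> dict:
    """Fill defaults and range-check every threshold; raises on violations."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    net = cfg["network"]
    if not -1.0 <= net["min_cluster"] <= 1.0:
        raise ValueError(f"min_cluster={net['min_cluster']} outside [-1, 1]")
    if net["min_activity"] < 0:
        raise ValueError("min_activity must be >= 0")
    if not 0.0 <= cfg["featsel"]["su_threshold"] < 1.0:
        raise ValueError("su_threshold must lie in [0, 1)")
    if cfg["histdiff"]["n_bins"] < 8:
        raise ValueError("histdiff n_bins must be >= 8")
    if not 0.0 < cfg["histdiff"]["vehicle_pool_fraction"] < 1.0:
        raise ValueError("vehicle_pool_fraction must lie in (0, 1)")
    if cfg["synth"]["layout"] not in ("compact", "standard"):
        raise ValueError(f"unknown layout {cfg['synth']['layout']!r}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def stage_synth(cfg: dict, data: dict, out: Path) -> dict:
    s = cfg["synth"]
    seed = cfg["seed"]
    treatments = [f"T{i:02d}" for i in range(1, s["n_treatments"] + 1)]
    gt = synth.default_ground_truth(
        treatments, s["n_features"], n_moa_classes=s["n_moa_classes"],
        n_affected=s["n_affected"], effect_sd=s["effect_sd"],
        effect_jitter=s["effect_jitter"],
        active_fraction=s["active_fraction"], seed=seed,
    )
    layout_fn = synth.compact_layout if s["layout"] == "compact" else synth.standard_layout
    layout = layout_fn(treatments, top_concentration=s["top_concentration"])
    tables, _ = synth.generate_plate(
        layout, s["n_features"], s["n_cells_per_well"], gt, seed=seed + 1,
        heavy_tail_fraction=s["heavy_tail_fraction"],
    )
    ms = synth.generate_ms_features(
        treatments, s["n_ms_features"], gt, seed=seed + 2,
        n_active=s["n_active_ms"], false_presence_rate=s["false_presence_rate"],
        background_cardinality=s["background_cardinality"],
    )
    synth.write_plate_map(layout, out / "plate_map.csv")
    synth.write_cell_tables(tables, out / "cell_tables.csv")
    synth.write_ground_truth(gt, out / "ground_truth.json")
    annotate.write_feature_table(ms, out / "ms_features.csv")
    return {"layout": layout, "tables": tables, "ground_truth": gt, "ms": ms,
            "treatments": treatments}


def stage_profile(cfg: dict, data: dict, out: Path) -> dict:
    h = cfg["histdiff"]
    layout: synth.PlateMap = data["layout"]
    tables = data["tables"]
    vehicle = sorted(layout.wells_of_kind("vehicle"))
    n_pool = max(1, int(round(h["vehicle_pool_fraction"] * len(vehicle))))
    pool, held_out = vehicle[:n_pool], vehicle[n_pool:]
    profiles = histdiff.profile_plate(
        tables, pool, n_bins=h["n_bins"], smoothing=h["smoothing"]
    )
    scores = histdiff.cp_scores(profiles, root=h["cp_root"])

    meta = []
    for well in profiles.index:
        role = layout.wells[well]
        meta.append({
            "well": well, "kind": role.kind, "treatment_id": role.treatment_id,
            "concentration": role.concentration, "cp_score": scores[well],
        })
    meta = pd.DataFrame(meta).set_index("well")

    # one representative well per treatment: the strongest phenotype
    treated = meta[meta["kind"] != "vehicle"]
    rep_wells = treated.groupby("treatment_id")["cp_score"].idxmax().sort_index()
    sample_scores = pd.Series(
        {t: scores[w] for t, w in rep_wells.items()}, dtype=float
    )
    vehicle_scores = scores.loc[[w for w in held_out if w in scores.index]]
    retained = histdiff.activity_filter(
        sample_scores, vehicle_scores, stat=h["vehicle_stat"],
        quantile=h["vehicle_quantile"],
    )

    profiles.to_csv(out / "well_profiles.csv", index_label="well")
    meta.to_csv(out / "cp_scores.csv")
    pd.Series(retained, name="treatment_id").to_csv(out / "retained_samples.csv",
                                                    index=False)
    return {"profiles": profiles, "meta": meta, "rep_wells": rep_wells,
            "retained": retained, "held_out_vehicle": held_out}


def stage_select(cfg: dict, data: dict, out: Path) -> dict:
    f = cfg["featsel"]
    profiles: pd.DataFrame = data["profiles"]
    meta: pd.DataFrame = data["meta"]
    if f["class_mode"] == "active":
        labels = meta.loc[profiles.index, "treatment_id"].isin(data["retained"])
    else:  # control vs non-control
        labels = meta.loc[profiles.index, "kind"] != "vehicle"
    sel = featsel.fcbf(profiles, labels.to_numpy(), su_threshold=f["su_threshold"],
                       n_bins=f["n_bins"])
    table = pd.DataFrame({
        "feature": sel.selected,
        "su_with_class": [sel.su_with_class[x] for x in sel.selected],
    })
    table.to_csv(out / "selected_features.csv", index=False)
    return {"selection": sel}


def _usable_features(data: dict, min_features: int) -> list[str]:
    # FCBF returns a minimal non-redundant subset, which can be too sparse
    # for correlation-based fingerprints; pad with the next most relevant
    # (highest SU-with-class) features up to the configured floor
    sel = data["selection"]
    features = list(sel.selected)
    if len(features) >= min_features:
        return features
    ranked = sorted(
        (f for f in sel.su_with_class if sel.su_with_class[f] > 0),
        key=lambda f: (-sel.su_with_class[f], f),
    )
    for f in ranked:
        if len(features) >= min_features:
            break
        if f not in features:
            features.append(f)
    if len(features) < len(sel.selected) + 1 and len(features) < 3:
        logger.warning("fewer than 3 usable features; using all features")
        return list(data["profiles"].columns)
    return features


def stage_cluster(cfg: dict, data: dict, out: Path) -> dict:
    profiles: pd.DataFrame = data["profiles"]
    meta: pd.DataFrame = data["meta"]
    selected = _usable_features(data, cfg["featsel"]["min_fingerprint_features"])
    rep_wells = data["rep_wells"]

    leaves = {}
    positives = set()
    for t, well in rep_wells.items():
        if t == synth.POSITIVE_CONTROL or t in data["retained"]:
            leaves[f"{t}"] = profiles.loc[well, selected]
    for well in meta.index[meta["kind"] == "positive_control"]:
        sid = f"{synth.POSITIVE_CONTROL}@{meta.loc[well, 'concentration']:g}"
        leaves[sid] = profiles.loc[well, selected]
        positives.add(sid)
    leaves.pop(synth.POSITIVE_CONTROL, None)  # replicate wells already added
    fp = pd.DataFrame(leaves).T
    D = cluster.spearman_distance(fp)
    tree = cluster.ward_cluster(D)
    assignment = cluster.gate_clusters(tree, positives)

    (out / "dendrogram.newick").write_text(tree.to_newick())
    pd.DataFrame({
        "id": list(assignment.labels),
        "cluster": [assignment.labels[i] for i in assignment.labels],
        "is_positive_control": [i in positives for i in assignment.labels],
    }).to_csv(out / "clusters.csv", index=False)
    cluster.heatmap_export(fp, assignment, tree, out / "heatmap.png",
                           positive_ids=positives)
    return {"tree": tree, "assignment": assignment, "cluster_fingerprints": fp}


def stage_network(cfg: dict, data: dict, out: Path) -> dict:
    n = cfg["network"]
    profiles: pd.DataFrame = data["profiles"]
    selected = _usable_features(data, cfg["featsel"]["min_fingerprint_features"])
    rep_wells = data["rep_wells"]
    extracts = [t for t in data["treatments"]]
    fp = pd.DataFrame(
        {t: profiles.loc[rep_wells[t], selected] for t in extracts}
    ).T
    fingerprints = histdiff.fingerprint_normalize(fp)
    network.write_bioactivity_profiles(fingerprints, out / "bioactivity_profiles.csv")

    scores = network.score_features(
        data["ms"], fingerprints, min_intensity=n["min_intensity"],
        activity_mode=n["activity_mode"], singleton_score=n["singleton_score"],
    )
    scores.scores.to_csv(out / "feature_scores.csv", index_label="feature")
    net = network.build_network(scores, min_activity=n["min_activity"],
                                min_cluster=n["min_cluster"])
    if net.number_of_nodes() > 0:
        network.detect_communities(net, seed=cfg["seed"])
    network.export_network(net, out, stem="network")
    return {"scores": scores, "net": net}


def stage_annotate(cfg: dict, data: dict, out: Path) -> dict:
    a = cfg["annotate"]
    if not a["compound_db"]:
        return {}
    db = annotate.read_compound_db(a["compound_db"])
    ann = annotate.annotate_features(
        data["ms"], db, tol_ppm=a["tol_ppm"],
        electron_correction=a["electron_correction"],
    )
    annotate.write_annotations(ann, out / "annotations.csv")
    return {"annotations": ann}


_STAGES = [
    ("synth", stage_synth),
    ("profile", stage_profile),
    ("select", stage_select),
    ("cluster", stage_cluster),
    ("network", stage_network),
    ("annotate", stage_annotate),
]


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Run all stages into ``out_dir``; returns the run directory.

    A failing stage raises with the stage name; outputs of completed
    stages are retained.  The manifest records the config, its hash,
    seed and library versions.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data: dict = {}
    completed = []
    try:
        for name, fn in _STAGES:
            logger.info("stage %s", name)
            data.update(fn(cfg, data, out))
            completed.append(name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    finally:
        import networkx as nx
        import scipy

        manifest = {
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "seed": cfg["seed"],
            "stages_completed": completed,
            "versions": {
                "phenomet": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "networkx": nx.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
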