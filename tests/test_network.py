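import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenomet import synth
from phenomet.network import (
    FeatureScores,
    activity_score,
    build_network,
    cluster_score,
    detect_communities,
    detect_presence,
    export_network,
    read_bioactivity_profiles,
    score_features,
    write_bioactivity_profiles,
)


def _table(rows: dict, samples):
    return pd.DataFrame(rows, index=samples).T


class TestDetectPresence:
    def test_all_zero_intensities_give_empty_sets(self):
        table = pd.DataFrame(np.zeros((3, 4)),
                             index=[f"1.0_{100+i}.0" for i in range(3)],
                             columns=list("abcd"))
        assert all(s == set() for s in detect_presence(table, 0.0).values())

    def test_synthetic_zero_background_rate_equals_ground_truth(self):
        gt = synth.GroundTruth(
            phenotype_effects={s: np.ones(2) for s in ["S1", "S2", "S3"]},
            moa_class={"S1": 0, "S2": 0, "S3": 0},
        )
        table = synth.generate_ms_features(["S1", "S2", "S3", "S4"], 5, gt, seed=0,
                                           n_active=2, false_presence_rate=0.0)
        presence = detect_presence(table, 0.0)
        for fid, members in gt.active_ms_features.items():
            assert presence[fid] == members

    def test_threshold_sweep_is_monotone(self, rng):
        table = pd.DataFrame(rng.uniform(0, 10, (6, 5)),
                             index=[f"1.0_{100+i}.0" for i in range(6)],
                             columns=list("abcde"))
        sweep = [detect_presence(table, t) for t in (0.0, 2.0, 5.0, 9.0)]
        for lo, hi in zip(sweep, sweep[1:]):
            for fid in table.index:
                assert hi[fid] <= lo[fid]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_presence(pd.DataFrame(), -1.0)


class TestActivityScore:
    def test_all_zero_fingerprint_scores_zero(self):
        prof = pd.DataFrame([[0.0, 0.0, 0.0]], index=["S1"])
        assert activity_score("f", prof, {"f": {"S1"}}) == 0.0

    def test_all_ones_fingerprint_scores_one(self):
        prof = pd.DataFrame([[1.0, 1.0, 1.0]], index=["S1"])
        assert activity_score("f", prof, {"f": {"S1"}}) == 1.0

    def test_toy_matches_direct_summation_oracle(self, toy_profiles):
        presence = {"f": {"S1", "S2", "S3"}}
        got = activity_score("f", toy_profiles, presence)
        expected = np.mean([np.mean(toy_profiles.loc[s].to_numpy() ** 2)
                            for s in ("S1", "S2", "S3")])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_sum_mode_is_literal_sum(self, toy_profiles):
        presence = {"f": {"S1", "S2"}}
        got = activity_score("f", toy_profiles, presence, mode="sum")
        expected = sum(np.mean(toy_profiles.loc[s].to_numpy() ** 2)
                       for s in ("S1", "S2"))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_absent_feature_rejected(self, toy_profiles):
        with pytest.raises(ValueError):
            activity_score("f", toy_profiles, {"f": set()})

    def test_sample_order_invariance(self, toy_profiles):
        presence = {"f": {"S3", "S1", "S2"}}
        a = activity_score("f", toy_profiles, presence)
        b = activity_score("f", toy_profiles.iloc[::-1], presence)
        assert a == pytest.approx(b, rel=1e-12)


class TestClusterScore:
    def test_identical_pair_scores_one(self):
        prof = pd.DataFrame([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]], index=["a", "b"])
        assert cluster_score("f", prof, {"f": {"a", "b"}}) == pytest.approx(1.0)

    def test_opposite_deviations_score_minus_one(self):
        prof = pd.DataFrame([[0.0, 1.0, 0.5, 0.5], [1.0, 0.0, 0.5, 0.5]],
                            index=["a", "b"])
        assert cluster_score("f", prof, {"f": {"a", "b"}}) == pytest.approx(-1.0)

    def test_four_extracts_matches_pairwise_oracle(self, toy_profiles):
        presence = {"f": set(toy_profiles.index)}
        got = cluster_score("f", toy_profiles, presence)
        X = toy_profiles.to_numpy()
        pairs = [np.corrcoef(X[i], X[j])[0, 1]
                 for i, j in itertools.combinations(range(4), 2)]
        assert len(pairs) == 6
        assert got == pytest.approx(np.mean(pairs), rel=1e-12)

    def test_singleton_scores_one_by_default_and_is_configurable(self, toy_profiles):
        presence = {"f": {"S1"}}
        assert cluster_score("f", toy_profiles, presence) == 1.0
        assert cluster_score("f", toy_profiles, presence, singleton_score=0.0) == 0.0

    def test_constant_fingerprint_pair_contributes_zero(self):
        prof = pd.DataFrame([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]], index=["a", "b"])
        assert cluster_score("f", prof, {"f": {"a", "b"}}) == 0.0

    def test_sample_order_invariance(self, toy_profiles):
        presence = {"f": {"S1", "S2", "S4"}}
        a = cluster_score("f", toy_profiles, presence)
        b = cluster_score("f", toy_profiles.iloc[::-1], presence)
        assert a == pytest.approx(b, rel=1e-12)


class TestBuildNetwork:
    def _scores(self, rows):
        df = pd.DataFrame(rows, columns=["activity_score", "cluster_score"],
                          index=[f"1.0_{100+i}.0" for i in range(len(rows))])
        containing = {fid: {"sA", "sB"} for fid in df.index}
        return FeatureScores(scores=df, containing=containing)

    def test_all_below_threshold_gives_empty_network(self):
        net = build_network(self._scores([[0.01, 0.2], [0.02, 0.1]]))
        assert net.number_of_nodes() == 0

    def test_paper_thresholds(self):
        net = build_network(self._scores([[0.04, 0.6], [0.04, 0.4]]))
        features = [n for n, d in net.nodes(data=True) if d["kind"] == "feature"]
        assert features == ["1.0_100.0"]  # 0.04/0.6 kept, 0.04/0.4 dropped

    def test_matches_brute_force_threshold_filter(self, rng):
        rows = np.column_stack([rng.uniform(0, 0.1, 40), rng.uniform(-1, 1, 40)])
        fs = self._scores(list(rows))
        net = build_network(fs, 0.03, 0.5)
        got = {n for n, d in net.nodes(data=True) if d["kind"] == "feature"}
        expected = {fid for fid, r in fs.scores.iterrows()
                    if r["activity_score"] >= 0.03 and r["cluster_score"] >= 0.5}
        assert got == expected

    def test_raising_thresholds_never_adds_nodes(self, rng):
        rows = np.column_stack([rng.uniform(0, 0.1, 30), rng.uniform(-1, 1, 30)])
        fs = self._scores(list(rows))
        base = set(build_network(fs, 0.02, 0.3).nodes)
        for a, c in [(0.03, 0.3), (0.02, 0.5), (0.05, 0.7)]:
            assert set(build_network(fs, a, c).nodes) <= base

    def test_feature_node_size_tracks_activity(self):
        net = build_network(self._scores([[0.08, 0.9]]))
        assert net.nodes["1.0_100.0"]["size"] == pytest.approx(0.08)

    def test_bipartite_structure(self):
        net = build_network(self._scores([[0.08, 0.9], [0.06, 0.8]]))
        for u, v in net.edges():
            assert {net.nodes[u]["kind"], net.nodes[v]["kind"]} == {"sample", "feature"}

    def test_threshold_range_validated(self):
        with pytest.raises(ValueError):
            build_network(self._scores([[0.1, 0.9]]), min_cluster=1.1)


class TestCommunities:
    def test_two_disjoint_stars_give_two_communities(self):
        G = nx.Graph()
        for i in range(4):
            G.add_edge("hub1", f"leaf1_{i}")
            G.add_edge("hub2", f"leaf2_{i}")
        labels = detect_communities(G, seed=0)
        assert len(set(labels.values())) == 2
        assert len({labels[f"leaf1_{i}"] for i in range(4)} | {labels["hub1"]}) == 1

    def test_single_edge_one_community(self):
        G = nx.Graph([("a", "b")])
        assert len(set(detect_communities(G, seed=0).values())) == 1

    def test_planted_two_block_incidence_recovered(self):
        scores = []
        truth = {}
        G_template = []
        for block, (samples, feats) in enumerate([
            ([f"A{i}" for i in range(5)], [f"1.0_{100 + i}.0" for i in range(8)]),
            ([f"B{i}" for i in range(5)], [f"2.0_{200 + i}.0" for i in range(8)]),
        ]):
            for f in feats:
                for s in samples:
                    G_template.append((s, f))
            for n in samples + feats:
                truth[n] = block
        aris = []
        for seed in range(20):
            G = nx.Graph(G_template)
            G.add_edge("A0", "2.0_200.0")  # single cross-block edge
            labels = detect_communities(G, seed=seed)
            nodes = sorted(truth)
            aris.append(adjusted_rand_score([truth[n] for n in nodes],
                                            [labels[n] for n in nodes]))
        assert np.median(aris) >= 0.9

    def test_deterministic_given_seed(self):
        G = nx.karate_club_graph()
        assert detect_communities(G, seed=5) == detect_communities(G, seed=5)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(nx.Graph(), seed=0)


class TestExportNetwork:
    def test_round_trip_identity(self, tmp_path):
        net = nx.Graph()
        net.add_node("s1", kind="sample", bipartite=0)
        net.add_node("1.0_100.0", kind="feature", bipartite=1,
                     activity_score=0.05, cluster_score=0.75, size=0.05)
        net.add_edge("s1", "1.0_100.0")
        export_network(net, tmp_path)
        back = nx.read_graphml(tmp_path / "network.graphml")
        assert set(back.nodes) == set(net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.edges))
        assert isinstance(back.nodes["1.0_100.0"]["activity_score"], float)
        assert back.nodes["1.0_100.0"]["activity_score"] == pytest.approx(0.05)

    def test_empty_network_valid_graphml(self, tmp_path):
        export_network(nx.Graph(), tmp_path, stem="empty")
        back = nx.read_graphml(tmp_path / "empty.graphml")
        assert back.number_of_nodes() == 0
        assert (tmp_path / "empty_nodes.csv").exists()
        assert (tmp_path / "empty_edges.csv").exists()


class TestScoreFeaturesAndIO:
    def test_absent_feature_skipped(self, toy_profiles):
        table = pd.DataFrame(
            [[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]],
            index=["1.0_100.0", "2.0_200.0"],
            columns=["S1", "S2", "S3", "S4"],
        )
        fs = score_features(table, toy_profiles)
        assert list(fs.scores.index) == ["1.0_100.0"]

    def test_profile_range_validated(self):
        bad = pd.DataFrame([[1.5, 0.2, 0.1]], index=["S1"])
        table = pd.DataFrame([[1.0]], index=["1.0_100.0"], columns=["S1"])
        with pytest.raises(ValueError):
            score_features(table, bad)

    def test_bioactivity_profiles_round_trip(self, toy_profiles, tmp_path):
        write_bioactivity_profiles(toy_profiles, tmp_path / "p.csv")
        back = read_bioactivity_profiles(tmp_path / "p.csv")
        pd.testing.assert_frame_equal(back, toy_profiles, check_names=False)

    def test_planted_cluster_scores_exceed_background_on_average(self):
        # full synthetic route: planted features' consistency beats background
        treatments = [f"T{i:02d}" for i in range(1, 9)]
        gt = synth.default_ground_truth(treatments, n_features=40,
                                        n_moa_classes=2, active_fraction=0.75,
                                        seed=3)
        rng = np.random.default_rng(3)
        fp = {}
        for t in treatments:
            eff = np.abs(gt.phenotype_effects[t])
            fp[t] = np.clip(eff / 4.0 + rng.uniform(0, 0.1, 40), 0, 1)
        profiles = pd.DataFrame(fp).T
        table = synth.generate_ms_features(treatments, 30, gt, seed=3,
                                           false_presence_rate=0.0)
        fs = score_features(table, profiles)
        planted = fs.scores.index.isin(gt.active_ms_features)
        assert (fs.scores.loc[planted, "cluster_score"].mean()
                > fs.scores.loc[~planted, "cluster_score"].mean())
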