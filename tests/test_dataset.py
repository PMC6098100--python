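import warnings

import numpy as np
import pandas as pd
import pytest

from netnet import (
    FEATURES_BSI,
    FEATURES_MT,
    Network,
    NoisyOracleClassifier,
    SklearnBaseClassifier,
    build_bsi,
    build_mt,
    confusion,
    entropy_table,
    parse_topology,
    sample_pairs,
    split_dataset,
    train_base_pool,
)


@pytest.fixture
def web33():
    """Bipartite 3x3 web with 4 links."""
    rows, cols = ["r1", "r2", "r3"], ["c1", "c2", "c3"]
    adj = np.zeros((6, 6))
    for i, j in [(0, 3), (0, 4), (1, 4), (2, 5)]:
        adj[i, j] = adj[j, i] = 1
    return Network(rows + cols, adj, bipartite_partition=(rows, cols))


class TestSamplePairs:
    def test_exhaustive_bipartite_case(self, web33):
        pairs = sample_pairs(web33, n_pos=4, n_neg=5, seed=0)
        assert len(pairs) == 9
        assert pairs["A_ij"].sum() == 4
        # i always from the row guild, j from the column guild
        assert pairs["node_i"].str.startswith("r").all()
        assert pairs["node_j"].str.startswith("c").all()

    def test_requesting_too_many_links_errors(self, web33):
        with pytest.raises(ValueError, match="4"):
            sample_pairs(web33, n_pos=5, n_neg=1)

    def test_seed_determinism(self, web33):
        a = sample_pairs(web33, 2, 2, seed=5)
        b = sample_pairs(web33, 2, 2, seed=5)
        c = sample_pairs(web33, 2, 2, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_unipartite_pairs_not_mirrored(self, path3):
        pairs = sample_pairs(path3, n_pos=2, n_neg=1, seed=0)
        seen = {tuple(sorted(p)) for p in zip(pairs["node_i"], pairs["node_j"])}
        assert len(seen) == 3  # no duplicate unordered pair
        assert not (pairs["node_i"] == pairs["node_j"]).any()


class TestBuildBsi:
    def test_schema_and_row_count(self, path3):
        bsi = build_bsi([path3], n_pos_per_net=2, n_neg_per_net=1, seed=0)
        assert list(bsi.columns) == ["network_id", "node_i", "node_j"] + FEATURES_BSI + ["A_ij"]
        assert len(FEATURES_BSI) == 18
        assert len(bsi) == 3

    def test_delta_columns_recomputed_independently(self, webs):
        bsi = build_bsi(webs, seed=3)
        tables = {
            f"net{i}": entropy_table(net).set_index("node_id")
            for i, net in enumerate(webs)
        }
        for k in range(6):
            expect = np.array(
                [
                    tables[r.network_id].loc[r.node_i, f"Sh_{k}"]
                    - tables[r.network_id].loc[r.node_j, f"Sh_{k}"]
                    for r in bsi.itertuples()
                ]
            )
            assert np.allclose(bsi[f"dSh_{k}"], expect)

    def test_labels_match_adjacency(self, webs):
        bsi = build_bsi(webs, seed=3)
        net = webs[0]
        sub = bsi[bsi.network_id == "net0"]
        for r in sub.itertuples():
            assert r.A_ij == int(net.adjacency[net.index(r.node_i), net.index(r.node_j)] > 0)

    def test_default_sampling_is_balanced(self, webs):
        bsi = build_bsi(webs, seed=1)
        assert bsi["A_ij"].mean() == pytest.approx(0.5)

    def test_features_all_finite(self, bsi_small):
        assert np.isfinite(bsi_small[FEATURES_BSI].to_numpy()).all()


class TestTrainBasePool:
    def test_pool_preserves_topology_order(self, bsi_small, registry):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = train_base_pool(bsi_small, registry[:3], seed=0)
        assert [c.topology.name for c in pool] == [t.name for t in registry[:3]]

    def test_linear_topology_gets_linear_model(self, bsi_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = train_base_pool(bsi_small, [parse_topology("LNN 16:16-1:1")], seed=0)
        from sklearn.linear_model import LogisticRegression

        assert isinstance(pool[0]._est, LogisticRegression)

    def test_single_topology_smoke_on_small_table(self, bsi_small):
        small = bsi_small.head(50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = train_base_pool(small, [parse_topology("MLP 18:18-8-1:1")], seed=0)
        scores = pool[0].predict_score(small[FEATURES_BSI])
        assert scores.shape == (50,) and ((0 <= scores) & (scores <= 1)).all()


class TestBuildMt:
    def _oracle_pool(self, bsi, accuracies):
        pool = []
        topos = ["MLP 18:18-8-1:1", "LNN 16:16-1:1", "MLP 14:14-10-1:1"]
        for rank, acc in enumerate(accuracies):
            clf = NoisyOracleClassifier(parse_topology(topos[rank]), accuracy=acc, seed=rank)
            clf.fit(bsi[FEATURES_BSI], bsi["A_ij"].to_numpy())
            pool.append(clf)
        return pool

    def test_row_count_is_pairs_times_classifiers(self, bsi_small):
        pool = self._oracle_pool(bsi_small, [0.8, 0.5])
        mt = build_mt(bsi_small, pool)
        assert len(mt) == len(bsi_small) * 2
        assert len(FEATURES_MT) == 24
        assert mt.columns[-1] == "meta_label"

    def test_perfect_oracle_all_meta_labels_one(self, bsi_small):
        mt = build_mt(bsi_small, self._oracle_pool(bsi_small, [1.0]))
        assert (mt["meta_label"] == 1).all()

    def test_anti_oracle_all_meta_labels_zero(self, bsi_small):
        mt = build_mt(bsi_small, self._oracle_pool(bsi_small, [0.0]))
        assert (mt["meta_label"] == 0).all()

    def test_meta_label_mean_equals_classifier_accuracy(self, bsi_small):
        pool = self._oracle_pool(bsi_small, [0.7, 0.3])
        mt = build_mt(bsi_small, pool)
        for clf in pool:
            scores = clf.predict_score(bsi_small[FEATURES_BSI])
            stats = confusion(bsi_small["A_ij"].to_numpy(), (scores >= 0.5).astype(int))
            mean = mt.loc[mt.ann_id == clf.topology.name, "meta_label"].mean()
            assert mean * 100 == pytest.approx(stats.ac)

    def test_printed_descriptor_source(self, bsi_small, registry):
        clf = NoisyOracleClassifier(registry[7], accuracy=0.5, seed=0)
        clf.fit(bsi_small[FEATURES_BSI], bsi_small["A_ij"].to_numpy())
        mt = build_mt(bsi_small, [clf], descriptor_source="printed")
        assert (mt["annSh_1"] == 2.637).all()
        no_print = NoisyOracleClassifier(parse_topology("MLP 2:2-2-1:1"), 0.5)
        no_print.fit(bsi_small[FEATURES_BSI], bsi_small["A_ij"].to_numpy())
        with pytest.raises(ValueError, match="printed"):
            build_mt(bsi_small, [no_print], descriptor_source="printed")


class TestSplitDataset:
    def _balanced_table(self, n=100):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "A_ij": np.tile([0, 1], n // 2),
                "network_id": np.repeat(["a", "b"], n // 2),
            }
        )

    def test_75_25_split_preserves_balance(self):
        table = self._balanced_table()
        train, test = split_dataset(table, fraction=0.75, seed=0)
        assert len(train) == 75 and len(test) == 25
        assert abs(train["A_ij"].mean() - 0.5) <= 0.02
        assert abs(test["A_ij"].mean() - 0.5) <= 0.06

    def test_disjoint_and_exhaustive(self):
        table = self._balanced_table().reset_index(names="row")
        train, test = split_dataset(table, fraction=0.6, seed=1)
        assert set(train["row"]) | set(test["row"]) == set(table["row"])
        assert not (set(train["row"]) & set(test["row"]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            split_dataset(self._balanced_table(), fraction=bad)

    def test_seed_determinism(self):
        table = self._balanced_table()
        a, _ = split_dataset(table, seed=9)
        b, _ = split_dataset(table, seed=9)
        pd.testing.assert_frame_equal(a, b)
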