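import numpy as np
import pytest

from picoda import DataError, DAResult, pathway_errorbar, pathway_heatmap, pathway_pca

from conftest import make_meta, make_table


def _da(feature, p_adjust, effect=1.0):
    return DAResult(feature=feature, method="welch_t", group1="A", group2="B",
                    effect=effect, p_value=p_adjust / 2, p_adjust=p_adjust)


@pytest.fixture
def table_meta():
    t = make_table(
        [[10, 20, 5, 8], [30, 20, 45, 32], [60, 60, 50, 60]],
        sample_ids=["S1", "S2", "S3", "S4"],
    )
    m = make_meta(t.sample_ids, ["A", "A", "B", "B"])
    return t, m


class TestErrorbar:
    def test_means_match_hand_tss(self, table_meta):
        t, m = table_meta
        results = [_da("K00001", 0.01), _da("K00002", 0.02), _da("K00003", 0.9)]
        layer = pathway_errorbar(t, m, results)
        # column sums are 100 everywhere, so TSS means are simple averages
        f1a = layer.stats.query("feature == 'K00001' and group == 'A'").iloc[0]
        assert f1a["mean_rel_abund"] == pytest.approx((0.10 + 0.20) / 2)
        f2b = layer.stats.query("feature == 'K00002' and group == 'B'").iloc[0]
        assert f2b["mean_rel_abund"] == pytest.approx((0.45 + 0.32) / 2)
        sem = np.std([0.10, 0.20], ddof=1) / np.sqrt(2)
        assert f1a["sem"] == pytest.approx(sem)
        # K00003 is not significant at the default threshold
        assert set(layer.annotation["feature"]) == {"K00001", "K00002"}

    def test_order_by_p_with_feature_tiebreak(self, table_meta):
        t, m = table_meta
        results = [_da("K00002", 0.01), _da("K00001", 0.01), _da("K00003", 0.002)]
        layer = pathway_errorbar(t, m, results, threshold=0.05)
        assert list(layer.annotation["feature"]) == ["K00003", "K00001", "K00002"]

    def test_no_significant_errors(self, table_meta):
        t, m = table_meta
        with pytest.raises(DataError, match="no features significant"):
            pathway_errorbar(t, m, [_da("K00001", 0.9)])

    def test_cap_at_30_features(self):
        n = 31
        vals = np.abs(np.random.default_rng(0).lognormal(2, 0.5, size=(n, 4)))
        t = make_table(vals, sample_ids=["S1", "S2", "S3", "S4"])
        m = make_meta(t.sample_ids, ["A", "A", "B", "B"])
        results = [_da(f, 0.01) for f in t.feature_ids]
        with pytest.raises(DataError, match="30"):
            pathway_errorbar(t, m, results)
        # select rescues the plot
        layer = pathway_errorbar(t, m, results, select=set(t.feature_ids[:5]))
        assert len(layer.annotation) == 5

    def test_threshold_one_keeps_all(self, table_meta):
        t, m = table_meta
        results = [_da(f, 0.5) for f in t.feature_ids]
        layer = pathway_errorbar(t, m, results, threshold=1.0)
        assert len(layer.annotation) == 3

    def test_layer_serialization_deterministic(self, table_meta, tmp_path):
        t, m = table_meta
        results = [_da("K00001", 0.01), _da("K00002", 0.02)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        pathway_errorbar(t, m, results).to_tsv(p1)
        pathway_errorbar(t, m, results).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_figure_rendering_preserves_layer(self, table_meta, tmp_path):
        t, m = table_meta
        results = [_da("K00001", 0.01)]
        bare = pathway_errorbar(t, m, results)
        drawn = pathway_errorbar(t, m, results, figure_path=tmp_path / "f.png")
        assert bare.stats.equals(drawn.stats)
        assert (tmp_path / "f.png").exists()


class TestPca:
    def test_two_samples_rank_one(self):
        t = make_table([[1, 5], [2, 3], [7, 1]], sample_ids=["S1", "S2"])
        m = make_meta(t.sample_ids, ["A", "B"])
        layer = pathway_pca(t, m, k=1)
        assert layer.variance_fraction[0] == pytest.approx(1.0)

    def test_sample_duplication_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(2, 0.7, size=(8, 5))
        t = make_table(vals, sample_ids=[f"S{i}" for i in range(5)])
        m = make_meta(t.sample_ids, ["A", "A", "A", "B", "B"])
        base = pathway_pca(t, m, k=2)
        t2 = make_table(np.hstack([vals, vals]),
                        sample_ids=[f"S{i}" for i in range(10)])
        m2 = make_meta(t2.sample_ids, ["A", "A", "A", "B", "B"] * 2)
        dup = pathway_pca(t2, m2, k=2)
        assert np.allclose(base.variance_fraction, dup.variance_fraction, atol=1e-9)

    def test_variance_fractions_sorted_and_bounded(self, spiked_sims):
        sim = spiked_sims[0]
        layer = pathway_pca(sim.table, sim.meta, k=4)
        vf = layer.variance_fraction
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1 + 1e-9
        assert set(layer.scores["group"]) == {"G1", "G2"}

    def test_k_beyond_rank_errors(self):
        t = make_table([[1, 5], [2, 3]], sample_ids=["S1", "S2"])
        m = make_meta(t.sample_ids, ["A", "B"])
        with pytest.raises(DataError, match="rank"):
            pathway_pca(t, m, k=2)

    def test_figure_written(self, table_meta, tmp_path):
        t, m = table_meta
        pathway_pca(t, m, k=2, figure_path=tmp_path / "pca.svg")
        assert (tmp_path / "pca.svg").stat().st_size > 0


class TestHeatmap:
    def test_row_zscore_hand_value(self):
        t = make_table([[1, 2, 3]], sample_ids=["S1", "S2", "S3"])
        m = make_meta(t.sample_ids, ["A", "A", "B"])
        layer = pathway_heatmap(t, m)
        assert np.allclose(layer.zscores.to_numpy()[0], [-1, 0, 1])

    def test_constant_row_zeroed_with_warning(self, caplog):
        t = make_table([[5, 5, 5], [1, 2, 3]], sample_ids=["S1", "S2", "S3"])
        m = make_meta(t.sample_ids, ["A", "A", "B"])
        with caplog.at_level("WARNING", logger="picoda"):
            layer = pathway_heatmap(t, m)
        assert np.allclose(layer.zscores.loc["K00001"], 0.0)
        assert "constant row" in caplog.text

    def test_columns_grouped_then_sorted(self):
        t = make_table([[1, 2, 3, 4]], sample_ids=["S4", "S1", "S3", "S2"])
        m = make_meta(t.sample_ids, ["B", "A", "A", "B"])
        layer = pathway_heatmap(t, m)
        assert list(layer.zscores.columns) == ["S1", "S3", "S2", "S4"]
        assert list(layer.groups) == ["A", "A", "B", "B"]

    def test_feature_selection(self):
        t = make_table([[1, 2, 3], [4, 6, 5]], sample_ids=["S1", "S2", "S3"])
        m = make_meta(t.sample_ids, ["A", "A", "B"])
        layer = pathway_heatmap(t, m, features={"K00002"})
        assert list(layer.zscores.index) == ["K00002"]
        with pytest.raises(DataError, match="empty feature selection"):
            pathway_heatmap(t, m, features=set())
        with pytest.raises(DataError, match="absent"):
            pathway_heatmap(t, m, features={"K09999"})
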