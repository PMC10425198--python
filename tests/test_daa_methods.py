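"""Behavioral tests of the registered DA methods and the dispatcher."""

import numpy as np
import pytest
from scipy import stats as sps

from picoda import DataError, METHODS, pathway_daa, results_to_frame
from picoda.daa import (
    _fit_variance_prior,
    _kde_mode,
    aldex2_like,
    css_like,
    lefse_like,
    linda_like,
    maaslin2_like,
)
from picoda.synthetic import SimulationConfig, simulate_profile

from conftest import make_meta, make_table


def _signal_table(n1=6, n2=6, seed=0):
    """Three features; the first is ~8x higher in group B."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(5, 0.2, size=(3, n1 + n2))
    base[0, n1:] *= 8.0
    t = make_table(np.rint(base), sample_ids=[f"S{i}" for i in range(n1 + n2)])
    m = make_meta(t.sample_ids, ["A"] * n1 + ["B"] * n2)
    return t, m


class TestDispatcher:
    def test_one_record_per_feature(self, tiny_table, tiny_meta):
        res = pathway_daa(tiny_table, tiny_meta, method="welch_t")
        assert [r.feature for r in res] == tiny_table.feature_ids
        assert all(r.group1 == "A" and r.group2 == "B" for r in res)

    def test_three_groups_reference_contrasts(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.integers(1, 100, size=(4, 12)).astype(float),
                       sample_ids=[f"S{i}" for i in range(12)])
        m = make_meta(t.sample_ids, ["A"] * 4 + ["B"] * 4 + ["C"] * 4, reference="A")
        res = pathway_daa(t, m, method="welch_t")
        contrasts = {(r.group1, r.group2) for r in res}
        assert contrasts == {("A", "B"), ("A", "C")}
        assert len(res) == 8  # 4 features x 2 contrasts, pooled adjustment
        raw = [r.p_value for r in res]
        from picoda import adjust_pvalues
        assert np.allclose([r.p_adjust for r in res], adjust_pvalues(raw, "BH"))

    @pytest.mark.parametrize("name", ["ancombc", "ancom", "nonsense"])
    def test_unknown_method(self, tiny_table, tiny_meta, name):
        with pytest.raises(DataError, match="unknown method"):
            pathway_daa(tiny_table, tiny_meta, method=name)

    @pytest.mark.parametrize("name", ["deseq2_like", "edger_like"])
    def test_reserved_method(self, tiny_table, tiny_meta, name):
        with pytest.raises(DataError, match="reserved"):
            pathway_daa(tiny_table, tiny_meta, method=name)

    def test_small_group_rejected(self, tiny_table):
        m = make_meta(tiny_table.sample_ids, ["A", "A", "A", "B"])
        with pytest.raises(DataError, match=">= 2"):
            pathway_daa(tiny_table, m, method="welch_t")

    def test_zero_total_features_dropped(self, caplog):
        t = make_table([[1, 2, 3, 4], [0, 0, 0, 0]],
                       sample_ids=["S1", "S2", "S3", "S4"])
        m = make_meta(t.sample_ids, ["A", "A", "B", "B"])
        with caplog.at_level("WARNING", logger="picoda"):
            res = pathway_daa(t, m, method="welch_t")
        assert [r.feature for r in res] == ["K00001"]
        assert "zero-total" in caplog.text

    @pytest.mark.parametrize("method", sorted(METHODS))
    def test_every_method_detects_strong_signal(self, method):
        t, m = _signal_table(seed=3)
        res = pathway_daa(t, m, method=method, seed=1,
                          params={"M": 32} if method == "aldex2_like" else None)
        by_feature = {r.feature: r for r in res}
        assert by_feature["K00001"].p_value == min(r.p_value for r in res)
        assert by_feature["K00001"].effect > 0


class TestAldex2:
    def test_seed_determinism(self):
        t, m = _signal_table()
        a = aldex2_like(t, m, M=16, seed=7)
        b = aldex2_like(t, m, M=16, seed=7)
        assert results_to_frame(a).equals(results_to_frame(b))
        c = aldex2_like(t, m, M=16, seed=8)
        assert not results_to_frame(a).equals(results_to_frame(c))

    def test_rejects_tiny_m(self):
        t, m = _signal_table()
        with pytest.raises(DataError, match="M >= 2"):
            aldex2_like(t, m, M=1, seed=1)

    def test_multigroup_omnibus_branch(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(10, 100, size=(3, 9)).astype(float),
                       sample_ids=[f"S{i}" for i in range(9)])
        m = make_meta(t.sample_ids, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        res = pathway_daa(t, m, method="aldex2_like", params={"M": 8})
        assert all(r.group2 == "all" for r in res)

    def test_wilcoxon_variant_runs(self):
        t, m = _signal_table()
        res = aldex2_like(t, m, M=16, seed=1, test="wilcoxon")
        assert min(r.p_value for r in res) < 0.2


class TestLinda:
    def test_mode_oracle_on_four_slopes(self):
        # the tight cluster {0.98, 1.00, 1.02} defines the mode; the
        # outlying slope 5.00 must not drag it away
        slopes = np.array([1.00, 1.02, 0.98, 5.00])
        mode = _kde_mode(slopes)
        assert abs(mode - 1.0) < 0.05
        corrected = slopes - mode
        assert np.allclose(corrected, [0.0, 0.02, -0.02, 4.0], atol=0.05)

    def test_group_flip_negates_effects(self):
        t, m = _signal_table()
        fwd = linda_like(t, m)
        flipped = make_meta(t.sample_ids, ["B"] * 6 + ["A"] * 6)
        rev = linda_like(t, flipped)
        assert np.allclose([r.effect for r in fwd],
                           [-r.effect for r in rev], atol=1e-9)

    def test_compositional_offset_absorbed(self):
        # null features plus one dominant feature spiked in group 2: the
        # mode correction should re-center the null slopes near zero
        rng = np.random.default_rng(12)
        n = 50
        base = rng.lognormal(3, 0.5, size=(80, 2 * n))
        base[0] *= 50  # dominant feature
        base[0, n:] *= 4.0  # spiked only in group 2
        t = make_table(np.rint(base), sample_ids=[f"S{i}" for i in range(2 * n)])
        m = make_meta(t.sample_ids, ["A"] * n + ["B"] * n)
        res = linda_like(t, m)
        null_effects = np.array([r.effect for r in res[1:]])
        assert abs(null_effects.mean()) < 0.05 / np.log(2)


class TestLimma:
    def test_equal_variances_give_infinite_prior_df(self):
        # no excess spread in the log variances -> complete shrinkage
        d0, s0 = _fit_variance_prior(np.full(50, 1.7), d=10)
        assert np.isinf(d0)
        assert s0 == pytest.approx(1.7, rel=0.25)

    def test_variance_prior_recovery(self):
        # variances drawn from a scaled chi-square around s0^2 = 2, d0 = 8
        rng = np.random.default_rng(42)
        d, d0, s0_sq = 10, 8.0, 2.0
        sigma2 = s0_sq * d0 / rng.chisquare(d0, size=4000)
        s2 = sigma2 * rng.chisquare(d, size=4000) / d
        d0_hat, s0_hat = _fit_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.25)
        assert s0_hat == pytest.approx(s0_sq, rel=0.1)


class TestCss:
    def test_scaling_factor_hand_example(self):
        # sample [1,2,3,100]: median of nonzero values 2.5 -> s = 1 + 2 = 3
        col = np.array([1.0, 2.0, 3.0, 100.0])
        nz = col[col > 0]
        q = np.quantile(nz, 0.5)
        assert q == pytest.approx(2.5)
        assert col[col <= q].sum() == pytest.approx(3.0)

    def test_identical_columns_null(self):
        t = make_table(np.tile([[3.0], [5.0], [9.0]], (1, 6)),
                       sample_ids=[f"S{i}" for i in range(6)])
        m = make_meta(t.sample_ids, ["A"] * 3 + ["B"] * 3)
        res = css_like(t, m)
        assert all(r.p_value == 1 and r.effect == 0 for r in res)

    def test_depth_invariance(self):
        t, m = _signal_table()
        base = css_like(t, m)
        vals = t.values.copy()
        vals[:, 0] *= 2  # double one sample's counts
        doubled = css_like(make_table(vals, sample_ids=t.sample_ids), m)
        assert np.allclose([r.effect for r in base],
                           [r.effect for r in doubled], atol=1e-9)
        assert np.allclose([r.p_value for r in base],
                           [r.p_value for r in doubled], atol=1e-9)


class TestMaaslin2:
    def test_orthogonal_covariate_no_change(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.lognormal(4, 0.3, size=(5, 8)),
                       sample_ids=[f"S{i}" for i in range(8)])
        groups = ["A"] * 4 + ["B"] * 4
        m_plain = make_meta(t.sample_ids, groups)
        import pandas as pd

        cov = pd.DataFrame(
            {"age": [-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0]},
            index=t.sample_ids,
        )  # orthogonal to the group indicator (balanced within groups)
        m_cov = make_meta(t.sample_ids, groups)
        m_cov.covariates = cov
        plain = maaslin2_like(t, m_plain)
        with_cov = maaslin2_like(t, m_cov)
        assert np.allclose([r.effect for r in plain],
                           [r.effect for r in with_cov], atol=1e-9)

    def test_identical_groups_zero_effect(self):
        block = np.array([[4.0, 7.0], [1.0, 2.0], [9.0, 3.0]])
        t = make_table(np.hstack([block, block]),
                       sample_ids=["S1", "S2", "S3", "S4"])
        m = make_meta(t.sample_ids, ["A", "A", "B", "B"])
        res = maaslin2_like(t, m)
        assert np.allclose([r.effect for r in res], 0.0, atol=1e-12)

    def test_collinear_covariates_named(self):
        import pandas as pd

        t, m = _signal_table(4, 4)
        m.covariates = pd.DataFrame(
            {"dup_group": [0.0] * 4 + [1.0] * 4}, index=t.sample_ids
        )
        with pytest.raises(DataError, match="dup_group"):
            maaslin2_like(t, m)


class TestLefse:
    def _cpm_table(self, g1_val, g2_val, n=4):
        # one focal feature plus a filler keeping every column total at 1e6
        top = [g1_val] * n + [g2_val] * n
        filler = [1e6 - v for v in top]
        return (
            make_table([top, filler], sample_ids=[f"S{i}" for i in range(2 * n)],
                       feature_ids=["K00001", "K00002"]),
            make_meta([f"S{i}" for i in range(2 * n)], ["A"] * n + ["B"] * n),
        )

    def test_equal_means_zero_score(self):
        t, m = self._cpm_table(50.0, 50.0)
        res = lefse_like(t, m)
        assert res[0].effect == 0.0

    def test_zero_vs_99_cpm_scores_two(self):
        t, m = self._cpm_table(0.0, 99.0)
        res = lefse_like(t, m)
        assert res[0].p_value < 0.05
        assert res[0].effect == pytest.approx(2.0, abs=1e-9)

    def test_group_swap_negates_score(self):
        t, m = self._cpm_table(0.0, 99.0)
        swapped = make_meta(t.sample_ids, ["B"] * 4 + ["A"] * 4)
        res = lefse_like(t, m)
        rev = lefse_like(t, swapped)
        assert res[0].effect == pytest.approx(-rev[0].effect)

    def test_multigroup_unsupported(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.integers(1, 50, size=(2, 9)).astype(float),
                       sample_ids=[f"S{i}" for i in range(9)])
        m = make_meta(t.sample_ids, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        with pytest.raises(DataError, match="exactly 2 groups"):
            lefse_like(t, m)


class TestSimulatedRecovery:
    def test_linda_recovers_spiked_effect(self, spiked_sims):
        sim = spiked_sims[0]
        res = pathway_daa(sim.table, sim.meta, method="linda_like")
        eff = {r.feature: r.effect for r in res}
        spiked = [eff[f] for f in sim.spiked_features if f in eff]
        assert abs(np.mean(spiked) - sim.config.effect_log2) < 0.4
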