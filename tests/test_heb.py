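import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import shwheb as sw
from shwheb.heb import HebConfig, _lrt_from_sums

from oracles import grid_lrt_oracle


class TestComputeHeb:
    @pytest.mark.parametrize("a,b,d,expected", [
        (10, 10, 10, 0.0),
        (10, 10, 20, 1.0),
        (4, 16, 5, -1.0),  # log2(5 / mean(4,16)) = log2(0.5)
    ])
    def test_known_values(self, a, b, d, expected):
        assert sw.compute_heb(a, b, d) == pytest.approx(expected)

    def test_one_sided_zero_is_capped(self):
        assert sw.compute_heb(10, 10, 0) == -10.0
        assert sw.compute_heb(0, 0, 5) == 10.0
        assert sw.compute_heb(0, 0, 5, cap=4.0) == 4.0

    def test_both_sides_zero_is_missing(self):
        assert math.isnan(sw.compute_heb(0, 0, 0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sw.compute_heb(-1, 2, 3)

    @given(m=st.floats(0.01, 1e4), d=st.floats(0.01, 1e4))
    def test_antisymmetry_under_side_swap(self, m, d):
        assert sw.compute_heb(m, m, d) == pytest.approx(-sw.compute_heb(d, d, m))


class TestContexts:
    def test_insilico_pairs_replicates(self, small_meta):
        ctx = sw.build_insilico_context("PI377655", "AS2386", "shoot", small_meta)
        assert len(ctx.replicate_pairing) == 3
        assert ctx.background == "parental_insilico"
        assert ctx.ab_samples[0].startswith("PI377655")
        assert ctx.d_samples[0].startswith("AS2386")

    def test_unpaired_extra_replicates_dropped(self, small_meta, caplog):
        meta = small_meta.drop("AS2386_shoot_r3")
        with caplog.at_level("WARNING"):
            ctx = sw.build_insilico_context("PI377655", "AS2386", "shoot", meta)
        assert len(ctx.replicate_pairing) == 2
        assert "unequal replicate" in caplog.text

    def test_missing_tissue_is_an_error(self, small_meta):
        with pytest.raises(ValueError, match="root"):
            sw.build_insilico_context("PI377655", "AS2386", "root", small_meta)

    def test_shw_context_uses_same_libraries_for_both_sides(self, small_meta):
        ctx = sw.build_shw_context("C66", "shoot", small_meta)
        assert ctx.ab_samples == ctx.d_samples


class TestLrtTriad:
    def test_symmetric_instance_has_zero_statistic(self):
        r = sw.lrt_triad([100, 100], [100, 100], [100, 100], (1000, 1000, 1000),
                         [1e6, 1e6], [1e6, 1e6])
        assert r.lrt_stat == pytest.approx(0.0, abs=1e-9)
        assert r.p == pytest.approx(1.0)

    def test_worked_instance_matches_grid_oracle(self):
        r = sw.lrt_triad([100], [100], [200], (1000, 1000, 1000), [1e6], [1e6])
        oracle = grid_lrt_oracle(100, 100, 200, 1000, 1000, 1000, 1e6, 1e6)
        assert r.lrt_stat == pytest.approx(oracle, abs=1e-3)

    def test_doubling_counts_and_depth_preserves_rates_and_grows_stat(self):
        r1 = sw.lrt_triad([80], [120], [300], (1000, 1500, 900), [2e6], [2e6])
        r2 = sw.lrt_triad([160], [240], [600], (1000, 1500, 900), [4e6], [4e6])
        assert r2.fit.e_A == pytest.approx(r1.fit.e_A)
        assert r2.fit.e_B == pytest.approx(r1.fit.e_B)
        assert r2.fit.e_D == pytest.approx(r1.fit.e_D)
        assert r2.lrt_stat > r1.lrt_stat
        oracle = grid_lrt_oracle(160, 240, 600, 1000, 1500, 900, 4e6, 4e6)
        assert r2.lrt_stat == pytest.approx(oracle, abs=1e-3)

    def test_all_zero_counts_returns_not_expressed_sentinel(self):
        assert sw.lrt_triad([0], [0], [0], (1000, 1000, 1000), [1e6], [1e6]) is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sw.lrt_triad([-1], [0], [0], (1000, 1000, 1000), [1e6], [1e6])
        with pytest.raises(ValueError):
            sw.lrt_triad([1.5], [0], [0], (1000, 1000, 1000), [1e6], [1e6])

    def test_alt_loglik_dominates_null(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.poisson(30, size=3)
            r = sw.lrt_triad([x[0]], [x[1]], [x[2]], (900, 1100, 1300), [1e6], [2e6])
            assert r.fit.loglik_alt >= r.fit.loglik_null - 1e-9


class TestBhAdjust:
    def test_hand_evaluated_stepup(self):
        np.testing.assert_allclose(sw.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert sw.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(sw.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sw.bh_adjust([0.5, 1.5])


class TestClassify:
    def test_definition_cases(self):
        states = sw.classify_triads(
            heb=[np.nan, 2.3, 2.3, -1.0],
            q=[np.nan, 0.001, 0.20, 0.01],
            mean_a=[0.0, 5, 5, 5], mean_b=[0.0, 5, 5, 5], mean_d=[0.0, 20, 20, 2],
        )
        assert list(states) == ["NE", "D", "UN", "AB"]

    def test_zero_heb_with_significant_q_is_unbiased(self):
        states = sw.classify_triads([0.0], [0.001], [5], [5], [5])
        assert list(states) == ["UN"]


def _two_triads():
    return pd.DataFrame({
        "triad_id": ["T1", "T2"],
        "gene_A": ["a1", "a2"], "gene_B": ["b1", "b2"], "gene_D": ["d1", "d2"],
        "len_A": [1000, 800], "len_B": [1000, 800], "len_D": [1000, 800],
    })


def _design_counts(vals, meta):
    genes = ["a1", "a2", "b1", "b2", "d1", "d2"]
    df = pd.DataFrame(vals, index=genes, columns=meta.index)
    lengths = pd.Series({g: 1000 if g[1] == "1" else 800 for g in genes}, dtype=float)
    return sw.CountMatrix(df, meta, lengths)


class TestRunHeb:
    def test_one_row_per_triad_and_context(self, small_meta):
        rng = np.random.default_rng(0)
        cm = _design_counts(rng.poisson(50, size=(6, 9)), small_meta)
        ctxs = [sw.build_shw_context("C66", "shoot", small_meta),
                sw.build_insilico_context("PI377655", "AS2386", "shoot", small_meta)]
        res = sw.run_heb(cm, _two_triads(), ctxs)
        assert len(res) == 4
        assert set(res["context_id"]) == {c.context_id for c in ctxs}

    def test_all_low_expression_yields_ne_without_statistics(self, small_meta):
        cm = _design_counts(np.zeros((6, 9), dtype=int), small_meta)
        res = sw.run_heb(cm, _two_triads(), [sw.build_shw_context("C66", "shoot", small_meta)])
        assert (res["state"] == "NE").all()
        assert res[["heb", "p", "q"]].isna().all().all()

    def test_deterministic_for_identical_inputs(self, small_meta):
        rng = np.random.default_rng(1)
        cm = _design_counts(rng.poisson(40, size=(6, 9)), small_meta)
        ctxs = [sw.build_shw_context("C66", "shoot", small_meta)]
        res1 = sw.run_heb(cm, _two_triads(), ctxs)
        res2 = sw.run_heb(cm, _two_triads(), ctxs)
        pd.testing.assert_frame_equal(res1, res2)

    def test_states_partition_the_triads_per_context(self, tiny_sim):
        ctxs = sw.design_contexts(tiny_sim.counts.meta, sw.SHW_PARENTS)
        res = sw.run_heb(tiny_sim.counts, tiny_sim.triads, ctxs)
        for _, grp in res.groupby("context_id"):
            counts = sw.count_states(grp)
            assert counts.total == len(tiny_sim.triads)

    def test_fdr_family_excludes_ne(self, tiny_sim):
        ctx = sw.build_shw_context("C66", "shoot", tiny_sim.counts.meta)
        res = sw.run_heb(tiny_sim.counts, tiny_sim.triads, [ctx])
        ne = res["state"] == "NE"
        assert res.loc[ne, "q"].isna().all()
        assert res.loc[~ne, "q"].notna().all()
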