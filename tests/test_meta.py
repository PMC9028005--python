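"""Effect sizes, heterogeneity, random-effects combination, DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metareverse.meta import (ExpressionMetaAnalysis, bh_adjust, cochran_q,
                              hedges_g, random_effects_combine)
from tests.conftest import make_dataset

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestHedgesG:
    def test_equal_groups_give_zero(self):
        g, var_g = hedges_g([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert g == pytest.approx(0.0)
        assert var_g == pytest.approx(6 / 9)  # (n1+n2)/(n1 n2)

    def test_worked_example(self):
        # d = 3, J = 1 - 3/15 = 0.8, g = 2.4,
        # var = 6/9 + 2.4^2 / 12 = 1.146667
        g, var_g = hedges_g([1, 2, 3], [4, 5, 6])
        assert g == pytest.approx(2.4, abs=1e-12)
        assert var_g == pytest.approx(6 / 9 + 5.76 / 12, abs=1e-12)

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError, match="pooled variance"):
            hedges_g([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    @given(st.lists(finite_floats, min_size=3, max_size=8),
           st.lists(finite_floats, min_size=3, max_size=8))
    @settings(max_examples=50, derandomize=True)
    def test_swapping_groups_flips_sign(self, a, b):
        if np.var(a) + np.var(b) == 0:
            return
        g1, v1 = hedges_g(a, b)
        g2, v2 = hedges_g(b, a)
        assert g1 == pytest.approx(-g2, rel=1e-12)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestCochranQ:
    def test_equal_effects(self):
        Q, df, p = cochran_q([(1.0, 0.5), (1.0, 0.2), (1.0, 1.0)])
        assert Q == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        Q, df, p = cochran_q([(0.0, 1.0), (2.0, 1.0)])
        assert Q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(0.15730, abs=1e-5)

    def test_single_study_errors(self):
        with pytest.raises(ValueError):
            cochran_q([(1.0, 0.5)])

    @given(st.lists(st.tuples(finite_floats, st.floats(0.01, 5)),
                    min_size=2, max_size=6),
           st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_common_rescaling(self, effects, c):
        Q1, *_ = cochran_q(effects)
        Q2, *_ = cochran_q([(g * c, v * c * c) for g, v in effects])
        assert Q1 == pytest.approx(Q2, rel=1e-9, abs=1e-9)


class TestRandomEffects:
    def test_single_study_pass_through(self):
        res = random_effects_combine([(0.7, 0.09)])
        assert res["combined_es"] == pytest.approx(0.7)
        assert res["se"] == pytest.approx(0.3)

    def test_homogeneous_equals_fixed_effect(self):
        effects = [(1.0, 0.5), (1.0, 0.25)]
        res = random_effects_combine(effects)
        assert res["tau2"] == 0.0
        w = [2.0, 4.0]
        fe = sum(wi * g for wi, (g, _) in zip(w, effects)) / sum(w)
        assert res["combined_es"] == pytest.approx(fe)

    def test_worked_example(self):
        # Q=2, df=1, Sum w=2, Sum w^2/Sum w=1 -> tau2=1; w*=0.5 each
        res = random_effects_combine([(0.0, 1.0), (2.0, 1.0)])
        assert res["tau2"] == pytest.approx(1.0)
        assert res["combined_es"] == pytest.approx(1.0)
        assert res["se"] == pytest.approx(1.0)
        assert res["z"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(0.31731, abs=1e-5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            random_effects_combine([])

    @given(st.lists(st.tuples(finite_floats, st.floats(0.01, 5)),
                    min_size=2, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_combined_within_study_range(self, effects):
        res = random_effects_combine(effects)
        gs = [g for g, _ in effects]
        assert min(gs) - 1e-9 <= res["combined_es"] <= max(gs) + 1e-9
        assert res["tau2"] >= 0


class TestBhAdjust:
    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_at_least_raw_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))


class TestModel:
    def test_intersection_universe_and_exclusions(self):
        d1 = make_dataset("a", n_genes=8, seed=1)
        d2 = make_dataset("b", n_genes=6, seed=2)
        # make one shared gene constant in d2 -> undefined effect, excluded
        d2.matrix.loc["g0"] = 5.0
        res = ExpressionMetaAnalysis([d1, d2]).fit()
        assert set(res.table.index) == {f"g{i}" for i in range(1, 6)}
        assert res.n_excluded == 1

    def test_three_degs_from_constructed_pvalues(self):
        # step-up by hand: sorted p (.001,.002,.003,.2,...) -> 3 rejections
        p = np.array([0.001, 0.002, 0.003] + [0.2 + 0.05 * i for i in range(7)])
        m = len(p)
        passing = 0
        for i, pi in enumerate(np.sort(p), start=1):
            if pi <= 0.05 * i / m:
                passing = i
        assert passing == 3
        adj = bh_adjust(p)
        assert int((adj < 0.05).sum()) == 3

    def test_alpha_one_calls_every_gene(self, small_cohorts):
        datasets, _ = small_cohorts
        res = ExpressionMetaAnalysis(datasets).fit()
        assert len(res.call_degs(alpha=1.0)) == len(res.table)

    def test_direction_matches_sign(self, small_cohorts):
        datasets, _ = small_cohorts
        res = ExpressionMetaAnalysis(datasets).fit()
        t = res.table
        assert ((t["combined_es"] >= 0) == (t["direction"] == "up")).all()
        assert (t["tau2"] >= 0).all()
        assert t["fdr"].between(0, 1).all()

    def test_top_table_schema_and_ranking(self, small_cohorts):
        datasets, _ = small_cohorts
        res = ExpressionMetaAnalysis(datasets).fit()
        top = res.top_table("down", k=10)
        expected_cols = [f"{d.dataset_id}_FC" for d in datasets] + \
                        [f"{d.dataset_id}_AdjPval" for d in datasets] + \
                        ["combined_es", "fdr"]
        assert list(top.columns) == expected_cols
        mags = top["combined_es"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)
        assert res.summary().startswith("Random-effects")
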