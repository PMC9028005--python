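"""Cosine anti-similarity screen with permutation null and BBB filter."""

import numpy as np
import pandas as pd
import pytest

from metareverse.antisig import (AntiSignatureScreen, SignatureVector,
                                 bbb_annotate, build_disease_vector,
                                 cosine_similarity,
                                 permutation_antisimilarity, select_hits)
from metareverse.drugsig import build_meta_signatures, meta_signature_matrix
from metareverse.io import BBBTable
from metareverse.simulate import SimulationConfig, simulate_drug_library


class TestCosine:
    def test_self_and_negation(self):
        v = [1.0, -2.0, 0.5]
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(v, [-x for x in v]) == pytest.approx(-1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_worked_example(self):
        assert cosine_similarity([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14)

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 2])


class TestDiseaseVector:
    def _degs(self, genes, es):
        return pd.DataFrame({"combined_es": es},
                            index=pd.Index(genes, name="gene"))

    def test_all_degs_in_universe(self):
        degs = self._degs(["a", "b", "c"], [2.2507, -1.0, 0.5])
        vec = build_disease_vector(degs, ["a", "b", "c", "d"])
        assert len(vec) == 3
        # signed combined effect size carried through unchanged
        assert vec.values[list(vec.genes).index("a")] == pytest.approx(2.2507)

    def test_outside_universe_dropped(self):
        degs = self._degs(["a", "b", "x"], [1, -1, 2])
        vec = build_disease_vector(degs, ["a", "b", "c"])
        assert set(vec.genes) == {"a", "b"}

    def test_disjoint_universe_errors(self):
        with pytest.raises(ValueError):
            build_disease_vector(self._degs(["a"], [1.0]), ["z"])

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            SignatureVector(genes=pd.Index(["a", "b"]), values=[0.0, 0.0])


def _screen_inputs(seed=0, anti_strength=0.5, n_drugs=40, n_genes=300,
                   n_de=30, n_planted=3):
    cfg = SimulationConfig(n_genes=n_genes, n_de_genes=n_de, n_drugs=n_drugs,
                           n_planted_anti_drugs=n_planted,
                           anti_strength=anti_strength, seed=seed)
    from metareverse.simulate import simulate_cohorts
    _, truth = simulate_cohorts(cfg)
    lib = simulate_drug_library(cfg, truth)
    sm = meta_signature_matrix(build_meta_signatures(lib), lib.universe)
    vec = SignatureVector(genes=truth.de_genes.index,
                          values=(truth.de_genes["sign"]
                                  * truth.de_genes["delta"]).to_numpy())
    return vec, sm, truth


class TestPermutationScreen:
    def test_perfect_reversal_attains_minimum_p(self):
        vec, sm, truth = _screen_inputs(anti_strength=1.0)
        records = permutation_antisimilarity(vec, sm, n_perm=99, seed=1)
        planted = records[records["drug"].isin(truth.anti_drugs)]
        np.testing.assert_allclose(planted["cosine"], -1.0, atol=1e-10)
        np.testing.assert_allclose(planted["p_emp"], 1 / 100)

    def test_add_one_bound_and_fdr_order(self):
        vec, sm, _ = _screen_inputs(seed=3)
        records = permutation_antisimilarity(vec, sm, n_perm=50, seed=2)
        assert (records["p_emp"] >= 1 / 51 - 1e-15).all()
        assert (records["p_emp"] > 0).all()
        assert (records["fdr"] >= records["p_emp"] - 1e-12).all()

    def test_same_seed_identical_records(self):
        vec, sm, _ = _screen_inputs(seed=4)
        r1 = permutation_antisimilarity(vec, sm, n_perm=50, seed=9)
        r2 = permutation_antisimilarity(vec, sm, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_gene_relabelling_invariance(self):
        """Shuffling universe row order must not change any record."""
        vec, sm, _ = _screen_inputs(seed=5)
        rng = np.random.default_rng(0)
        shuffled = sm.iloc[rng.permutation(len(sm))]
        r1 = permutation_antisimilarity(vec, sm, n_perm=30, seed=7)
        r2 = permutation_antisimilarity(vec, shuffled, n_perm=30, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_low_overlap_drugs_excluded(self):
        vec, sm, _ = _screen_inputs(seed=6)
        small = SignatureVector(genes=vec.genes[:5], values=vec.values[:5])
        records = permutation_antisimilarity(small, sm, n_perm=20, seed=1)
        assert records["low_overlap"].all()
        assert records["fdr"].isna().all()
        assert select_hits(records, 0.05).empty

    def test_model_front_end_matches_function(self):
        vec, sm, _ = _screen_inputs(seed=7)
        res = AntiSignatureScreen(vec, sm, n_perm=40, seed=3).fit()
        direct = permutation_antisimilarity(vec, sm, n_perm=40, seed=3)
        pd.testing.assert_frame_equal(res.records, direct)
        assert "drugs screened" in res.summary()


class TestHitsAndBbb:
    def _records(self):
        return pd.DataFrame({
            "drug": ["efv", "pos", "weak", "var"],
            "cosine": [-0.28, 0.30, -0.05, -0.24],
            "p_emp": [0.001, 0.001, 0.4, 0.002],
            "fdr": [0.01, 0.001, 0.6, 0.01],
            "n_perm": 1000,
            "low_overlap": False,
        })

    def test_negative_and_significant_retained(self):
        hits = select_hits(self._records(), alpha=0.05)
        assert list(hits["drug"]) == ["efv", "var"]  # cosine ascending

    def test_positive_cosine_excluded_despite_fdr(self):
        hits = select_hits(self._records(), alpha=0.05)
        assert "pos" not in set(hits["drug"])

    def test_alpha_zero_empty(self):
        assert select_hits(self._records(), alpha=0.0).empty

    def test_bbb_join_and_permeable_only(self):
        table = BBBTable(labels={"var": "permeable", "efv": "non_permeable"})
        annotated = bbb_annotate(self._records(), table)
        assert list(annotated["bbb"]) == ["non_permeable", "unknown",
                                          "unknown", "permeable"]
        only = bbb_annotate(self._records(), table, permeable_only=True)
        assert list(only["drug"]) == ["var"]

    def test_empty_bbb_table_all_unknown(self):
        annotated = bbb_annotate(self._records(), BBBTable())
        assert (annotated["bbb"] == "unknown").all()
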