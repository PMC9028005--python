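"""Synthetic-data generators: reproducibility and planted structure."""

import numpy as np
import pytest

from metareverse.io import write_gmt
from metareverse.meta import _hedges_g_matrix
from metareverse.simulate import (SimulationConfig, simulate_bbb_table,
                                  simulate_cohorts, simulate_drug_library,
                                  simulate_gene_sets)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_de_genes": 600, "n_genes": 500},
        {"anti_strength": 1.5},
        {"bbb_fraction": -0.1},
        {"n_planted_anti_drugs": 20, "n_drugs": 10},
        {"n_genes": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_default_cohort_sizes_are_study_sizes(self):
        cfg = SimulationConfig()
        assert [(c[0], c[1]) for c in cfg.cohorts] == [(18, 37), (18, 15)]


class TestCohorts:
    def test_same_seed_identical(self, tmp_path):
        cfg = SimulationConfig(n_genes=100, n_de_genes=10, seed=5)
        ds1, t1 = simulate_cohorts(cfg)
        ds2, t2 = simulate_cohorts(cfg)
        for a, b in zip(ds1, ds2):
            assert a.matrix.equals(b.matrix)
        assert t1.de_genes.equals(t2.de_genes)

    def test_null_effect_vanishes_with_samples(self):
        diffs = []
        for n in (10, 200):
            cfg = SimulationConfig(n_genes=300, n_de_genes=10,
                                   effect_size_delta=0.0,
                                   cohorts=[(n, n, 0.5)], seed=2)
            (ds,), _ = simulate_cohorts(cfg)
            ctrl = ds.matrix[ds.group_samples("control")].to_numpy()
            case = ds.matrix[ds.group_samples("case")].to_numpy()
            diffs.append(np.abs(case.mean(1) - ctrl.mean(1)).mean())
        assert diffs[1] < diffs[0] / 2

    def test_planted_effect_recovered_as_hedges_g(self):
        """Monte-Carlo oracle: mean g over DE genes ~ delta at n=200/200."""
        gs = []
        for seed in range(50):
            cfg = SimulationConfig(n_genes=200, n_de_genes=40,
                                   effect_size_delta=1.0, noise_sd=1.0,
                                   cohorts=[(200, 200, 0.0)], seed=seed)
            (ds,), truth = simulate_cohorts(cfg)
            sub = ds.matrix.loc[truth.de_genes.index]
            g, _ = _hedges_g_matrix(sub[ds.group_samples("control")].to_numpy(),
                                    sub[ds.group_samples("case")].to_numpy())
            gs.append((g * truth.de_genes["sign"].to_numpy()).mean())
        assert np.mean(gs) == pytest.approx(1.0, abs=0.05)

    def test_signs_split_evenly(self):
        cfg = SimulationConfig(n_genes=500, n_de_genes=100, seed=3)
        _, truth = simulate_cohorts(cfg)
        assert (truth.de_genes["sign"] == 1).sum() == 50


class TestDrugLibrary:
    def test_full_strength_zero_noise_reverses_exactly(self, small_cohorts):
        _, truth = small_cohorts
        cfg = SimulationConfig(n_genes=len(truth.genes), n_drugs=10,
                               n_planted_anti_drugs=2, anti_strength=1.0,
                               seed=9)
        lib = simulate_drug_library(cfg, truth)
        u = truth.disease_direction
        for drug in truth.anti_drugs:
            for rep in lib.replicates[drug]:
                cos = rep @ u / (np.linalg.norm(rep) * np.linalg.norm(u))
                assert cos == pytest.approx(-1.0, abs=1e-12)

    def test_zero_strength_indistinguishable_from_background(self, small_cohorts):
        _, truth = small_cohorts
        cfg = SimulationConfig(n_genes=len(truth.genes), n_drugs=40,
                               n_planted_anti_drugs=20, anti_strength=0.0,
                               seed=10)
        lib = simulate_drug_library(cfg, truth)
        u = truth.disease_direction
        cosines = [rep @ u / np.linalg.norm(rep)
                   for d in truth.anti_drugs for rep in lib.replicates[d]]
        # null cosine sd is 1/sqrt(p); mean over 60 draws well inside 3 se
        assert abs(np.mean(cosines)) < 3 / np.sqrt(len(cosines) * len(u))

    def test_all_drugs_default_fda_approved(self, small_config, small_cohorts):
        _, truth = small_cohorts
        lib = simulate_drug_library(small_config, truth)
        assert all(lib.fda_approved.values())
        assert len(lib) == small_config.n_drugs


class TestGeneSets:
    def test_fully_enriched_sets_hit_de_genes(self, small_cohorts):
        _, truth = small_cohorts
        coll = simulate_gene_sets(truth, n_sets=10, set_size=20,
                                  enriched_fraction=1.0, seed=1)
        de = set(truth.de_genes.index)
        for _, members in coll:
            assert len(set(members) & de) >= 10

    def test_unenriched_overlap_is_hypergeometric(self, small_cohorts):
        """Monte-Carlo oracle: mean overlap ~ set_size * n_de / n_genes."""
        _, truth = small_cohorts
        de = set(truth.de_genes.index)
        overlaps = []
        for seed in range(30):
            coll = simulate_gene_sets(truth, n_sets=10, set_size=20,
                                      enriched_fraction=0.0, seed=seed)
            overlaps += [len(set(m) & de) for _, m in coll]
        expected = 20 * len(de) / len(truth.genes)
        sd = np.sqrt(expected)  # approx hypergeometric sd upper bound
        assert np.mean(overlaps) == pytest.approx(
            expected, abs=3 * sd / np.sqrt(len(overlaps)))

    def test_fixed_seed_identical_gmt(self, tmp_path, small_cohorts):
        _, truth = small_cohorts
        for name in ("a.gmt", "b.gmt"):
            write_gmt(simulate_gene_sets(truth, seed=7), tmp_path / name)
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()


def test_bbb_table_covers_subset_with_fraction(small_cohorts):
    _, truth = small_cohorts
    drugs = [f"drug_{i:03d}" for i in range(1, 201)]
    table = simulate_bbb_table(truth, drugs, bbb_fraction=0.5, seed=4,
                               coverage=0.9)
    assert 0 < len(table) < len(drugs)
    frac_perm = np.mean([v == "permeable" for v in table.labels.values()])
    assert 0.3 < frac_perm < 0.7
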