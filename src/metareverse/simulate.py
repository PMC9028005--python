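"""Synthetic cohorts, drug libraries, gene sets and BBB tables.

The generators emulate the statistical structure the pipeline assumes,
with planted ground truth so every downstream stage can be scored:

* cohorts — log-intensity expression, gene baseline mu_g ~ N(7, 1),
  an additive per-cohort batch shift b_g ~ N(0, batch_shift_sd) drawn
  per gene, a group effect s_g * delta on a planted DE subset (signs
  split evenly up/down), and i.i.d. Gaussian noise;
* drug library — background replicates are i.i.d. N(0, 1) z-vectors;
  planted anti-drugs mix a reversed disease-direction component into
  the noise at a chosen strength (see :func:`simulate_drug_library`);
* gene sets — a stated fraction of sets draw at least half their
  members from the planted DE genes, the rest uniformly;
* BBB table — covers a subset of drugs with permeable/non-permeable
  labels at a chosen rate.

Default cohort sizes are 18 control / 37 case and 18 control / 15 case,
the sizes of the two entorhinal-cortex case/control studies the
pipeline was designed around, so power behaviour is comparable. All
draws descend from one master seed via ``numpy`` SeedSequence spawning,
so every artifact is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drugsig import DrugSignatureLibrary
from .io import BBBTable, ExpressionDataset, GeneSetCollection

#: fraction of drugs covered by the simulated BBB table; real benchmark
#: tables never cover a whole screening library
BBB_COVERAGE = 0.9


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs."""

    n_genes: int = 5000
    cohorts: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(18, 37, 1.0), (18, 15, 1.0)])
    n_de_genes: int = 200
    effect_size_delta: float = 1.0
    noise_sd: float = 1.0
    n_drugs: int = 200
    n_replicates_per_drug: int = 3
    n_planted_anti_drugs: int = 5
    anti_strength: float = 0.5
    bbb_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must be <= n_genes")
        counts = [self.n_genes, self.n_de_genes, self.n_drugs,
                  self.n_replicates_per_drug]
        counts += [n for nc, ncs, _ in self.cohorts for n in (nc, ncs)]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.anti_strength <= 1.0):
            raise ValueError("anti_strength must be in [0, 1]")
        if not (0.0 <= self.bbb_fraction <= 1.0):
            raise ValueError("bbb_fraction must be in [0, 1]")
        if self.n_planted_anti_drugs > self.n_drugs:
            raise ValueError("n_planted_anti_drugs must be <= n_drugs")
        if not self.cohorts:
            raise ValueError("need >=1 cohort")

    # deterministic child streams, one per artifact family
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the synthetic artifacts."""

    genes: list[str]
    de_genes: pd.DataFrame          # index gene, columns sign, delta
    anti_drugs: list[str] = field(default_factory=list)
    bbb_labels: dict[str, str] = field(default_factory=dict)

    @property
    def disease_direction(self) -> np.ndarray:
        """Unit vector over the gene universe: s_g * delta on DE genes."""
        v = np.zeros(len(self.genes))
        pos = pd.Index(self.genes).get_indexer(self.de_genes.index)
        v[pos] = self.de_genes["sign"].to_numpy() * self.de_genes["delta"].to_numpy()
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def to_dict(self) -> dict:
        return {
            "de_genes": {g: {"sign": int(r["sign"]), "delta": float(r["delta"])}
                         for g, r in self.de_genes.iterrows()},
            "anti_drugs": list(self.anti_drugs),
            "bbb_labels": dict(self.bbb_labels),
            "n_genes": len(self.genes),
        }


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohorts(config: SimulationConfig) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate one ExpressionDataset per configured cohort.

    Gene g, sample j of cohort i:
    x = mu_g + b_ig + s_g * delta * 1[case] * 1[g in DE] + eps,
    eps ~ N(0, noise_sd). mu_g is shared across cohorts; b_ig is drawn
    per cohort and gene with sd ``batch_shift_sd``.
    """
    genes = _gene_names(config.n_genes)
    rng = config._rng(0)
    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    de_idx = np.sort(rng.choice(config.n_genes, size=config.n_de_genes,
                                replace=False))
    signs = np.ones(config.n_de_genes, dtype=int)
    signs[config.n_de_genes // 2:] = -1
    signs = rng.permutation(signs)
    effect = np.zeros(config.n_genes)
    effect[de_idx] = signs * config.effect_size_delta

    de_table = pd.DataFrame(
        {"sign": signs, "delta": config.effect_size_delta},
        index=pd.Index([genes[i] for i in de_idx], name="gene"))
    truth = GroundTruth(genes=genes, de_genes=de_table)

    datasets = []
    for i, (n_ctrl, n_case, batch_sd) in enumerate(config.cohorts, start=1):
        crng = config._rng(100 + i)
        batch = crng.normal(0.0, batch_sd, size=config.n_genes)
        n = n_ctrl + n_case
        is_case = np.array([0] * n_ctrl + [1] * n_case)
        X = (mu[:, None] + batch[:, None]
             + np.outer(effect, is_case)
             + crng.normal(0.0, config.noise_sd, size=(config.n_genes, n)))
        dataset_id = f"cohort{i}"
        sample_ids = ([f"{dataset_id}_ctrl{j + 1}" for j in range(n_ctrl)]
                      + [f"{dataset_id}_case{j + 1}" for j in range(n_case)])
        manifest = pd.DataFrame({
            "sample_id": sample_ids,
            "group": ["control"] * n_ctrl + ["case"] * n_case,
            "batch": dataset_id,
        })
        matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"),
                              columns=sample_ids)
        datasets.append(ExpressionDataset(dataset_id=dataset_id,
                                          matrix=matrix, manifest=manifest))
    return datasets, truth


def simulate_drug_library(config: SimulationConfig,
                          disease_truth: GroundTruth) -> DrugSignatureLibrary:
    """Replicate z-score library with planted anti-correlated drugs.

    Background replicates are i.i.d. N(0, 1) over the universe. For a
    planted anti-drug with strength a, each replicate is

        z = -a * sqrt(p) * u + sqrt(1 - a^2) * eps,   eps ~ N(0, I_p)

    where u is the unit disease-direction vector over the p-gene
    universe. The sqrt(p) scaling keeps the replicate an (approximately)
    unit-variance z-vector at every strength while giving cosine(z, u)
    an expectation of about -a over the full universe; a = 1 with zero
    noise yields cosine exactly -1 and a = 0 is indistinguishable from
    background.
    """
    if config.n_planted_anti_drugs > config.n_drugs:
        raise ValueError("n_planted_anti_drugs must be <= n_drugs")
    p = len(disease_truth.genes)
    u = disease_truth.disease_direction
    rng = config._rng(200)
    width = max(3, len(str(config.n_drugs)))
    drug_names = [f"drug_{i:0{width}d}" for i in range(1, config.n_drugs + 1)]
    planted = sorted(rng.choice(config.n_drugs, size=config.n_planted_anti_drugs,
                                replace=False))
    planted_names = [drug_names[i] for i in planted]
    a = config.anti_strength
    replicates: dict[str, np.ndarray] = {}
    for i, name in enumerate(drug_names):
        eps = rng.normal(0.0, 1.0, size=(config.n_replicates_per_drug, p))
        if i in set(planted):
            reps = -a * np.sqrt(p) * u[None, :] + np.sqrt(1.0 - a**2) * eps
        else:
            reps = eps
        replicates[name] = reps
    disease_truth.anti_drugs = planted_names
    return DrugSignatureLibrary(
        universe=pd.Index(disease_truth.genes, name="gene"),
        replicates=replicates,
        fda_approved={d: True for d in drug_names})


def simulate_gene_sets(truth: GroundTruth, n_sets: int = 20,
                       set_size: int = 20, enriched_fraction: float = 0.5,
                       seed: int = 0) -> GeneSetCollection:
    """GMT collection with a fraction of sets enriched in the DE genes.

    Enriched sets draw at least half their members from the planted DE
    genes; the rest are uniform over the universe.
    """
    if set_size > len(truth.genes):
        raise ValueError("set_size must be <= universe size")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(300,)))
    de = list(truth.de_genes.index)
    universe = list(truth.genes)
    non_de = [g for g in universe if g not in set(de)]
    n_enriched = int(round(enriched_fraction * n_sets))
    sets: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        if i <= n_enriched:
            n_from_de = min((set_size + 1) // 2, len(de))
            members = list(rng.choice(de, size=n_from_de, replace=False))
            members += list(rng.choice(non_de, size=set_size - n_from_de,
                                       replace=False))
            name = f"SET_ENRICHED_{i:03d}"
        else:
            members = list(rng.choice(universe, size=set_size, replace=False))
            name = f"SET_RANDOM_{i:03d}"
        sets[name] = sorted(members)
    return GeneSetCollection(sets=sets, source="simulated")


def simulate_bbb_table(truth: GroundTruth, drug_names: list[str],
                       bbb_fraction: float = 0.5, seed: int = 0,
                       coverage: float = BBB_COVERAGE) -> BBBTable:
    """BBB table covering a subset of drugs.

    ``coverage`` of the drugs appear in the table at all; each covered
    drug is labelled permeable with probability ``bbb_fraction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(400,)))
    labels: dict[str, str] = {}
    for name in sorted(drug_names):
        if rng.random() >= coverage:
            continue
        label = "permeable" if rng.random() < bbb_fraction else "non_permeable"
        labels[name.strip().casefold()] = label
    truth.bbb_labels = dict(labels)
    return BBBTable(labels=labels)
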