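"""End-to-end orchestration of the meta-analysis + drug-screen pipeline.

``run_all`` chains: simulate (or ingest) -> ComBat -> random-effects
meta-analysis -> directional ORA -> consensus drug signatures ->
anti-signature permutation screen -> BBB annotation -> clustering of the
top hits. Every stage writes self-describing TSVs (header comments carry
the parameters), and a JSON manifest records version, parameters, seed
and a checksum of every artifact, so a rerun with the same config and
seed reproduces the run directory byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .antisig import (AntiSignatureScreen, bbb_annotate, build_disease_vector,
                      select_hits)
from .cluster import (complete_linkage, cosine_distance_matrix,
                      similarity_matrix, top_k_signatures)
from .combat import batch_variance_report, combat_adjust
from .drugsig import build_meta_signatures, meta_signature_matrix
from .enrich import enrich_directional, heatmap_table
from .meta import ExpressionMetaAnalysis
from .simulate import (SimulationConfig, simulate_bbb_table, simulate_cohorts,
                       simulate_drug_library, simulate_gene_sets)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML round-trippable)."""

    out_dir: str = "run"
    # input paths; None with simulate=True means generate synthetically
    cohort_paths: list[tuple[str, str, str]] = field(default_factory=list)
    library_path: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    bbb_path: str | None = None
    simulate: bool = True
    sim: dict = field(default_factory=dict)   # SimulationConfig overrides
    alpha_deg: float = 0.05
    n_perm: int = 1000
    fda_only: bool = True
    permeable_only: bool = False
    top_k: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw["cohort_paths"] = [tuple(t) for t in raw.get("cohort_paths", [])]
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    if config.permeable_only and not config.simulate and config.bbb_path is None:
        raise ValueError("permeable_only requires a BBB table")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {"version": __version__, "seed": config.seed,
              "alpha_deg": config.alpha_deg, "n_perm": config.n_perm,
              "fda_only": config.fda_only,
              "permeable_only": config.permeable_only, "top_k": config.top_k}

    # -- stage 0: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            sim = SimulationConfig(**{"seed": config.seed, **config.sim})
            datasets, truth = simulate_cohorts(sim)
            library = simulate_drug_library(sim, truth)
            collection = simulate_gene_sets(truth, seed=sim.seed)
            bbb = simulate_bbb_table(truth, library.drug_names,
                                     bbb_fraction=sim.bbb_fraction,
                                     seed=sim.seed)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            for ds in datasets:
                io.write_expression(ds, inputs / f"{ds.dataset_id}_matrix.tsv",
                                    inputs / f"{ds.dataset_id}_manifest.tsv")
            io.write_drug_library(library, inputs / "drug_library.tsv")
            io.write_gmt(collection, inputs / "gene_sets.gmt")
            io.write_bbb_table(bbb, inputs / "bbb.tsv")
            (inputs / "ground_truth.json").write_text(
                json.dumps(truth.to_dict(), sort_keys=True, indent=1))
            collections = [collection]
        else:
            if not config.cohort_paths or config.library_path is None:
                raise ValueError("cohort_paths and library_path are required "
                                 "when simulate=false")
            datasets = [io.read_expression(m, s, ds_id)
                        for m, s, ds_id in config.cohort_paths]
            library = io.read_drug_library(config.library_path)
            collections = [io.read_gmt(p) for p in config.gmt_paths]
            bbb = io.read_bbb_table(config.bbb_path) if config.bbb_path else None
        if config.permeable_only and bbb is None:
            raise ValueError("permeable_only requires a BBB table")

        # -- stage 1: batch correction ----------------------------------
        stage = "combat"
        merged = pd.concat([ds.matrix for ds in datasets], axis=1, join="inner")
        manifest = pd.concat([ds.manifest for ds in datasets], ignore_index=True)
        merged = merged.loc[:, list(manifest["sample_id"])]
        pre_report = batch_variance_report(merged, manifest["batch"]) \
            if len(datasets) > 1 else None
        adjusted = combat_adjust(merged, manifest["batch"], manifest["group"])
        io.write_result_table(adjusted, out / "adjusted_matrix.tsv",
                              params, index=True)
        if pre_report is not None:
            post_report = batch_variance_report(adjusted, manifest["batch"])
            diag = pre_report.rename(columns=lambda c: f"pre_{c}").join(
                post_report.rename(columns=lambda c: f"post_{c}"))
            io.write_result_table(diag, out / "batch_diagnostics.tsv",
                                  params, index=True)

        # -- stage 2: meta-analysis --------------------------------------
        stage = "meta"
        model = ExpressionMetaAnalysis.from_merged(adjusted, manifest)
        results = model.fit()
        io.write_result_table(results.table, out / "meta_results.tsv",
                              params, index=True)
        degs = results.call_degs(config.alpha_deg)
        io.write_result_table(degs, out / "degs.tsv", params, index=True)
        for direction in ("up", "down"):
            io.write_result_table(
                results.top_table(direction, k=20, alpha=config.alpha_deg),
                out / f"top20_{direction}.tsv", params, index=True)

        # -- stage 3: enrichment -----------------------------------------
        stage = "enrich"
        for i, coll in enumerate(collections, start=1):
            table = enrich_directional(degs, coll, results.table.index)
            io.write_result_table(table, out / f"enrichment_{i}.tsv", params)
            io.write_result_table(heatmap_table(table),
                                  out / f"enrichment_{i}_heatmap.tsv",
                                  params, index=True)

        # -- stage 4: consensus drug signatures --------------------------
        stage = "drugsig"
        signatures = build_meta_signatures(library, fda_only=config.fda_only)
        sig_matrix = meta_signature_matrix(signatures, library.universe)
        io.write_result_table(sig_matrix, out / "meta_signatures.tsv",
                              params, index=True)

        # -- stage 5: anti-signature screen ------------------------------
        stage = "match"
        disease_vec = build_disease_vector(degs, library.universe)
        screen = AntiSignatureScreen(disease_vec, sig_matrix,
                                     n_perm=config.n_perm, seed=config.seed)
        screen_results = screen.fit()
        records = screen_results.records
        if bbb is not None:
            records = bbb_annotate(records, bbb)
        io.write_result_table(records.sort_values(["cosine", "drug"]),
                              out / "screen_records.tsv", params)
        hits = select_hits(records, alpha=config.alpha_deg)
        io.write_result_table(hits, out / "hits.tsv", params)
        if bbb is not None:
            permeable = hits[hits["bbb"] == "permeable"].reset_index(drop=True)
            io.write_result_table(permeable, out / "hits_bbb_permeable.tsv",
                                  params)

        # -- stage 6: clustering of top drugs ----------------------------
        stage = "cluster"
        if len(records) >= 2:
            top = top_k_signatures(sig_matrix.loc[disease_vec.genes.intersection(
                sig_matrix.index)], records, k=config.top_k)
            linkage = complete_linkage(cosine_distance_matrix(top))
            (out / "dendrogram.nwk").write_text(linkage.to_newick() + "\n")
            io.write_result_table(linkage.merge_table(),
                                  out / "cluster_merges.tsv", params)
            io.write_result_table(similarity_matrix(top, linkage.leaf_order),
                                  out / "similarity_matrix.tsv", params,
                                  index=True)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    # -- manifest --------------------------------------------------------
    artifacts = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name != "run_manifest.json")
    manifest_doc = {
        "tool": "metareverse",
        "version": __version__,
        "parameters": params,
        "config": dataclasses.asdict(config),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest_doc, sort_keys=True, indent=1))
    return out
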