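"""End-to-end orchestration: normalize -> DE -> enrichment -> clustering ->
network ensemble -> consensus -> hubs, with a JSON manifest of every artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    log10_to_log2,
    quantile_normalize,
    read_expression_tsv,
    read_sample_meta,
    write_expression_tsv,
)
from .cluster import pca_samples, resistant_phase_correlations, signature_heatmap_order
from .diffexpr import run_pairwise, subtype_check
from .enrichment import enrich_direction_tables, pathway_alteration_profile, read_gmt
from .network import RegulatoryNetworkModel
from .simulate import (
    SimulationConfig,
    make_annotation_fixture,
    make_ground_truth,
    simulate_expression,
)

__all__ = ["PipelineConfig", "run_full"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seed of one full analysis run.

    Exactly one of (``expression_path``, ``simulate``) must be given.
    Threshold defaults follow the CML study design: DE at q <= 0.05, link
    q <= 0.01, consensus support >= 90 of 100 networks, 75% training
    fraction, hubs at out-degree >= 3.
    """

    out_dir: str = "phasenet_out"
    expression_path: str | None = None
    meta_path: str | None = None
    catalog_path: str | None = None
    simulate: dict | None = None
    input_scale: str = "log2"  # or "log10"
    quantile: bool = True
    q_de: float = 0.05
    lfc: float | None = None
    link_q: float = 0.01
    support: int = 90
    n_networks: int = 100
    train_frac: float = 0.75
    min_out: int = 3
    max_steps: int = 15
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if (self.expression_path is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of expression_path or simulate must be given"
            )
        if not (0 < self.q_de < 1 and 0 < self.link_q < 1):
            raise ValueError("q-value thresholds must lie in (0, 1)")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0 < self.support <= self.n_networks:
            raise ValueError("support must lie in (0, n_networks]")
        return self

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh)).validate()


def run_full(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the artifact manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    stage = "load"
    try:
        catalog = None
        truth = None
        if cfg.simulate is not None:
            sim = SimulationConfig(**cfg.simulate)
            truth = make_ground_truth(sim)
            matrix, meta = simulate_expression(truth, sim)
            truth.edges.to_csv(out / "ground_truth_edges.tsv", sep="\t", index=False)
            catalog = make_annotation_fixture(truth, seed=sim.seed)
        else:
            matrix = read_expression_tsv(cfg.expression_path)
            meta = read_sample_meta(cfg.meta_path)
            if cfg.catalog_path:
                catalog = read_gmt(cfg.catalog_path)
        record(stage, n_genes=matrix.shape[0], n_samples=matrix.shape[1])

        stage = "normalize"
        if cfg.input_scale == "log10":
            matrix = log10_to_log2(matrix)
        if cfg.quantile:
            matrix = quantile_normalize(matrix)
        write_expression_tsv(matrix, out / "normalized.tsv")
        record(stage, n_genes=matrix.shape[0], n_samples=matrix.shape[1],
               path=str(out / "normalized.tsv"))

        stage = "subtype_check"
        sub = subtype_check(matrix, meta, q_cut=cfg.q_de)
        record(stage, n_called=sub["n_called"],
               merge_recommended=sub["merge_recommended"])

        stage = "differential_expression"
        has_resistant = (meta["phase"] == "resistant").any()
        de = run_pairwise(
            matrix, meta, q_cut=cfg.q_de, lfc_cut=cfg.lfc,
            include_resistant=bool(has_resistant),
        )
        de.write_tables(out)
        record(stage, signature_size=len(de.signature),
               n_called={k: de.n_called(k) for k in de.tables})

        stage = "enrichment"
        if catalog:
            for name, tab in de.tables.items():
                enr = enrich_direction_tables(tab, catalog)
                enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
                prof = pathway_alteration_profile(tab, catalog)
                prof.to_csv(out / f"pathway_profile_{name}.tsv", sep="\t", index=False)
            record(stage, n_categories=len(catalog))
        else:
            record(stage, skipped="no catalog provided")

        stage = "pca_and_heatmap"
        pca = pca_samples(matrix)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")
        heat_info = {}
        if len(de.signature) >= 3:
            phase_cols = meta.loc[meta["phase"] != "resistant", "sample_id"]
            heat = signature_heatmap_order(
                matrix.loc[de.signature, [c for c in matrix.columns if c in set(phase_cols)]],
                meta,
            )
            heat["cross_table"].to_csv(out / "heatmap_cluster_phase.tsv", sep="\t")
            heat_info = {"cross_table": heat["cross_table"].to_dict()}
        record(stage, variance_fraction_pc1=float(pca.variance_fractions[0]),
               **heat_info)

        stage = "network"
        gene_set = de.signature if de.signature else list(matrix.index)
        phase_cols = [
            c for c in matrix.columns
            if meta.set_index("sample_id").loc[c, "phase"] != "resistant"
        ]
        model = RegulatoryNetworkModel(
            matrix[phase_cols], gene_set, link_q=cfg.link_q, max_steps=cfg.max_steps
        )
        results = model.fit(
            n_networks=cfg.n_networks, train_frac=cfg.train_frac,
            min_support=cfg.support, seed=cfg.seed,
        )
        results.consensus.edges.to_csv(out / "consensus_edges.tsv", sep="\t",
                                       index=False, float_format="%.6g")
        pq = results.prediction_quality()
        record(stage, n_signature=len(gene_set),
               n_consensus_edges=len(results.consensus.edges),
               median_r_real=pq["median_real"], median_r_random=pq["median_random"],
               utest_p=pq["utest_p"])

        stage = "hubs"
        hubs = results.hubs(de_tables=de.tables, min_out=cfg.min_out)
        hubs.to_csv(out / "hubs.tsv", sep="\t", index=False)
        record(stage, n_hubs=len(hubs),
               groups=hubs["behavior_group"].value_counts().to_dict()
               if "behavior_group" in hubs else {})

        if has_resistant:
            stage = "resistant_correlations"
            rc = resistant_phase_correlations(matrix, meta)
            rc["pairwise"].to_csv(out / "resistant_correlations.tsv", sep="\t",
                                  float_format="%.6g")
            record(stage, mean_by_phase=rc["mean_by_phase"].mean(axis=0).to_dict())
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        record("error", failed_stage=stage, message=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["results"] = {"de": de.summary(), "network": results.summary()}
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
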