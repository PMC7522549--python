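"""End-to-end orchestration: simulate -> differential (both layers) ->
integration -> optional enrichment -> lncRNA targets -> structure variation.

One global seed deterministically derives per-stage seeds by hashing the
stage name, so any stage can be re-run in isolation from its persisted
inputs and reproduce its persisted outputs. Each stage writes a tidy TSV and
the run ends with a JSON manifest recording the configuration echo, record
counts, seeds consumed and wall-clock per stage.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrichment, integration, regulatory, structvar
from .io import write_design, write_expression_matrix, write_report
from .models import LAYER_MRNA, LAYER_PROTEIN, ExpressionMatrix
from .simulate import (
    GroundTruth,
    SimulationConfig,
    generate_lncrna_layer,
    generate_paired_omics,
    generate_structure_tables,
)

__version__ = "0.1.0"


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from the global seed and the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    simulation: SimulationConfig | None = None
    fdr_threshold: float = differential.DEFAULT_FDR_THRESHOLD
    fc_threshold: float = differential.DEFAULT_FC_THRESHOLD
    pseudocount: float = differential.DEFAULT_PSEUDOCOUNT
    trans_abs_r: float = regulatory.DEFAULT_TRANS_ABS_R
    up_window: int = regulatory.DEFAULT_UP_WINDOW
    dw_window: int = regulatory.DEFAULT_DW_WINDOW
    overlap_replicates: int = 10_000
    gsea_gmt: str | None = None
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5

    def __post_init__(self) -> None:
        if self.simulation is None:
            raise ValueError("a simulation block is required (real-input mode is file-driven via the CLI subcommands)")


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage on simulated inputs and persist all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={**asdict(config)})
    results: dict[str, pd.DataFrame] = {}

    def timed(stage):
        manifest.seeds[stage] = stage_seed(config.seed, stage)
        return time.perf_counter()

    # --- simulate ---------------------------------------------------------
    t0 = timed("simulate")
    sim = SimulationConfig(**{**asdict(config.simulation), "seed": stage_seed(config.seed, "simulate")})
    mrna, protein, truth = generate_paired_omics(sim)
    lnc_annotations, lnc_expr, intended = generate_lncrna_layer(sim, mrna, truth)
    variants, splice, fusions = generate_structure_tables(sim, truth)
    design = sim.design()
    write_design(design, out / "design.tsv")
    write_expression_matrix(mrna, out / "mrna_counts.tsv")
    write_expression_matrix(protein, out / "protein_intensity.tsv")
    results["ground_truth"] = truth.genes
    results["lncrna_intended_relations"] = intended
    manifest.stage_seconds["simulate"] = time.perf_counter() - t0

    # --- differential, both layers ---------------------------------------
    t0 = timed("de")
    de_mrna = differential.run_differential(
        mrna, config.fdr_threshold, config.fc_threshold, config.pseudocount
    )
    de_protein = differential.run_differential(
        protein, config.fdr_threshold, config.fc_threshold, config.pseudocount
    )
    results["de_mrna"] = de_mrna
    results["de_protein"] = de_protein
    manifest.stage_seconds["de"] = time.perf_counter() - t0

    # --- integration ------------------------------------------------------
    t0 = timed("integrate")
    corr, fraction_positive = integration.per_gene_correlation(mrna, protein)
    consistent, inconsistent = integration.select_hub_genes(de_mrna, de_protein)
    n_sig_m = int(de_mrna["significant"].sum())
    n_sig_p = int(de_protein["significant"].sum())
    observed = len(consistent) + len(inconsistent)
    overlap = integration.overlap_permutation_test(
        universe_mrna=mrna.n_genes,
        universe_protein=protein.n_genes,
        n_de_mrna=n_sig_m,
        n_de_protein=n_sig_p,
        observed=observed,
        replicates=config.overlap_replicates,
        seed=stage_seed(config.seed, "integrate"),
    )
    candidates = pd.concat([consistent, inconsistent], ignore_index=True)
    if len(candidates) >= 3:
        fc_r, fc_p = integration.cross_omics_fc_correlation(candidates)
    else:
        fc_r, fc_p = float("nan"), float("nan")
    results["correlation"] = corr
    results["hub_genes"] = consistent
    results["co_de_inconsistent"] = inconsistent
    results["overlap_test"] = overlap.to_frame()
    results["integration_summary"] = pd.DataFrame(
        [
            {
                "fraction_positive_correlation": fraction_positive,
                "n_significant_mrna": n_sig_m,
                "n_significant_protein": n_sig_p,
                "n_co_differential": observed,
                "n_trend_consistent": len(consistent),
                "fc_correlation_r": fc_r,
                "fc_correlation_p": fc_p,
            }
        ]
    )
    manifest.stage_seconds["integrate"] = time.perf_counter() - t0

    # --- enrichment (optional) -------------------------------------------
    t0 = timed("gsea")
    if config.gsea_gmt:
        sets = enrichment.read_gmt(config.gsea_gmt)
        ranking = corr.loc[~corr["degenerate"]].set_index("gene_id")["pearson_r"]
        ranked = enrichment.RankedList.from_scores(ranking)
        results["gsea"] = enrichment.gsea_preranked(
            ranked,
            sets,
            n_perm=config.gsea_n_perm,
            weight=config.gsea_weight,
            min_size=config.gsea_min_size,
            seed=stage_seed(config.seed, "gsea"),
        )
    else:
        manifest.notes.append("gsea skipped: no gene sets")
    manifest.stage_seconds["gsea"] = time.perf_counter() - t0

    # --- lncRNA targets ----------------------------------------------------
    t0 = timed("lncrna")
    gene_annotations = [a for a in lnc_annotations if a.biotype == "mrna"]
    lncrna_annotations = [a for a in lnc_annotations if a.biotype == "lncrna"]
    results["lncrna_targets"] = regulatory.call_targets(
        lncrna_annotations,
        lnc_expr,
        gene_annotations,
        mrna,
        hub_genes=sorted(consistent["gene_id"]),
        trans_abs_r=config.trans_abs_r,
        up_window=config.up_window,
        dw_window=config.dw_window,
    )
    manifest.stage_seconds["lncrna"] = time.perf_counter() - t0

    # --- structure variation ----------------------------------------------
    t0 = timed("structvar")
    results["variant_association"] = structvar.variant_association(variants, design)
    results["splice_association"] = structvar.splice_association(splice, design)
    results["fusion_summary"] = structvar.summarize_fusions(fusions, design)
    manifest.stage_seconds["structvar"] = time.perf_counter() - t0

    manifest.record_counts = {name: int(len(df)) for name, df in results.items()}
    write_report(results, out, manifest.to_dict())
    return manifest
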