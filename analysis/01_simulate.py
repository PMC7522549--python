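#!/usr/bin/env python
"""Generate the synthetic paired-omics dataset at the target study design.

5 cases vs 5 controls; 17,860 mRNAs with a 4,800-gene protein subset; 728
planted differential mRNAs and 439 differential proteins, 31 co-differential
(23 trend-consistent hubs); lncRNA loci at controlled distances from hub
genes; variant/splice/fusion tables with planted case-associated events.

Full matrices go to scratch/ (they are large, regenerable artifacts); the
ground-truth summary goes to results/.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from pashub.io import (
    write_annotation_bed,
    write_design,
    write_expression_matrix,
    write_fusion_table,
    write_report,
    write_splice_table,
    write_variant_table,
)
from pashub.simulate import (
    SimulationConfig,
    generate_lncrna_layer,
    generate_paired_omics,
    generate_structure_tables,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--scratch", type=Path, default=Path("scratch/analysis/simulated"))
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.scratch.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    mrna, protein, truth = generate_paired_omics(cfg)
    annotations, lnc_expr, intended = generate_lncrna_layer(cfg, mrna, truth)
    variants, splice, fusions = generate_structure_tables(cfg, truth)

    design = cfg.design()
    write_design(design, args.scratch / "design.tsv")
    write_expression_matrix(mrna, args.scratch / "mrna_counts.tsv")
    write_expression_matrix(protein, args.scratch / "protein_intensity.tsv")
    write_expression_matrix(lnc_expr, args.scratch / "lncrna_counts.tsv")
    write_annotation_bed(annotations, args.scratch / "annotations.bed")
    write_variant_table(variants, args.scratch / "variants.tsv")
    write_splice_table(splice, args.scratch / "splice_events.tsv")
    write_fusion_table(fusions, args.scratch / "fusions.tsv")
    truth.genes.to_csv(args.scratch / "ground_truth.tsv", sep="\t", index=False)
    intended.to_csv(args.scratch / "lncrna_intended.tsv", sep="\t", index=False)

    g = truth.genes
    summary = pd.DataFrame(
        [
            {
                "n_mrna": mrna.n_genes,
                "n_protein": protein.n_genes,
                "n_case": design.n_case,
                "n_control": design.n_control,
                "planted_de_mrna": int(g["de_in_mrna"].sum()),
                "planted_de_protein": int(g["de_in_protein"].sum()),
                "planted_hubs": int(g["hub"].sum()),
                "planted_consistent_hubs": int(g["trend_consistent"].sum()),
                "n_lncrna": len(intended),
                "planted_variant_units": len(truth.planted_variant_units),
                "planted_splice_units": len(truth.planted_splice_units),
            }
        ]
    )
    write_report({"01_simulation_summary": summary}, args.results, {"seed": args.seed, "config": asdict(cfg)})
    print(summary.to_string(index=False))
    print(f"full tables -> {args.scratch}")


if __name__ == "__main__":
    main()
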