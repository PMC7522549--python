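#!/usr/bin/env python
"""Classify lncRNA-hub-gene regulatory relations.

Positional rules first (within 10 kb upstream, 20 kb downstream, or
overlapping, strand-aware); remaining pairs become trans candidates when
|Pearson r| or |Spearman rho| across the 10 samples reaches 0.9.
"""

import argparse
from pathlib import Path

import pandas as pd

from pashub import regulatory
from pashub.io import read_annotation, read_design, read_expression_matrix, write_report
from pashub.models import LAYER_MRNA


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scratch", type=Path, default=Path("scratch/analysis/simulated"))
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    design = read_design(args.scratch / "design.tsv")
    anns = read_annotation(args.scratch / "annotations.bed", "bed")
    gene_anns = [a for a in anns if a.biotype == "mrna"]
    lnc_anns = [a for a in anns if a.biotype == "lncrna"]
    mrna = read_expression_matrix(args.scratch / "mrna_counts.tsv", LAYER_MRNA, design)
    lnc = read_expression_matrix(args.scratch / "lncrna_counts.tsv", LAYER_MRNA, design)
    hubs = pd.read_csv(args.results / "03_hub_genes.tsv", sep="\t")["gene_id"].tolist()

    calls = regulatory.call_targets(lnc_anns, lnc, gene_anns, mrna, hubs)
    called = calls[calls["relation"] != regulatory.RELATION_NONE]
    counts = called["figure_label"].value_counts().rename_axis("relation").reset_index(name="n_pairs")
    n_lnc = called["lncrna_id"].nunique()
    print(f"{n_lnc} lncRNAs called against {len(hubs)} hub genes:")
    print(counts.to_string(index=False))
    write_report(
        {"05_lncrna_targets": called, "05_relation_counts": counts},
        args.results,
        {"trans_abs_r": regulatory.DEFAULT_TRANS_ABS_R},
    )


if __name__ == "__main__":
    main()
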