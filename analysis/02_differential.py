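#!/usr/bin/env python
"""Call differential genes in each omics layer at FDR < 0.05, fold change > 1.5.

Counts are tested with the conditional NB exact test (common dispersion,
median-of-ratios library equalisation); protein intensities with Welch's t
on log2 values. Full per-gene tables go to scratch/; the up/down summary and
the top significant genes go to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pashub import differential
from pashub.io import read_design, read_expression_matrix, write_report
from pashub.models import LAYER_MRNA, LAYER_PROTEIN


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scratch", type=Path, default=Path("scratch/analysis/simulated"))
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    design = read_design(args.scratch / "design.tsv")
    summaries = {}
    for layer, path in ((LAYER_MRNA, "mrna_counts.tsv"), (LAYER_PROTEIN, "protein_intensity.tsv")):
        matrix = read_expression_matrix(args.scratch / path, layer, design)
        res = differential.run_differential(matrix)
        res.to_csv(args.scratch / f"de_{layer}.tsv", sep="\t", index=False)
        sig = res[res["significant"]]
        summaries[layer] = {
            "layer": layer,
            "n_genes": len(res),
            "n_significant": len(sig),
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
        }
        print(
            f"{layer}: {len(sig)} significant of {len(res)} "
            f"({summaries[layer]['n_up']} up, {summaries[layer]['n_down']} down)"
        )
    summary = pd.DataFrame(list(summaries.values()))
    write_report({"02_differential_summary": summary}, args.results, {"stage": "differential"})


if __name__ == "__main__":
    main()
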