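"""Positional and correlation-based lncRNA-target classification.

Cis candidates follow the positional rules of the source figure vocabulary:
a lncRNA within 10 kb upstream of a gene (cis_up10k), within 20 kb
downstream (cis_dw20k), or overlapping it by at least one base
(cis_overlap). Upstream/downstream are strand-aware — for a minus-strand
gene, upstream is the higher-coordinate side — and distances are measured
between nearest interval edges, the least-assumption reading since the
source never defines an anchor point. Pairs with no cis relation are called
trans when either |Pearson r| or |Spearman rho| across samples reaches a
threshold (default 0.9), otherwise none.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, GeneAnnotation, GenomicInterval

RELATION_UP = "cis_up10k"
RELATION_DOWN = "cis_dw20k"
RELATION_OVERLAP = "cis_overlap"
RELATION_TRANS = "trans"
RELATION_NONE = "none"

#: Output vocabulary used in study figures for the same relations.
FIGURE_LABELS = {
    RELATION_UP: "cis_mRNA_up10k",
    RELATION_DOWN: "cis_mRNA_dw20k",
    RELATION_OVERLAP: "cis_mRNA_overlap",
    RELATION_TRANS: "tran",
}

DEFAULT_UP_WINDOW = 10_000
DEFAULT_DW_WINDOW = 20_000
DEFAULT_TRANS_ABS_R = 0.9


def classify_cis(
    lncrna: GenomicInterval,
    gene: GenomicInterval,
    up_window: int = DEFAULT_UP_WINDOW,
    dw_window: int = DEFAULT_DW_WINDOW,
) -> tuple[str, int | None]:
    """Positional relation of a lncRNA locus to a gene locus.

    Returns (relation, distance); distance is the edge-to-edge gap in bp
    (0 for overlap, None when no cis relation holds). Precedence is
    overlap > up10k > dw20k. The gene strand must be known: silently
    guessing would flip up- and downstream for minus-strand genes.
    """
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene strand must be known for cis classification (gene at {gene.chrom}:{gene.start}-{gene.end})")
    if lncrna.chrom != gene.chrom:
        return RELATION_NONE, None
    if lncrna.overlaps(gene):
        return RELATION_OVERLAP, 0
    if lncrna.end < gene.start:
        gap = gene.start - lncrna.end
        side_is_upstream = gene.strand == "+"
    else:
        gap = lncrna.start - gene.end
        side_is_upstream = gene.strand == "-"
    if side_is_upstream and gap <= up_window:
        return RELATION_UP, gap
    if not side_is_upstream and gap <= dw_window:
        return RELATION_DOWN, gap
    return RELATION_NONE, None


def correlate_lncrna_gene(
    lncrna_expr: np.ndarray, gene_expr: np.ndarray
) -> tuple[float, float, bool]:
    """(Pearson r, Spearman rho, degenerate flag) across matched samples."""
    x = np.asarray(lncrna_expr, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression rows must be 1-D and matched")
    if len(x) < 3:
        raise ValueError("need at least 3 matched samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), True
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho, False


def call_targets(
    lncrna_annotations: list[GeneAnnotation],
    lncrna_expression: ExpressionMatrix,
    gene_annotations: list[GeneAnnotation],
    gene_expression: ExpressionMatrix,
    hub_genes: list[str],
    trans_abs_r: float = DEFAULT_TRANS_ABS_R,
    up_window: int = DEFAULT_UP_WINDOW,
    dw_window: int = DEFAULT_DW_WINDOW,
) -> pd.DataFrame:
    """Classify every (lncRNA, hub gene) pair.

    Cis relations are assigned by position regardless of correlation; trans
    is assigned when no cis relation holds and max(|r|, |rho|) >= the
    threshold; all other pairs are none. Hub genes without an annotation are
    skipped with a warning.
    """
    gene_loci = {a.gene_id: a.locus for a in gene_annotations}
    lnc_loci = {a.gene_id: a.locus for a in lncrna_annotations}
    rows = []
    for hub in hub_genes:
        if hub not in gene_loci:
            warnings.warn(f"hub gene {hub} lacks an annotation; skipped")
            continue
        gene_row = (
            gene_expression.values.loc[hub].to_numpy()
            if hub in gene_expression.gene_ids
            else None
        )
        for lnc_id, lnc_locus in lnc_loci.items():
            relation, distance = classify_cis(lnc_locus, gene_loci[hub], up_window, dw_window)
            r = rho = float("nan")
            if gene_row is not None and lnc_id in lncrna_expression.gene_ids:
                lnc_row = lncrna_expression.values.loc[lnc_id].to_numpy()
                r, rho, degen = correlate_lncrna_gene(np.log2(lnc_row + 1), np.log2(gene_row + 1))
            if relation == RELATION_NONE and np.nanmax(
                [abs(r) if np.isfinite(r) else 0.0, abs(rho) if np.isfinite(rho) else 0.0]
            ) >= trans_abs_r:
                relation = RELATION_TRANS
            rows.append(
                {
                    "lncrna_id": lnc_id,
                    "gene_id": hub,
                    "relation": relation,
                    "figure_label": FIGURE_LABELS.get(relation, relation),
                    "distance": distance if distance is not None else np.nan,
                    "pearson_r": r,
                    "spearman_rho": rho,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "gene_id", "relation", "figure_label", "distance", "pearson_r", "spearman_rho"],
    )
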