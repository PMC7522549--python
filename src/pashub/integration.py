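"""Cross-omics integration: per-gene correlation, hub-gene selection, overlap null.

Hub genes are genes significant in both the transcriptome and the proteome
whose fold-change direction agrees across layers. The chance level of the
two-list intersection is assessed with a permutation null (random
differential sets of the observed sizes drawn from their universes) and an
analytic hypergeometric tail that serves as its closed-form oracle: because
the protein universe is a fixed subset of the mRNA universe and the protein
draw is uniform within it, the protein-universe size cancels and the overlap
is Hypergeometric(N = mRNA universe, K = protein draws, n = mRNA draws).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix


@dataclass(frozen=True)
class OverlapTestResult:
    universe_mrna: int
    universe_protein: int
    n_de_mrna: int
    n_de_protein: int
    observed_overlap: int
    expected_overlap: float
    p_permutation: float
    p_hypergeometric: float
    replicates: int
    seed: int
    replicate_mean: float
    replicate_overlaps: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {k: getattr(self, k) for k in (
            "universe_mrna", "universe_protein", "n_de_mrna", "n_de_protein",
            "observed_overlap", "expected_overlap", "p_permutation",
            "p_hypergeometric", "replicates", "seed", "replicate_mean")}
        return pd.DataFrame([d])


def per_gene_correlation(
    mrna: ExpressionMatrix, protein: ExpressionMatrix, log_transform: bool = True
) -> tuple[pd.DataFrame, float]:
    """Pearson correlation between mRNA and protein levels of each shared gene.

    Computed across matched samples, on log2(x + 1) values by default (both
    layers are multiplicative). Returns the per-gene table and the fraction
    of non-degenerate genes with r > 0; genes with zero variance in either
    layer are flagged degenerate and excluded from that denominator.
    """
    if mrna.design.sample_ids != protein.design.sample_ids:
        raise ValueError("mRNA and protein matrices must share the sample design")
    n = len(mrna.design.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    shared = mrna.gene_ids.intersection(protein.gene_ids)
    if len(shared) == 0:
        raise ValueError("no shared genes between layers")
    x = mrna.values.loc[shared].to_numpy(dtype=float)
    y = protein.values.loc[shared].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    degenerate = (sx == 0) | (sy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r = np.where(degenerate, np.nan, r)
    table = pd.DataFrame(
        {"gene_id": shared, "pearson_r": r, "n_samples": n, "degenerate": degenerate}
    )
    ok = table.loc[~table["degenerate"], "pearson_r"]
    fraction_positive = float((ok > 0).mean()) if len(ok) else float("nan")
    return table, fraction_positive


def co_de_intersection(de_mrna: set[str], de_protein: set[str]) -> list[str]:
    """Exact intersection of the two significant sets, sorted by gene id."""
    return sorted(set(de_mrna) & set(de_protein))


def trend_filter(candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition co-differential genes by cross-layer fold-change sign agreement.

    Expects columns gene_id, log2fc_mrna, log2fc_protein (FDR columns pass
    through). A zero log2fc (possible only through pseudocounts) is
    classified inconsistent and flagged; partition is exhaustive, exclusive
    and invariant to row order.
    """
    df = candidates.copy()
    zero = (df["log2fc_mrna"] == 0) | (df["log2fc_protein"] == 0)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} candidate(s) with zero log2fc classified inconsistent")
    consistent_mask = (np.sign(df["log2fc_mrna"]) == np.sign(df["log2fc_protein"])) & ~zero
    df["trend_consistent"] = consistent_mask
    df = df.sort_values("gene_id", kind="stable").reset_index(drop=True)
    return df[df["trend_consistent"]].reset_index(drop=True), df[~df["trend_consistent"]].reset_index(drop=True)


def select_hub_genes(
    de_mrna: pd.DataFrame, de_protein: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Co-differential genes with per-layer statistics, split by trend consistency."""
    sig_m = de_mrna[de_mrna["significant"]].set_index("gene_id")
    sig_p = de_protein[de_protein["significant"]].set_index("gene_id")
    shared = co_de_intersection(set(sig_m.index), set(sig_p.index))
    cand = pd.DataFrame(
        {
            "gene_id": shared,
            "log2fc_mrna": sig_m.loc[shared, "log2fc"].to_numpy(),
            "fdr_mrna": sig_m.loc[shared, "fdr"].to_numpy(),
            "log2fc_protein": sig_p.loc[shared, "log2fc"].to_numpy(),
            "fdr_protein": sig_p.loc[shared, "fdr"].to_numpy(),
        }
    )
    return trend_filter(cand)


def overlap_hypergeometric_tail(
    universe_mrna: int, n_de_mrna: int, n_de_protein: int, observed: int
) -> float:
    """P(overlap >= observed) for random differential sets, closed form.

    X ~ Hypergeometric(N = universe_mrna, K = n_de_protein, n = n_de_mrna);
    the protein-universe size cancels because the protein draw is uniform
    within a fixed subset of the mRNA universe.
    """
    _check_overlap_args(universe_mrna, universe_mrna, n_de_mrna, n_de_protein, observed)
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, universe_mrna, n_de_protein, n_de_mrna))


def _check_overlap_args(universe_mrna, universe_protein, n_de_mrna, n_de_protein, observed):
    if universe_protein > universe_mrna:
        raise ValueError("protein universe must be a subset of the mRNA universe")
    if n_de_mrna > universe_mrna or n_de_protein > universe_protein:
        raise ValueError("differential counts exceed their universes")
    if observed > min(n_de_mrna, n_de_protein):
        raise ValueError("observed overlap exceeds the smaller differential set")
    if min(universe_mrna, universe_protein, n_de_mrna, n_de_protein) < 0 or observed < 0:
        raise ValueError("counts must be non-negative")


def overlap_permutation_test(
    universe_mrna: int,
    universe_protein: int,
    n_de_mrna: int,
    n_de_protein: int,
    observed: int,
    replicates: int = 10_000,
    seed: int = 0,
    conservative: bool = False,
    keep_replicates: bool = False,
) -> OverlapTestResult:
    """Permutation null for the co-differential overlap.

    Each replicate draws n_de_mrna labels without replacement from the mRNA
    universe and n_de_protein from the protein universe (a fixed subset of
    the mRNA universe) and counts the intersection. p is the plain tail
    proportion (overlap >= observed), matching the study's simulation
    convention; ``conservative=True`` switches to (b+1)/(m+1).
    """
    _check_overlap_args(universe_mrna, universe_protein, n_de_mrna, n_de_protein, observed)
    rng = np.random.default_rng(seed)
    overlaps = np.empty(replicates, dtype=np.int64)
    protein_hit = np.zeros(universe_protein, dtype=bool)
    for i in range(replicates):
        mrna_draw = rng.choice(universe_mrna, n_de_mrna, replace=False)
        in_protein = mrna_draw[mrna_draw < universe_protein]
        prot_draw = rng.choice(universe_protein, n_de_protein, replace=False)
        protein_hit[prot_draw] = True
        overlaps[i] = int(protein_hit[in_protein].sum())
        protein_hit[prot_draw] = False
    b = int((overlaps >= observed).sum())
    p = (b + 1) / (replicates + 1) if conservative else b / replicates
    return OverlapTestResult(
        universe_mrna=universe_mrna,
        universe_protein=universe_protein,
        n_de_mrna=n_de_mrna,
        n_de_protein=n_de_protein,
        observed_overlap=observed,
        expected_overlap=n_de_mrna * n_de_protein / universe_mrna,
        p_permutation=float(p),
        p_hypergeometric=overlap_hypergeometric_tail(universe_mrna, n_de_mrna, n_de_protein, observed),
        replicates=replicates,
        seed=seed,
        replicate_mean=float(overlaps.mean()),
        replicate_overlaps=overlaps if keep_replicates else None,
    )


def cross_omics_fc_correlation(candidates: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) over (log2fc_mrna, log2fc_protein) pairs."""
    if len(candidates) < 3:
        raise ValueError("need at least 3 gene pairs")
    res = stats.pearsonr(candidates["log2fc_mrna"], candidates["log2fc_protein"])
    return float(res.statistic), float(res.pvalue)
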