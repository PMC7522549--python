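"""Differential calling in each omics layer at FDR < 0.05 and fold change > 1.5.

The count layer is tested with a conditional negative-binomial exact test:
given the two-group total for a gene, the case-group sum follows a
beta-binomial law whose shape parameters are the group sample counts divided
by a common dispersion, so the unknown mean cancels. The dispersion is a
method-of-moments estimate pooled across genes — ten samples cannot support
per-gene dispersions. The intensity layer is tested with Welch's t on log2
values. Significance is threshold-driven: BH FDR below the cut and absolute
log2 fold change at least log2 of the fold-change cut, symmetric for up- and
down-regulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .models import LAYER_MRNA, LAYER_PROTEIN, ExpressionMatrix, SampleDesign

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.5

# Relative tolerance when comparing point probabilities in two-sided exact
# tests (guards against float noise splitting exact ties).
_TIE_RTOL = 1e-7


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample column to counts per million (library-size correction)."""
    if matrix.layer != LAYER_MRNA:
        raise ValueError("normalize_counts expects the mRNA count layer")
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    cpm = matrix.values / totals * 1e6
    return ExpressionMatrix(values=cpm, layer=matrix.layer, design=matrix.design)


def log2_fold_change(
    matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Per-gene log2((mean_case + c) / (mean_control + c)), case over control."""
    mean_case = matrix.case_values().mean(axis=1)
    mean_ctrl = matrix.control_values().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_case + pseudocount) - np.log2(mean_ctrl + pseudocount)
    # Both means zero with pseudocount 0 is the symmetric degenerate case.
    lfc = np.where((mean_case == 0) & (mean_ctrl == 0), 0.0, lfc)
    return pd.Series(lfc, index=matrix.gene_ids, name="log2fc")


def size_factors(matrix: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios effective library sizes (robust to composition bias).

    Total-count scaling is biased when differential genes are asymmetric in
    direction: strongly up-regulated genes inflate case-sample totals and
    shift every null gene down after scaling. The median ratio of each
    sample to the gene-wise geometric mean, over genes quantified in all
    samples, ignores that minority. Factors are normalised to mean 1; falls
    back to total-count factors if too few genes are everywhere-positive.
    """
    counts = matrix.values.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 50:
        log_gm = np.log(counts[positive]).mean(axis=1, keepdims=True)
        ratios = np.exp(np.log(counts[positive]) - log_gm)
        s = np.median(ratios, axis=0)
    else:
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("all-zero sample column")
        s = totals
    return s / s.mean()


def size_factor_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts divided by median-of-ratios size factors (original count scale)."""
    s = size_factors(matrix)
    return ExpressionMatrix(matrix.values / s, matrix.layer, matrix.design)


def estimate_common_dispersion(matrix: ExpressionMatrix) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    Uses within-group sample variances so planted group differences do not
    inflate the estimate: for NB, var = mu + phi * mu^2, hence
    phi = sum_g (v_g - m_g) / sum_g m_g^2 with pooled within-group moments.
    The mean-squared weights would let a handful of extreme-abundance genes
    dominate (and with few samples their variance estimates are noisy), so
    genes above the 95th abundance percentile are excluded from the pool.
    """
    case = matrix.case_values()
    ctrl = matrix.control_values()
    overall = np.hstack([case, ctrl]).mean(axis=1)
    keep = overall <= np.quantile(overall, 0.95) if len(overall) >= 100 else np.ones_like(overall, bool)
    num = 0.0
    den = 0.0
    for grp in (case, ctrl):
        m = grp.mean(axis=1)[keep]
        v = grp.var(axis=1, ddof=1)[keep]
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if den <= 0:
        return 1e-8
    return max(num / den, 1e-8)


def _betabinom_exact_p(s_case: int, total: int, n_case: int, n_control: int, phi: float) -> float:
    """Two-sided conditional NB exact p for one gene.

    Conditional on the total, the case-group sum is BetaBinomial(total,
    n_case/phi, n_control/phi). The two-sided p sums the probabilities of all
    outcomes no more probable than the observed one (point-probability
    method), evaluated in log space over a window that carries all
    non-negligible mass.
    """
    if total == 0:
        return 1.0
    if phi < 1e-6:
        # dispersion -> 0 limit: the conditional law is binomial (the
        # beta-binomial shapes overflow gammaln precision here)
        pmf = stats.binom.pmf(np.arange(total + 1), total, n_case / (n_case + n_control))
        obs = pmf[s_case]
        return float(min(1.0, pmf[pmf <= obs * (1 + _TIE_RTOL)].sum()))
    a = n_case / phi
    b = n_control / phi
    mean = total * a / (a + b)
    var = total * a * b * (a + b + total) / ((a + b) ** 2 * (a + b + 1))
    half = max(12.0 * np.sqrt(max(var, 1.0)), 50.0)
    lo = max(0, int(np.floor(mean - half)))
    hi = min(total, int(np.ceil(mean + half)))
    if total <= 4000:
        lo, hi = 0, total
    support = np.arange(lo, hi + 1)
    logp = stats.betabinom.logpmf(support, total, a, b)
    if s_case < lo or s_case > hi:
        return float(min(1.0, np.exp(stats.betabinom.logpmf(s_case, total, a, b))))
    lp_obs = logp[s_case - lo]
    keep = logp <= lp_obs + np.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def nb_exact_test(
    matrix: ExpressionMatrix, dispersion: float | None = None
) -> pd.Series:
    """Conditional NB exact test per gene on library-equalised counts."""
    design = matrix.design
    if design.n_case < 2 or design.n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    if (matrix.values.sum(axis=0).to_numpy() <= 0).any():
        raise ValueError("all-zero sample column")
    # Equalise effective library sizes so the common-mean assumption of the
    # conditional test holds across samples; median-of-ratios factors avoid
    # the composition bias of total-count scaling.
    scale = 1.0 / size_factors(matrix)
    eq = np.rint(matrix.values.to_numpy() * scale[None, :]).astype(np.int64)
    eq_df = pd.DataFrame(eq, index=matrix.gene_ids, columns=matrix.values.columns)
    eq_matrix = ExpressionMatrix(eq_df.astype(float), matrix.layer, design)
    if dispersion is None:
        dispersion = estimate_common_dispersion(eq_matrix)
    s_case = eq_matrix.case_values().sum(axis=1).astype(np.int64)
    s_ctrl = eq_matrix.control_values().sum(axis=1).astype(np.int64)
    n1, n2 = design.n_case, design.n_control
    pvals = np.ones(matrix.n_genes)
    for i in range(matrix.n_genes):
        pvals[i] = _betabinom_exact_p(int(s_case[i]), int(s_case[i] + s_ctrl[i]), n1, n2, dispersion)
    return pd.Series(pvals, index=matrix.gene_ids, name="p_raw")


def welch_t_test(matrix: ExpressionMatrix, log_offset: float = 1.0) -> pd.Series:
    """Two-sample unequal-variance t-test on log2 intensities per gene."""
    design = matrix.design
    if design.n_case < 2 or design.n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    case = np.log2(matrix.case_values() + log_offset)
    ctrl = np.log2(matrix.control_values() + log_offset)
    res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=matrix.gene_ids, name="p_raw")


def de_test(matrix: ExpressionMatrix, dispersion: float | None = None) -> pd.Series:
    """Layer-dispatching per-gene test: NB exact on counts, Welch t on intensities."""
    if matrix.layer == LAYER_MRNA:
        return nb_exact_test(matrix, dispersion=dispersion)
    if matrix.layer == LAYER_PROTEIN:
        return welch_t_test(matrix)
    raise ValueError(f"unknown layer {matrix.layer!r}")


def bh_adjust(p_values) -> pd.Series:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return pd.Series([], dtype=float, name="fdr")
    fdr = multipletests(p, method="fdr_bh")[1]
    index = p_values.index if isinstance(p_values, pd.Series) else None
    return pd.Series(fdr, index=index, name="fdr")


def call_differential(
    log2fc: pd.Series,
    fdr: pd.Series,
    p_raw: pd.Series | None = None,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Assemble per-gene differential results at the study thresholds.

    significant <=> fdr < fdr_threshold and |log2fc| >= log2(fc_threshold);
    "fold change > 1.5" is applied symmetrically for up- and down-regulation.
    """
    if fdr_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if not log2fc.index.equals(fdr.index):
        fdr = fdr.reindex(log2fc.index)
        if fdr.isna().any():
            raise ValueError("log2fc and fdr indices do not align")
    lfc_cut = np.log2(fc_threshold)
    out = pd.DataFrame(
        {
            "gene_id": log2fc.index,
            "log2fc": log2fc.to_numpy(),
            "p_raw": (p_raw.reindex(log2fc.index).to_numpy() if p_raw is not None else np.nan),
            "fdr": fdr.to_numpy(),
        }
    )
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["log2fc"].abs() >= lfc_cut)
    return out


def run_differential(
    matrix: ExpressionMatrix,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full single-layer differential analysis: normalise, test, adjust, call."""
    if matrix.layer == LAYER_MRNA:
        p = de_test(matrix)
        norm = size_factor_normalize(matrix)
        lfc = log2_fold_change(norm, pseudocount=pseudocount)
    else:
        p = de_test(matrix)
        lfc = log2_fold_change(matrix, pseudocount=pseudocount)
    fdr = bh_adjust(p)
    return call_differential(lfc, fdr, p_raw=p, fdr_threshold=fdr_threshold, fc_threshold=fc_threshold)


def significant_genes(result: pd.DataFrame) -> set[str]:
    return set(result.loc[result["significant"], "gene_id"])
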