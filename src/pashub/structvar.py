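"""Association of gene-structure variation with case status via exact tests.

SNP presence per (gene, effect class) and fusion presence are tested against
case status with a two-sided Fisher exact test using the point-probability
convention: the p-value sums the hypergeometric probabilities of all tables
with the observed margins that are no more probable than the observed table.
Splice-event expression is compared between groups with an exact
Mann-Whitney U test (full enumeration of the U distribution via dynamic
programming) when samples are few and untied, else a tie- and
continuity-corrected normal approximation flagged as approximate. Raw
p-values are reported by default; the study design reads single structural
hypotheses per hub gene, and a BH flag is available for reuse across many
units.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .models import SampleDesign, splice_sample_columns, validate_fusion_table, validate_splice_table, validate_variant_table

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (rows = case/control, columns = present/absent)."""

    a: int  # case, present
    b: int  # case, absent
    c: int  # control, present
    d: int  # control, absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(A = a) for the hypergeometric law of a 2x2 table with fixed margins."""
    n = row1 + row2

    def lchoose(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return float(lchoose(row1, a) + lchoose(row2, col1 - a) - lchoose(n, col1))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the point-probability method, in log space.

    Sums P(tables with the same margins) over all tables whose point
    probability is <= the observed one (within 1e-7 relative tolerance for
    ties). An empty margin makes every table identical: p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1 = a + c
    if row1 == 0 or row2 == 0 or col1 == 0 or b + d == 0:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    support = np.arange(lo, hi + 1)
    logp = np.array([_log_hypergeom_pmf(int(x), row1, row2, col1) for x in support])
    lp_obs = logp[a - lo]
    keep = logp <= lp_obs + np.log1p(_TIE_RTOL)
    p = float(np.exp(logp[keep]).sum())
    return min(1.0, p)


@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of rank configurations per U value (exact null distribution).

    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u): the largest
    observation belongs either to sample 1 (contributing n2 to U) or to
    sample 2. Returns counts for u = 0..n1*n2, summing to C(n1+n2, n1).
    """
    max_u = n1 * n2
    # DP over (count in sample 1, U): insert observations in increasing
    # order; a sample-1 value inserted after j sample-2 values adds j to U.
    table = {(0, 0): 1}
    for step in range(1, n1 + n2 + 1):
        nxt: dict[tuple[int, int], int] = {}
        for (i, u), v in table.items():
            j = step - 1 - i  # sample-2 values placed so far
            if i < n1:  # place a sample-1 value: exceeds j sample-2 values
                key = (i + 1, u + j)
                nxt[key] = nxt.get(key, 0) + v
            if j < n2:  # place a sample-2 value
                key = (i, u)
                nxt[key] = nxt.get(key, 0) + v
        table = nxt
    counts = [0] * (max_u + 1)
    for (i, u), v in table.items():
        if i == n1:
            counts[u] += v
    return tuple(counts)


def mann_whitney_exact(x, y) -> tuple[float, float, bool]:
    """Mann-Whitney U with exact two-sided p for small untied samples.

    Returns (U of the first sample, two-sided p, approximate flag). U is
    computed by rank summation with midranks for ties. For
    n_x + n_y <= 20 with no ties the p-value is exact: two-sided =
    2 * min(P(U <= u), P(U >= u)) capped at 1, from the enumerated U
    distribution. Otherwise a tie- and continuity-corrected normal
    approximation is used and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if n1 + n2 <= 20 and not has_ties:
        counts = _u_distribution(n1, n2)
        total = sum(counts)
        u = int(round(u1))
        lower = sum(counts[: u + 1]) / total
        upper = sum(counts[u:]) / total
        p = min(1.0, 2.0 * min(lower, upper))
        return float(u), float(p), False
    # Normal approximation with tie correction and continuity correction.
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return float(u1), 1.0, True
    z = (u1 - mu - np.sign(u1 - mu) * 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return float(u1), p, True


def variant_association(variants: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Fisher exact association of SNP presence with case status.

    One 2x2 table per (gene, effect class) unit: group membership against
    event presence. Units with zero presence overall are skipped; a unit
    present in every sample is degenerate (p = 1 by the empty-margin
    convention).
    """
    variants = validate_variant_table(variants)
    unknown = set(variants["sample_id"]) - set(design.sample_ids)
    if unknown:
        raise ValueError(f"variant sample id(s) not in design: {sorted(unknown)}")
    case_ids = set(design.case_ids)
    control_ids = set(design.control_ids)
    rows = []
    present = variants[variants["present"]]
    for (gene, eclass), grp in present.groupby(["gene_id", "effect_class"], sort=True):
        samples = set(grp["sample_id"])
        a = len(samples & case_ids)
        c = len(samples & control_ids)
        if a + c == 0:
            continue
        tab = ContingencyTable2x2(a, design.n_case - a, c, design.n_control - c)
        p = fisher_exact_two_sided(tab)
        rows.append(
            {
                "unit_id": f"{gene}:{eclass}",
                "gene_id": gene,
                "effect_class": eclass,
                "test": "fisher_exact",
                "case_present": a,
                "control_present": c,
                "statistic": float(a),
                "p_value": p,
                "degenerate": (a + c == len(design.sample_ids)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "gene_id", "effect_class", "test", "case_present", "control_present", "statistic", "p_value", "degenerate"],
    ).sort_values("p_value", kind="stable").reset_index(drop=True)


def splice_association(events: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Mann-Whitney association of splice-event expression with case status."""
    events = validate_splice_table(events, design)
    sample_cols = splice_sample_columns(events)
    rows = []
    for idx, row in events.iterrows():
        x = np.array([row[s] for s in design.case_ids], dtype=float)
        y = np.array([row[s] for s in design.control_ids], dtype=float)
        u, p, approx = mann_whitney_exact(x, y)
        rows.append(
            {
                "unit_id": f"{row['gene_id']}:{row['event_type']}:{row['chrom']}:{int(row['start'])}-{int(row['end'])}",
                "gene_id": row["gene_id"],
                "event_type": row["event_type"],
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "test": "mann_whitney",
                "statistic": u,
                "p_value": p,
                "approximate": approx,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "gene_id", "event_type", "chrom", "start", "end", "test", "statistic", "p_value", "approximate"],
    ).sort_values("p_value", kind="stable").reset_index(drop=True)


def summarize_fusions(
    fusions: pd.DataFrame, design: SampleDesign, with_test: bool = False
) -> pd.DataFrame:
    """Per-fusion case/control presence counts, optional Fisher p on request."""
    fusions = validate_fusion_table(fusions)
    case_ids = set(design.case_ids)
    control_ids = set(design.control_ids)
    rows = []
    present = fusions[fusions["present"]]
    for (ga, gb, chrom), grp in present.groupby(["gene_a", "gene_b", "chrom"], sort=True):
        samples = set(grp["sample_id"])
        a = len(samples & case_ids)
        c = len(samples & control_ids)
        if a + c == 0:
            continue  # fusion absent everywhere: excluded
        row = {
            "gene_a": ga,
            "gene_b": gb,
            "chrom": chrom,
            "case_count": a,
            "control_count": c,
        }
        if with_test:
            tab = ContingencyTable2x2(a, design.n_case - a, c, design.n_control - c)
            row["p_value"] = fisher_exact_two_sided(tab)
        rows.append(row)
    cols = ["gene_a", "gene_b", "chrom", "case_count", "control_count"] + (["p_value"] if with_test else [])
    return pd.DataFrame(rows, columns=cols)


def adjust_association(results: pd.DataFrame) -> pd.DataFrame:
    """Optional BH adjustment across association units (off by default upstream)."""
    from .differential import bh_adjust

    out = results.copy()
    out["fdr"] = bh_adjust(out["p_value"]).to_numpy()
    return out
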