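"""Exact Fisher and Mann-Whitney tests against enumeration oracles, and the
association drivers over variant/splice/fusion tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pashub import structvar as sv
from pashub.structvar import ContingencyTable2x2


# ------------------------------------------------------------------ Fisher
def oracle_fisher_two_sided(a, b, c, d):
    """Exact-fraction enumeration over all tables with the observed margins."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = math.comb(n, col1)
    probs = {}
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        probs[x] = math.comb(row1, x) * math.comb(row2, col1 - x)
    obs = probs[a]
    return sum(v for v in probs.values() if v <= obs) / denom


def test_fisher_reproduces_printed_association():
    """4 of 5 cases vs 0 of 5 controls: p = 0.048 at the printed precision."""
    p = sv.fisher_exact_two_sided(ContingencyTable2x2(4, 1, 0, 5))
    assert p == pytest.approx(10 / 210)
    assert round(p, 3) == 0.048


def test_fisher_symmetric_table_is_one():
    assert sv.fisher_exact_two_sided(ContingencyTable2x2(2, 3, 2, 3)) == pytest.approx(1.0)


def test_fisher_complete_separation():
    assert sv.fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(2 / 252)


def test_fisher_empty_margin_degenerate():
    assert sv.fisher_exact_two_sided(ContingencyTable2x2(5, 0, 5, 0)) == 1.0
    assert sv.fisher_exact_two_sided(ContingencyTable2x2(0, 0, 0, 5)) == 1.0


def test_fisher_matches_enumeration_oracle_exhaustively():
    """All tables with group sizes <= 8 match the exact-fraction oracle."""
    for row1 in range(1, 9):
        for row2 in range(1, 9):
            for a in range(row1 + 1):
                for c in range(row2 + 1):
                    tab = ContingencyTable2x2(a, row1 - a, c, row2 - c)
                    ours = sv.fisher_exact_two_sided(tab)
                    oracle = oracle_fisher_two_sided(a, row1 - a, c, row2 - c)
                    assert ours == pytest.approx(oracle, abs=1e-9), (a, row1, c, row2)


def test_fisher_agrees_with_scipy_cross_check():
    rng = np.random.default_rng(1)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 7, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        ours = sv.fisher_exact_two_sided(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
        theirs = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-6)


# ------------------------------------------------------------ Mann-Whitney
def oracle_mw_two_sided(x, y):
    """Enumerate all rank assignments (no ties) and assemble 2*min(tail)."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(n1 + n2), n1):
        r = [c + 1 for c in comb]
        us.append(sum(r) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lower = (us <= u_obs).mean()
    upper = (us >= u_obs).mean()
    return min(1.0, 2 * min(lower, upper))


def test_mw_reproduces_printed_splice_association():
    """U = 2 at 5 vs 5: exact two-sided p = 8/252, printed as 0.032."""
    x, y = [1, 2, 3, 4, 7], [5, 6, 8, 9, 10]
    u, p, approx = sv.mann_whitney_exact(x, y)
    assert u == 2 and not approx
    assert p == pytest.approx(8 / 252)
    assert round(p, 3) == 0.032


def test_mw_complete_separation_floor():
    u, p, _ = sv.mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
    assert u == 0 and p == pytest.approx(2 / 252)


def test_mw_group_swap_symmetry():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=5), rng.normal(size=6)
    u1, p1, _ = sv.mann_whitney_exact(x, y)
    u2, p2, _ = sv.mann_whitney_exact(y, x)
    assert p1 == pytest.approx(p2)
    assert u1 + u2 == pytest.approx(len(x) * len(y))


def test_mw_monotone_transform_invariance():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=5), rng.normal(size=5)
    _, p1, _ = sv.mann_whitney_exact(x, y)
    _, p2, _ = sv.mann_whitney_exact(np.exp(x), np.exp(y))
    assert p1 == pytest.approx(p2)


def test_mw_matches_enumeration_oracle():
    rng = np.random.default_rng(4)
    for n1, n2 in [(3, 3), (4, 5), (5, 5), (6, 6)]:
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        _, ours, approx = sv.mann_whitney_exact(x, y)
        assert not approx
        assert ours == pytest.approx(oracle_mw_two_sided(x, y), abs=1e-12)


def test_mw_agrees_with_scipy_exact_cross_check():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=5), rng.normal(size=5)
    _, ours, _ = sv.mann_whitney_exact(x, y)
    theirs = stats.mannwhitneyu(x, y, method="exact").pvalue
    assert ours == pytest.approx(theirs, rel=1e-9)


def test_mw_all_ties_is_approximate_p_one():
    u, p, approx = sv.mann_whitney_exact([3.0] * 5, [3.0] * 5)
    assert approx and p == 1.0


def test_mw_large_samples_take_normal_path():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=15, loc=1.0), rng.normal(size=15)
    _, p, approx = sv.mann_whitney_exact(x, y)
    assert approx and 0 <= p <= 1
    with pytest.raises(ValueError, match="non-empty"):
        sv.mann_whitney_exact([], [1.0])


# -------------------------------------------------------------- drivers
def _variant_frame(design, gene, eclass, present_samples):
    return pd.DataFrame(
        {
            "gene_id": gene,
            "effect_class": eclass,
            "sample_id": list(design.sample_ids),
            "present": [s in present_samples for s in design.sample_ids],
        }
    )


def test_variant_association_planted_unit(design10):
    planted = _variant_frame(design10, "FSTL3", "intergenic", set(design10.case_ids[:4]))
    res = sv.variant_association(planted, design10)
    assert len(res) == 1
    assert round(res.loc[0, "p_value"], 3) == 0.048
    assert (res.loc[0, "case_present"], res.loc[0, "control_present"]) == (4, 0)


def test_variant_association_all_present_degenerate(design10):
    everywhere = _variant_frame(design10, "g", "intron", set(design10.sample_ids))
    res = sv.variant_association(everywhere, design10)
    assert res.loc[0, "degenerate"]
    assert res.loc[0, "p_value"] == 1.0


def test_variant_association_skips_absent_units(design10):
    absent = _variant_frame(design10, "g", "utr", set())
    assert len(sv.variant_association(absent, design10)) == 0


def test_variant_association_attainable_size_under_null(design10):
    """1,000 balanced background units: at most 5% reach p <= 0.05 (the exact
    test's attainable size at 5 vs 5 is below nominal)."""
    rng = np.random.default_rng(7)
    frames = []
    for i in range(1000):
        present = {s for s in design10.sample_ids if rng.random() < 0.5}
        frames.append(_variant_frame(design10, f"bg{i:04d}", "missense", present))
    res = sv.variant_association(pd.concat(frames, ignore_index=True), design10)
    assert (res["p_value"] <= 0.05).mean() <= 0.05


def test_splice_association_planted_separation(design10):
    case_high = [100.0 + i for i in range(5)] + [1.0 + i * 0.1 for i in range(5)]
    df = pd.DataFrame(
        [["TSS", "LAMB3", "chr1", 209652369, 209652475, *case_high]],
        columns=["event_type", "gene_id", "chrom", "start", "end", *design10.sample_ids],
    )
    res = sv.splice_association(df, design10)
    assert res.loc[0, "p_value"] == pytest.approx(2 / 252)
    assert not res.loc[0, "approximate"]
    assert set(res["event_type"]) <= {"AE", "TSS", "TTS", "IR", "MIR", "SKIP", "MSKIP"}


def test_splice_association_constant_event(design10):
    df = pd.DataFrame(
        [["IR", "g", "chr1", 100, 200, *([5.0] * 10)]],
        columns=["event_type", "gene_id", "chrom", "start", "end", *design10.sample_ids],
    )
    res = sv.splice_association(df, design10)
    assert res.loc[0, "p_value"] == 1.0
    assert res.loc[0, "approximate"]


def test_fusion_summary_counts_and_optional_test(design10):
    rows = []
    for s in design10.sample_ids:
        rows.append(("INHA", "STK11IP", "chr2", s, s in {"PAS1", "PAS2", "PAS5"}))
        rows.append(("A", "B", "chr3", s, False))  # absent everywhere
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "chrom", "sample_id", "present"])
    summary = sv.summarize_fusions(df, design10)
    assert len(summary) == 1  # the absent fusion is excluded
    assert (summary.loc[0, "case_count"], summary.loc[0, "control_count"]) == (3, 0)
    assert "p_value" not in summary.columns  # counts only, as reported
    tested = sv.summarize_fusions(df, design10, with_test=True)
    assert tested.loc[0, "p_value"] == pytest.approx(1 / 6)
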