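"""Cross-omics integration: correlation, trend filter, and the permutation
overlap null against its hypergeometric closed form."""

import numpy as np
import pandas as pd
import pytest

from pashub import integration
from pashub.io import load_reference_hub_genes
from pashub.models import LAYER_PROTEIN


def test_identical_rows_correlate_at_one(design10, make_matrix):
    rng = np.random.default_rng(1)
    x = rng.uniform(1, 100, size=(3, 10))
    m = make_matrix(x, design10)
    p = make_matrix(x, design10, layer=LAYER_PROTEIN)
    table, frac = integration.per_gene_correlation(m, p, log_transform=False)
    np.testing.assert_allclose(table["pearson_r"], 1.0, atol=1e-12)
    assert frac == 1.0


def test_negated_rows_correlate_at_minus_one(design10, make_matrix):
    rng = np.random.default_rng(2)
    x = rng.uniform(1, 50, size=(3, 10))
    m = make_matrix(x, design10)
    p = make_matrix(-x + 100.0, design10, layer=LAYER_PROTEIN)
    table, frac = integration.per_gene_correlation(m, p, log_transform=False)
    np.testing.assert_allclose(table["pearson_r"], -1.0, atol=1e-12)
    assert frac == 0.0


def test_degenerate_rows_flagged_and_excluded(design10, make_matrix):
    x = np.vstack([np.arange(10.0) + 1, np.full(10, 7.0)])
    m = make_matrix(x, design10, genes=["g0", "g1"])
    p = make_matrix(x[::-1], design10, layer=LAYER_PROTEIN, genes=["g0", "g1"])
    table, frac = integration.per_gene_correlation(m, p, log_transform=False)
    assert table.set_index("gene_id").loc["g0", "degenerate"]
    assert table.set_index("gene_id").loc["g1", "degenerate"]
    assert np.isnan(frac)  # no non-degenerate gene remains


def test_default_generator_emulates_positive_majority(full_runs):
    """With default latent coupling most genes correlate positively (~62%)."""
    fracs = []
    for run in full_runs:
        _, frac = integration.per_gene_correlation(run["mrna"], run["protein"])
        fracs.append(frac)
    assert 0.55 < float(np.mean(fracs)) < 0.75


def test_intersection_examples():
    assert integration.co_de_intersection({"a", "b"}, {"c"}) == []
    assert integration.co_de_intersection({"a", "b"}, {"b", "a"}) == ["a", "b"]


def test_trend_filter_on_published_hub_table():
    ref = load_reference_hub_genes()
    consistent, inconsistent = integration.trend_filter(ref)
    assert len(consistent) == 23 and len(inconsistent) == 0
    # direction matches the printed signs gene by gene
    merged = consistent.set_index("gene_id")
    for row in ref.itertuples(index=False):
        assert np.sign(merged.loc[row.gene_id, "log2fc_mrna"]) == np.sign(row.log2fc_mrna)


def test_trend_filter_sign_cases():
    df = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "log2fc_mrna": [2.0, 2.0, 0.0],
            "log2fc_protein": [-1.0, 0.1, 1.0],
        }
    )
    with pytest.warns(UserWarning, match="zero log2fc"):
        consistent, inconsistent = integration.trend_filter(df)
    assert list(consistent["gene_id"]) == ["b"]
    assert list(inconsistent["gene_id"]) == ["a", "c"]  # zero-FC goes inconsistent


def test_trend_filter_invariant_to_row_order():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(20)],
            "log2fc_mrna": rng.normal(size=20),
            "log2fc_protein": rng.normal(size=20),
        }
    )
    c1, i1 = integration.trend_filter(df)
    c2, i2 = integration.trend_filter(df.sample(frac=1, random_state=0))
    assert list(c1["gene_id"]) == list(c2["gene_id"])
    assert list(i1["gene_id"]) == list(i2["gene_id"])
    assert len(c1) + len(i1) == len(df)  # exhaustive and exclusive


# ------------------------------------------------------------ overlap null
def test_hypergeometric_tail_small_instance_exact():
    """N=10 universe, draws 4 and 3: P(X >= 2) = 3/10 + 1/30 = 1/3 by enumeration."""
    assert integration.overlap_hypergeometric_tail(10, 4, 3, 2) == pytest.approx(1 / 3)
    assert integration.overlap_hypergeometric_tail(10, 4, 3, 0) == 1.0


def test_permutation_matches_hypergeometric_on_small_instance():
    res = integration.overlap_permutation_test(10, 6, 4, 3, 2, replicates=100_000, seed=42)
    p_exact = res.p_hypergeometric
    assert p_exact == pytest.approx(1 / 3)
    se = np.sqrt(p_exact * (1 - p_exact) / res.replicates)
    assert abs(res.p_permutation - p_exact) <= 4 * se


def test_permutation_observed_zero_gives_one():
    res = integration.overlap_permutation_test(50, 20, 10, 5, 0, replicates=500, seed=0)
    assert res.p_permutation == 1.0


def test_expected_overlap_matches_replicate_mean():
    res = integration.overlap_permutation_test(200, 80, 40, 20, 10, replicates=20_000, seed=1, keep_replicates=True)
    se = res.replicate_overlaps.std(ddof=1) / np.sqrt(res.replicates)
    assert abs(res.replicate_mean - res.expected_overlap) <= 3 * se
    # p is a multiple of 1/replicates (plain proportion convention)
    assert (res.p_permutation * res.replicates) == pytest.approx(round(res.p_permutation * res.replicates))


def test_overlap_precondition_violations():
    with pytest.raises(ValueError, match="subset"):
        integration.overlap_permutation_test(10, 20, 5, 5, 1)
    with pytest.raises(ValueError, match="exceed"):
        integration.overlap_hypergeometric_tail(10, 11, 3, 1)
    with pytest.raises(ValueError, match="observed"):
        integration.overlap_permutation_test(10, 6, 4, 3, 4)


def test_conservative_permutation_variant():
    res = integration.overlap_permutation_test(10, 6, 4, 3, 2, replicates=1000, seed=3, conservative=True)
    assert res.p_permutation == pytest.approx((round(res.p_permutation * 1001) ) / 1001)
    assert res.p_permutation > 0


# --------------------------------------------------------- fc correlation
def test_fc_correlation_perfect_lines():
    up = pd.DataFrame({"log2fc_mrna": [1.0, 2, 3], "log2fc_protein": [2.0, 4, 6]})
    r, p = integration.cross_omics_fc_correlation(up)
    assert r == pytest.approx(1.0)
    anti = pd.DataFrame({"log2fc_mrna": [1.0, 2, 3], "log2fc_protein": [-1.0, -2, -3]})
    r, _ = integration.cross_omics_fc_correlation(anti)
    assert r == pytest.approx(-1.0)


def test_fc_correlation_on_published_pairs_is_positive():
    """The 23 printed pairs correlate positively; the study's 0.63 used all
    31 pairs (8 unprinted), so only the sign and strength are checked."""
    ref = load_reference_hub_genes()
    r, p = integration.cross_omics_fc_correlation(ref)
    assert r > 0.5
    assert p < 0.01


def test_hub_selection_contains_detected_planted_hubs(full_runs):
    for run in full_runs:
        truth = run["truth"]
        called = set(run["consistent"]["gene_id"]) | set(run["inconsistent"]["gene_id"])
        sig_m = set(run["de_mrna"].loc[run["de_mrna"]["significant"], "gene_id"])
        sig_p = set(run["de_protein"].loc[run["de_protein"]["significant"], "gene_id"])
        detected_hubs = set(truth.hub_genes) & sig_m & sig_p
        assert detected_hubs <= called
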