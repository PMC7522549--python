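"""Differential layer: normalisation arithmetic, the conditional NB exact
test against an independent enumeration oracle, BH adjustment, and the
threshold logic on the published hub-gene table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pashub import differential as de
from pashub.io import load_reference_hub_genes
from pashub.models import LAYER_MRNA, LAYER_PROTEIN
from pashub.simulate import SimulationConfig, generate_paired_omics


# ---------------------------------------------------------------- normalise
def test_cpm_arithmetic(design10, make_matrix):
    values = np.ones((2, 10))
    values[0, 0] = 200.0
    values[1, 0] = 2_000_000.0 - 200.0
    m = make_matrix(values, design10)
    cpm = de.normalize_counts(m)
    assert cpm.values.iloc[0, 0] == pytest.approx(100.0)


def test_cpm_scale_invariance(design10, make_matrix):
    rng = np.random.default_rng(0)
    col = rng.integers(1, 100, size=20).astype(float)
    values = np.column_stack([col * (i + 1) for i in range(10)])  # proportional columns
    cpm = de.normalize_counts(make_matrix(values, design10))
    first = cpm.values.iloc[:, 0].to_numpy()
    for j in range(1, 10):
        np.testing.assert_allclose(cpm.values.iloc[:, j].to_numpy(), first, rtol=1e-12)


def test_cpm_rejects_all_zero_column(design10, make_matrix):
    values = np.ones((3, 10))
    values[:, 4] = 0.0
    with pytest.raises(ValueError, match="all-zero"):
        de.normalize_counts(make_matrix(values, design10))


# ------------------------------------------------------------- fold change
@pytest.mark.parametrize(
    "case_mean, ctrl_mean, pseudocount, expected",
    [
        (5.0, 5.0, 0.0, 0.0),
        (15.0, 5.0, 0.0, np.log2(3)),
        (0.0, 0.0, 0.5, 0.0),
    ],
)
def test_log2_fold_change_examples(design10, make_matrix, case_mean, ctrl_mean, pseudocount, expected):
    row = [case_mean] * 5 + [ctrl_mean] * 5
    m = make_matrix([row], design10)
    lfc = de.log2_fold_change(m, pseudocount=pseudocount)
    assert lfc.iloc[0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------- NB exact test
def oracle_conditional_nb_p(s1: int, total: int, n1: int, n2: int, phi: float, mu: float = 3.0) -> float:
    """Independent oracle: enumerate the conditional law from NB pmfs.

    The group sums are NB(n*mu, phi/n); conditioning on the total gives
    P(S1 = y | T = t) proportional to f1(y) f2(t - y), which must not depend
    on the arbitrary mu used here.
    """
    r1, r2 = n1 / phi, n2 / phi
    f1 = stats.nbinom(r1, r1 / (r1 + n1 * mu))
    f2 = stats.nbinom(r2, r2 / (r2 + n2 * mu))
    y = np.arange(total + 1)
    probs = f1.pmf(y) * f2.pmf(total - y)
    probs = probs / probs.sum()
    obs = probs[s1]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-7)].sum()))


@pytest.mark.parametrize("phi", [0.05, 0.1, 0.5])
@pytest.mark.parametrize("s1,total", [(0, 8), (4, 8), (7, 13), (15, 30), (10, 30)])
def test_nb_exact_matches_enumeration_oracle(s1, total, phi):
    ours = de._betabinom_exact_p(s1, total, 5, 5, phi)
    theirs = oracle_conditional_nb_p(s1, total, 5, 5, phi)
    assert ours == pytest.approx(theirs, abs=1e-10)
    # the oracle itself is mu-free (sanity on the conditioning argument)
    assert theirs == pytest.approx(oracle_conditional_nb_p(s1, total, 5, 5, phi, mu=11.0), abs=1e-12)


def test_nb_exact_identical_groups_gives_p_one(design10, make_matrix):
    rng = np.random.default_rng(2)
    block = rng.integers(5, 50, size=(20, 5)).astype(float)
    m = make_matrix(np.hstack([block, block]), design10)  # case columns copy controls
    p = de.nb_exact_test(m, dispersion=0.1)
    np.testing.assert_allclose(p.to_numpy(), 1.0, rtol=1e-9)


def test_nb_exact_dispersion_zero_limit_is_binomial():
    """As phi -> 0 the conditional law converges to Binomial(t, n1/(n1+n2))."""
    total, s1, n1, n2 = 12, 9, 5, 5
    ours = de._betabinom_exact_p(s1, total, n1, n2, phi=1e-10)
    pmf = stats.binom.pmf(np.arange(total + 1), total, n1 / (n1 + n2))
    obs = pmf[s1]
    expected = pmf[pmf <= obs * (1 + 1e-7)].sum()
    assert ours == pytest.approx(expected, rel=1e-6)


def test_nb_exact_type_i_calibration_on_null_simulation():
    """Empirical size at nominal 0.05 within [0.03, 0.07] on a 5,000-gene null."""
    cfg = SimulationConfig(
        n_mrna=5000,
        n_protein=500,
        n_de_mrna=0,
        n_de_protein=0,
        n_hub_consistent=0,
        n_hub_inconsistent=0,
        seed=7,
    )
    mrna, _, _ = generate_paired_omics(cfg)
    p = de.nb_exact_test(mrna)
    size = float((p <= 0.05).mean())
    assert 0.03 <= size <= 0.07


def test_welch_t_on_intensities(design10, make_matrix):
    rng = np.random.default_rng(4)
    base = np.exp2(rng.normal(20, 1, size=(50, 10)))
    m = make_matrix(base, design10, layer=LAYER_PROTEIN)
    p = de.welch_t_test(m)
    assert ((p >= 0) & (p <= 1)).all()
    shifted = base.copy()
    shifted[0, :5] *= 2**6  # strong case-side shift
    p2 = de.welch_t_test(make_matrix(shifted, design10, layer=LAYER_PROTEIN))
    assert p2.iloc[0] < 0.001


def test_de_test_requires_two_samples_per_group(make_matrix):
    from pashub.models import CASE, CONTROL, SampleDesign

    design = SampleDesign(("a", "b", "c"), (CASE, CONTROL, CONTROL))
    m = make_matrix(np.ones((3, 3)), design)
    with pytest.raises(ValueError, match="2 samples"):
        de.de_test(m)


# ------------------------------------------------------------------- BH
def test_bh_hand_computed_step_up():
    fdr = de.bh_adjust(pd.Series([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(fdr.to_numpy(), [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_single_and_degenerate():
    assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
    np.testing.assert_allclose(de.bh_adjust(np.ones(5)).to_numpy(), np.ones(5))
    with pytest.raises(ValueError):
        de.bh_adjust(np.array([0.5, 1.5]))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_dominates_raw_p_after_sorting(pvals):
    p = np.sort(np.asarray(pvals))
    fdr = np.sort(de.bh_adjust(p).to_numpy())
    assert (fdr >= p - 1e-12).all()
    assert ((fdr >= 0) & (fdr <= 1)).all()


# ------------------------------------------------------------------ calls
def test_call_differential_boundary():
    lfc = pd.Series({"a": 0.60, "b": 0.50, "c": -0.60})
    fdr = pd.Series({"a": 0.04, "b": 0.04, "c": 0.04})
    res = de.call_differential(lfc, fdr).set_index("gene_id")
    assert bool(res.loc["a", "significant"]) and res.loc["a", "direction"] == "up"
    assert not bool(res.loc["b", "significant"])  # 0.50 < log2(1.5) ~ 0.585
    assert bool(res.loc["c", "significant"]) and res.loc["c", "direction"] == "down"
    with pytest.raises(ValueError, match="positive"):
        de.call_differential(lfc, fdr, fc_threshold=0.0)


def test_published_hub_genes_are_significant_in_both_layers():
    """Every printed (log2FC, FDR) hub pair passes the study thresholds."""
    ref = load_reference_hub_genes()
    for layer in ("mrna", "protein"):
        res = de.call_differential(
            ref.set_index("gene_id")[f"log2fc_{layer}"],
            ref.set_index("gene_id")[f"fdr_{layer}"],
        )
        assert res["significant"].all()


def test_significance_invariant_to_gene_order():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(40)]
    lfc = pd.Series(rng.normal(0, 2, 40), index=genes)
    p = pd.Series(rng.uniform(0, 1, 40), index=genes)
    res1 = de.call_differential(lfc, de.bh_adjust(p))
    perm = rng.permutation(genes)
    res2 = de.call_differential(lfc.loc[perm], de.bh_adjust(p.loc[perm]))
    s1 = set(res1.loc[res1["significant"], "gene_id"])
    s2 = set(res2.loc[res2["significant"], "gene_id"])
    assert s1 == s2
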