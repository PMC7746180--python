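"""Expression filtering, normalisation, NB exact test and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from oxpattern import (
    CANONICAL_COMPARISONS,
    CountMatrix,
    SimulationDesign,
    bh_adjust,
    call_de,
    estimate_size_factors,
    filter_expressed,
    nb_conditional_pvalue,
    nb_exact_test,
    simulate_counts,
)
from oxpattern.de import _pooled_mom_dispersion, nb_conditional_logpmf


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_conditional_pvalue(sum_a, n_a, sum_b, n_b, alpha):
    """Exhaustive enumeration of the conditional split distribution.

    Computes P(split) for every s = 0..t from products of scipy nbinom
    (or binom in the Poisson limit) pmfs, normalises, and sums outcomes no
    more probable than the observed one (same documented tie tolerance).
    """
    t = sum_a + sum_b
    s = np.arange(t + 1)
    if alpha <= 1e-8:
        probs = binom.pmf(s, t, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / alpha, n_b / alpha
        # any common NB success prob cancels in the conditional; use p=0.5
        w = nbinom.pmf(s, r_a, 0.5) * nbinom.pmf(t - s, r_b, 0.5)
        probs = w / w.sum()
    obs = probs[sum_a]
    return min(1.0, probs[probs <= obs * (1 + 1e-7)].sum())


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_keeps_gene_reaching_threshold_in_one_condition(tiny_counts):
    kept = filter_expressed(tiny_counts, threshold=10.0)
    assert "g_up" in kept.gene_ids and "g_flat" in kept.gene_ids
    # replicate means (9,9,9,10): max condition mean is exactly 10 -> kept
    assert "g_edge" in kept.gene_ids
    assert "g_zero" not in kept.gene_ids


def test_filter_idempotent_and_matches_brute_force():
    rng = np.random.default_rng(7)
    design = SimulationDesign(n_genes=500, baseline_mean=12.0, dispersion=0.3,
                              effect_logfc=0.0, seed=3)
    cm, _ = simulate_counts(design)
    kept = filter_expressed(cm, 10.0)
    # independent per-gene recomputation
    conds = cm.conditions()
    expected = []
    for g in cm.gene_ids:
        means = [cm.counts.loc[g, cm.condition_columns(*c)].mean() for c in conds]
        if max(means) >= 10.0:
            expected.append(g)
    assert list(kept.gene_ids) == expected
    again = filter_expressed(kept, 10.0)
    assert list(again.gene_ids) == list(kept.gene_ids)


def test_filter_empty_result_warns(tiny_counts):
    with pytest.warns(UserWarning):
        out = filter_expressed(tiny_counts, threshold=1e9)
    assert len(out.gene_ids) == 0


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identity_and_scale(tiny_counts):
    cm = filter_expressed(tiny_counts, 10.0)
    # identical columns -> all factors 1
    same = CountMatrix(
        pd.DataFrame(
            np.tile(cm.counts.iloc[:, :1].to_numpy(), (1, 8)),
            index=cm.counts.index, columns=cm.counts.columns,
        ),
        cm.samples,
    )
    assert np.allclose(estimate_size_factors(same), 1.0)
    # doubling one column doubles its factor relative to the rest
    doubled = same.counts.copy()
    doubled.iloc[:, 0] *= 2
    f = estimate_size_factors(CountMatrix(doubled, cm.samples))
    assert f.iloc[0] / f.iloc[1] == pytest.approx(2.0)


def test_size_factors_match_direct_median_of_ratios():
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(rng.integers(1, 500, size=(120, 6)),
                          index=[f"g{i}" for i in range(120)],
                          columns=[f"s{j}" for j in range(6)])
    samples = pd.DataFrame(
        {"genotype": ["WT"] * 3 + ["C3S"] * 3,
         "treatment": ["basal", "oxidation", "basal"] * 2,
         "replicate": [1, 1, 2, 1, 1, 2]},
        index=counts.columns.rename("sample"),
    )
    f = estimate_size_factors(CountMatrix(counts, samples))
    mat = counts.to_numpy(float)
    geo = np.exp(np.mean(np.log(mat), axis=1))
    expected = [np.median(mat[:, j] / geo) for j in range(6)]
    assert np.allclose(f.to_numpy(), expected, rtol=1e-12)


def test_size_factors_invariances():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(rng.integers(1, 200, size=(60, 4)),
                          index=[f"g{i}" for i in range(60)],
                          columns=list("abcd"))
    samples = pd.DataFrame(
        {"genotype": ["WT", "WT", "C3S", "C3S"],
         "treatment": ["basal", "oxidation"] * 2, "replicate": [1, 1, 1, 1]},
        index=counts.columns.rename("sample"),
    )
    f1 = estimate_size_factors(CountMatrix(counts, samples))
    shuffled = counts.sample(frac=1.0, random_state=1)
    f2 = estimate_size_factors(CountMatrix(shuffled, samples))
    assert np.allclose(f1, f2)
    # the per-gene geometric mean scales with the counts, so the
    # median-of-ratios factors are invariant under global rescaling;
    # scaling a single sample scales only that sample's factor
    f3 = estimate_size_factors(CountMatrix(counts * 3, samples))
    assert np.allclose(f3, f1)
    one_scaled = counts.copy()
    one_scaled["a"] *= 4
    f4 = estimate_size_factors(CountMatrix(one_scaled, samples))
    assert f4["a"] / f4["b"] == pytest.approx(4 * f1["a"] / f1["b"])


def test_size_factors_error_without_common_gene():
    counts = pd.DataFrame([[0, 5], [5, 0]], index=["g1", "g2"], columns=["a", "b"])
    samples = pd.DataFrame(
        {"genotype": ["WT", "C3S"], "treatment": ["basal", "basal"],
         "replicate": [1, 1]}, index=counts.columns.rename("sample"))
    with pytest.raises(ValueError, match="nonzero"):
        estimate_size_factors(CountMatrix(counts, samples))


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def test_identical_groups_give_p_one():
    assert nb_conditional_pvalue(50, 2, 50, 2, 0.1) == pytest.approx(1.0)


@pytest.mark.parametrize("alpha", [0.0, 0.05, 0.1, 0.5, 2.0])
@pytest.mark.parametrize("total", [1, 4, 10, 23])
def test_conditional_pvalue_matches_enumeration(alpha, total):
    for s in range(total + 1):
        mine = nb_conditional_pvalue(s, 2, total - s, 2, alpha)
        oracle = oracle_conditional_pvalue(s, 2, total - s, 2, alpha)
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_poisson_limit_equals_conditional_binomial():
    # dispersion at the floor -> conditional binomial by direct enumeration
    for s in range(11):
        mine = nb_conditional_pvalue(s, 2, 10 - s, 2, 1e-8)
        oracle = oracle_conditional_pvalue(s, 2, 10 - s, 2, 0.0)
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_conditional_pvalue_unequal_group_sizes():
    for s in range(16):
        mine = nb_conditional_pvalue(s, 1, 15 - s, 3, 0.2)
        oracle = oracle_conditional_pvalue(s, 1, 15 - s, 3, 0.2)
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_conditional_logpmf_normalises():
    lp = nb_conditional_logpmf(40, 2, 2, 0.3)
    assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-12)


def test_pooled_dispersion_floor_and_pooling():
    a = np.array([10.0, 10.0])
    assert _pooled_mom_dispersion(a, a, 1e-8) == 1e-8  # var < mean -> floored
    b = np.array([50.0, 150.0])  # var 5000, mean 100 -> alpha 0.49
    assert _pooled_mom_dispersion(b, b, 1e-8) == pytest.approx(0.49)


def test_nb_exact_test_table_structure(tiny_counts):
    cm = filter_expressed(tiny_counts, 10.0)
    res = nb_exact_test(cm, CANONICAL_COMPARISONS[0])
    assert list(res.columns) == ["gene_id", "mean_a", "mean_b", "logfc", "p"]
    assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
    # the planted 8x gene must be far more significant than the flat gene
    assert res.loc["g_up", "p"] < 1e-3 < res.loc["g_flat", "p"]
    assert res.loc["g_up", "logfc"] == pytest.approx(3.0, abs=0.3)


def test_null_pvalues_calibrated():
    """Fraction of p < 0.05 on null data within [0.03, 0.07] at 2000 genes."""
    design = SimulationDesign(n_genes=2000, effect_logfc=0.0, dispersion=0.05,
                              baseline_mean=100.0, seed=42)
    cm, _ = simulate_counts(design)
    cm = filter_expressed(cm, 10.0)
    res = nb_exact_test(cm, CANONICAL_COMPARISONS[0])
    frac = (res["p"].to_numpy() < 0.05).mean()
    assert 0.03 <= frac <= 0.07


# ---------------------------------------------------------------------------
# BH and calling
# ---------------------------------------------------------------------------

def test_bh_hand_case():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_value_and_validation():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=200)
    assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms())
def test_bh_permutation_invariant_and_bounded(p, rnd):
    q = bh_adjust(p)
    assert (q >= np.asarray(p) - 1e-12).all()
    assert (q <= 1).all() and (q >= 0).all()
    idx = list(range(len(p)))
    rnd.shuffle(idx)
    q_perm = bh_adjust([p[i] for i in idx])
    assert np.allclose([q[i] for i in idx], q_perm)


def test_call_de_strict_thresholds():
    res = pd.DataFrame({
        "gene_id": ["a", "b", "c"],
        "mean_a": [1, 1, 1], "mean_b": [2, 2, 2],
        "logfc": [1.5, 0.8, 2.0],
        "p": [0.001, 0.0001, 0.05],
    }).set_index("gene_id", drop=False)
    out = call_de(res)
    # q = BH(p): a->0.0015, b->0.0003, c->0.05
    assert bool(out.loc["a", "significant"])          # q<0.05 and |lfc|>1
    assert not bool(out.loc["b", "significant"])      # fails |logFC| > 1
    assert not bool(out.loc["c", "significant"])      # q == 0.05 not < 0.05
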