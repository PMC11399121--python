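import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lnctarget import (
    CountMatrix,
    bh_adjust,
    de_test,
    filter_low_counts,
    group_fold_change,
    nanostring_normalize,
    size_factors,
)
from lnctarget.synthetic import SimCountModel, simulate_counts


def make_cm(counts: np.ndarray, n_ctrl: int, n_kd: int, genes=None) -> CountMatrix:
    names = [f"control_{i+1}" for i in range(n_ctrl)] + [
        f"knockdown_{i+1}" for i in range(n_kd)
    ]
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=genes, columns=names)
    cond = pd.Series({c: c.rsplit("_", 1)[0] for c in names})
    return CountMatrix(df, cond)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def test_size_factors_identical_samples():
    cm = make_cm(np.tile([[10], [20], [30]], (1, 4)), 2, 2)
    assert np.allclose(size_factors(cm), 1.0)


def test_size_factors_proportional_samples_closed_form():
    base = np.array([[10.0], [100.0], [50.0]])
    counts = np.hstack([base, 2 * base])
    cm = make_cm(counts, 1, 1)
    f = size_factors(cm).to_numpy()
    assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_match_bruteforce_median_of_ratios(rng):
    counts = rng.integers(1, 2000, size=(50, 4)).astype(float)
    cm = make_cm(counts, 2, 2)
    f = size_factors(cm).to_numpy()
    geo = np.exp(np.log(counts).mean(axis=1))
    brute = np.array([np.median(counts[:, j] / geo) for j in range(4)])
    brute /= np.exp(np.mean(np.log(brute)))
    assert np.allclose(f, brute)


def test_size_factors_fallback_warns():
    counts = np.array([[0, 5], [3, 0]], dtype=float)
    cm = make_cm(counts, 1, 1)
    with pytest.warns(UserWarning, match="total-count"):
        f = size_factors(cm)
    assert np.allclose(np.exp(np.mean(np.log(f))), 1.0)


# ---------------------------------------------------------------------------
# low-count filter
# ---------------------------------------------------------------------------


def test_filter_low_counts_thresholds():
    counts = np.array([[1, 1, 1, 2], [2, 3, 2, 3], [5, 4, 3, 3]])  # totals 5,10,15
    cm = make_cm(counts, 2, 2)
    assert len(filter_low_counts(cm, 0).counts) == 3  # identity
    kept = filter_low_counts(cm, 10)
    assert list(kept.counts.index) == ["g1", "g2"]
    zeros = make_cm(np.zeros((1, 4), dtype=int), 2, 2)
    assert len(filter_low_counts(zeros, 10).counts) == 0


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def test_bh_hand_examples():
    assert bh_adjust([0.05]) == pytest.approx([0.05])
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_matches_statsmodels_on_random_vectors(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(1000):
        p = rng.random(int(rng.integers(1, 60)))
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_properties(p):
    out = bh_adjust(p)
    p = np.asarray(p)
    assert (out >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(out[order]) >= -1e-15).all()


def test_bh_adding_unit_p_never_decreases_others(rng):
    p = rng.random(20)
    base = bh_adjust(p)
    ext = bh_adjust(np.append(p, 1.0))[:-1]
    assert (ext >= base - 1e-15).all()


# ---------------------------------------------------------------------------
# NB differential test
# ---------------------------------------------------------------------------


def test_de_null_by_symmetry():
    counts = np.tile([[100], [50]], (1, 6))
    cm = make_cm(counts, 3, 3)
    res = de_test(cm)
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["p"], 1.0)
    assert (res["direction"] == "ns").all()


def test_de_requires_two_replicates():
    cm = make_cm(np.ones((3, 3), dtype=int), 1, 2)
    with pytest.raises(ValueError, match="replicates"):
        de_test(cm)


def test_de_label_swap_negates_log2fc(rng):
    counts = rng.integers(1, 500, size=(40, 6))
    a = de_test(make_cm(counts, 3, 3))
    swapped = counts[:, [3, 4, 5, 0, 1, 2]]
    b = de_test(make_cm(swapped, 3, 3))
    assert np.allclose(a["log2fc"], -b["log2fc"])
    assert np.allclose(a["p"], b["p"])


def test_de_planted_effect_recovered(rng):
    # planted log2FC = 2 at mu = 1000, alpha = 0.01, 5 vs 5, 200 genes
    n_genes = 200
    model = SimCountModel(
        baseline_mean=np.full(n_genes, 1000.0),
        dispersion=np.full(n_genes, 0.01),
        replicates_per_group=5,
        library_size_factors=np.ones(10),
    )
    genes = [f"g{i}" for i in range(n_genes)]
    cm = simulate_counts(genes, model, {g: 2.0 for g in genes}, rng)
    # every gene carries the effect, so fix unit size factors: the test
    # measures fold-change estimation, not normalization
    unit = pd.Series(1.0, index=cm.counts.columns)
    res = de_test(cm, factors=unit)
    assert 1.9 <= res["log2fc"].mean() <= 2.1


def test_de_log2fc_bias_shrinks_with_replicates(rng):
    biases = []
    for n in (3, 10, 50):
        n_genes = 300
        model = SimCountModel(
            baseline_mean=np.full(n_genes, 500.0),
            dispersion=np.full(n_genes, 0.05),
            replicates_per_group=n,
            library_size_factors=np.ones(2 * n),
        )
        genes = [f"g{i}" for i in range(n_genes)]
        cm = simulate_counts(genes, model, {g: 1.0 for g in genes}, rng)
        unit = pd.Series(1.0, index=cm.counts.columns)
        res = de_test(cm, factors=unit)
        biases.append(abs(res["log2fc"].mean() - 1.0))
    assert biases[2] < 0.03
    assert biases[2] <= biases[0] + 0.02


# ---------------------------------------------------------------------------
# NanoString normalization + panel fold change
# ---------------------------------------------------------------------------


def panel(rng=None, scale=None):
    data = np.array(
        [
            [100.0, 100, 100, 100],  # POS1
            [400.0, 400, 400, 400],  # POS2
            [50.0, 50, 50, 50],  # HK1 (low CV)
            [60.0, 80, 40, 60],  # HK2 (high CV)
            [55.0, 55, 55, 55],  # HK3 (low CV)
            [10.0, 20, 30, 40],  # target
        ]
    )
    if scale is not None:
        data = data * scale
    return pd.DataFrame(
        data,
        index=["POS1", "POS2", "HK1", "HK2", "HK3", "T1"],
        columns=["s1", "s2", "s3", "s4"],
    )


def test_nanostring_identity_when_samples_equal():
    df = panel()
    df.loc["T1"] = 25.0
    df.loc["HK2"] = 60.0
    norm, chosen = nanostring_normalize(df, ["POS1", "POS2"], ["HK1", "HK2", "HK3"], k=2)
    assert np.allclose(norm.to_numpy(), df.to_numpy())
    assert chosen == ["HK1", "HK2"]  # all CVs tie at 0; stable candidate order


def test_nanostring_lowest_cv_candidates_chosen():
    # CVs: HK1 = 0, HK2 > 0, HK3 = 0 -> first and third picked at k=2
    _, chosen = nanostring_normalize(
        panel(), ["POS1", "POS2"], ["HK1", "HK2", "HK3"], k=2
    )
    assert chosen == ["HK1", "HK3"]


def test_nanostring_scaled_sample_restored():
    df = panel(scale=np.array([1.0, 1.0, 1.0, 2.0]))
    norm, _ = nanostring_normalize(df, ["POS1", "POS2"], ["HK1", "HK3"], k=2)
    # the x2 sample (controls included) gets factor 1/2 relative to the
    # others: normalized counts match the unscaled panel up to one global
    # constant
    ratio = norm.to_numpy() / panel().to_numpy()
    assert np.allclose(ratio, ratio[0, 0])
    assert np.allclose(norm.loc["POS1"], norm.loc["POS1"].iloc[0])


def test_nanostring_zero_control_errors():
    df = panel()
    df.loc["POS1", "s2"] = 0.0
    with pytest.raises(ValueError, match="positive-control"):
        nanostring_normalize(df, ["POS1", "POS2"], ["HK1", "HK3"], k=1)


def test_group_fold_change_hand_fixture():
    df = pd.DataFrame(
        {"c1": [10.0], "c2": [12.0], "d1": [20.0], "d2": [24.0]}, index=["g1"]
    )
    groups = pd.Series({"c1": "CTRL", "c2": "CTRL", "d1": "DM", "d2": "DM"})
    res = group_fold_change(df, groups)
    assert res["fold_change"].iloc[0] == pytest.approx(2.0)


def test_group_fold_change_null_and_t_oracle():
    df = pd.DataFrame(
        {
            "c1": [10.0, 5.0],
            "c2": [12.0, 6.0],
            "c3": [11.0, 7.0],
            "d1": [10.0, 9.0],
            "d2": [12.0, 10.0],
            "d3": [11.0, 11.0],
        },
        index=["gnull", "gup"],
    )
    groups = pd.Series({c: ("CTRL" if c.startswith("c") else "DM") for c in df.columns})
    res = group_fold_change(df, groups)
    assert res.loc[0, "fold_change"] == pytest.approx(1.0)
    assert res.loc[0, "t"] == pytest.approx(0.0)
    assert res.loc[0, "p"] == pytest.approx(1.0)
    # textbook pooled-variance two-sample t for gup
    x, y = np.array([9.0, 10, 11]), np.array([5.0, 6, 7])
    sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
    t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert res.loc[1, "t"] == pytest.approx(t_hand)
    from scipy import stats

    assert res.loc[1, "p"] == pytest.approx(2 * stats.t.sf(abs(t_hand), 4))


def test_group_fold_change_zero_reference_flagged():
    df = pd.DataFrame(
        {"c1": [0.0], "c2": [0.0], "d1": [5.0], "d2": [6.0]}, index=["g"]
    )
    groups = pd.Series({"c1": "CTRL", "c2": "CTRL", "d1": "DM", "d2": "DM"})
    res = group_fold_change(df, groups)
    assert res["fc_undefined"].iloc[0]
    assert np.isnan(res["fold_change"].iloc[0])
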