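"""Normalization tests: hand-computed examples, naive loop-based oracle
equivalence, frozen edgeR/DESeq2 reference values, and structural
invariances."""

import numpy as np
import pandas as pd
import pytest

from temponorm import (
    CountMatrix,
    METHODS,
    apply_factors,
    log2_offset,
    median_of_ratios_factors,
    normalize,
    normalize_cpm,
    normalize_median,
    normalize_total_count,
    quantile_normalize,
    tmm_factors,
    upper_quartile_factors,
)

from .naive import (
    naive_cpm,
    naive_median,
    naive_mor_sizes,
    naive_quantile,
    naive_tc,
    naive_tmm_factors,
    naive_uq_factors,
)


def cm(rows, samples=None):
    return CountMatrix(pd.DataFrame(rows, columns=samples))


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------


def test_total_count_hand_example():
    counts = cm([[10, 30]])
    out = normalize_total_count(counts)
    np.testing.assert_allclose(out.values.to_numpy(), [[20.0, 20.0]])


def test_total_count_identity_under_equal_depths():
    counts = cm([[5, 5], [7, 7]])
    out = normalize_total_count(counts)
    np.testing.assert_allclose(out.values.to_numpy(), counts.values.to_numpy())


def test_total_count_column_sums_equal_mean_library():
    counts = cm([[3, 10, 2], [7, 30, 8]])
    out = normalize_total_count(counts)
    np.testing.assert_allclose(
        out.values.sum(axis=0), counts.library_sizes.mean()
    )


def test_cpm_hand_example_and_column_sums():
    counts = cm([[250], [750]])
    out = normalize_cpm(counts)
    np.testing.assert_allclose(out.values.to_numpy().ravel(), [250000.0, 750000.0])
    counts2 = cm([[3, 10, 2], [7, 30, 8]])
    np.testing.assert_allclose(normalize_cpm(counts2).values.sum(axis=0), 1e6)


def test_median_hand_example_and_scale_cancellation():
    counts = cm([[1, 5], [2, 10], [3, 15]])
    out = normalize_median(counts)
    np.testing.assert_allclose(
        out.values.to_numpy()[:, 0], np.array([0.5, 1.0, 1.5]) * 1e6
    )
    # scaling a sample by c leaves its normalized column unchanged
    np.testing.assert_allclose(
        out.values.to_numpy()[:, 1], out.values.to_numpy()[:, 0]
    )


def test_quantile_hand_example():
    counts = cm([[1, 4], [2, 5], [3, 6]])
    out = quantile_normalize(counts)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out.values.to_numpy(), expected)


def test_quantile_tie_rule():
    """Tied entries get the mean of the reference quantiles they span."""
    counts = cm([[1, 2], [1, 4], [3, 6]])
    out = quantile_normalize(counts)
    # sorted columns (1,1,3) and (2,4,6) -> reference (1.5, 2.5, 4.5)
    np.testing.assert_allclose(out.values.to_numpy()[:, 0], [2.0, 2.0, 4.5])
    np.testing.assert_allclose(out.values.to_numpy()[:, 1], [1.5, 2.5, 4.5])


def test_quantile_permutation_symmetry():
    rng = np.random.default_rng(3)
    col = rng.permutation(np.arange(1, 21))
    counts = cm(np.column_stack([col, rng.permutation(col)]))
    out = quantile_normalize(counts).values.to_numpy()
    assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]))


def test_mor_hand_example():
    counts = cm([[2, 8], [2, 8]])
    sf = median_of_ratios_factors(counts)
    np.testing.assert_allclose(sf.factors.to_numpy(), [0.5, 2.0])


def test_log2_offset_examples():
    vals = pd.DataFrame([[0.0, 7.0]])
    np.testing.assert_allclose(log2_offset(vals, 1.0).to_numpy(), [[0.0, 3.0]])
    np.testing.assert_allclose(
        log2_offset(pd.DataFrame([[7.5]]), 0.5).to_numpy(), [[3.0]]
    )
    with pytest.raises(ValueError, match="offset"):
        log2_offset(vals, 0.0)


# ---------------------------------------------------------------------------
# factor-method symmetry and depth invariance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "factor_fn", [upper_quartile_factors, tmm_factors, median_of_ratios_factors]
)
def test_identical_samples_give_unit_factors(factor_fn):
    counts = cm([[5, 5, 5], [9, 9, 9], [2, 2, 2], [14, 14, 14]])
    np.testing.assert_allclose(factor_fn(counts).factors.to_numpy(), 1.0)


@pytest.mark.parametrize("factor_fn", [upper_quartile_factors, tmm_factors])
def test_pure_depth_change_gives_unit_factors(factor_fn):
    rng = np.random.default_rng(1)
    a = rng.integers(1, 200, 40)
    counts = cm(np.column_stack([a, 3 * a]))
    np.testing.assert_allclose(
        factor_fn(counts).factors.to_numpy(), [1.0, 1.0], atol=1e-12
    )


@pytest.mark.parametrize("factor_fn", [upper_quartile_factors, tmm_factors])
def test_factors_have_unit_geometric_mean(factor_fn, random_counts):
    f = factor_fn(random_counts(seed=7)).factors.to_numpy()
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_depth_rescaling_leaves_normalized_sample_unchanged(random_counts):
    """Multiplying one sample's counts by c cancels in UQ exactly and in TMM
    up to the count-level precision of its gene weights."""
    counts = random_counts(seed=5)
    scaled = counts.values.copy()
    scaled.iloc[:, 2] = scaled.iloc[:, 2] * 3
    scaled = CountMatrix(scaled)

    uq_a = apply_factors(counts, upper_quartile_factors(counts)).values
    uq_b = apply_factors(scaled, upper_quartile_factors(scaled)).values
    np.testing.assert_allclose(uq_a.to_numpy(), uq_b.to_numpy(), rtol=1e-12)

    tmm_a = apply_factors(counts, tmm_factors(counts)).values
    tmm_b = apply_factors(scaled, tmm_factors(scaled)).values
    np.testing.assert_allclose(tmm_a.to_numpy(), tmm_b.to_numpy(), rtol=2e-2)


def test_mor_scale_equivariance(random_counts):
    counts = random_counts(n_genes=20, n_samples=4, seed=9)
    vals = counts.values + 1  # keep all-positive so every gene contributes
    base = median_of_ratios_factors(CountMatrix(vals)).factors
    scaled = vals.copy()
    scaled.iloc[:, 1] = scaled.iloc[:, 1] * 5
    after = median_of_ratios_factors(CountMatrix(scaled)).factors
    # relative sizes: the scaled sample's size grows 5x against every other
    for other in [0, 2, 3]:
        ratio_before = base.iloc[1] / base.iloc[other]
        ratio_after = after.iloc[1] / after.iloc[other]
        assert ratio_after == pytest.approx(5 * ratio_before, rel=1e-9)


def test_apply_factors_neutral_paths(random_counts):
    counts = random_counts(seed=2)
    sf = upper_quartile_factors(counts)
    sf.factors[:] = 1.0
    sf.effective_library_sizes = counts.library_sizes.astype(float)
    np.testing.assert_allclose(
        apply_factors(counts, sf).values.to_numpy(),
        normalize_cpm(counts).values.to_numpy(),
    )
    mor = median_of_ratios_factors(counts)
    mor.factors[:] = 1.0
    mor.effective_library_sizes[:] = 1.0
    np.testing.assert_allclose(
        apply_factors(counts, mor).values.to_numpy(),
        counts.values.to_numpy(),
    )


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_methods_match_naive_oracles(random_counts, seed):
    """Every method agrees with an independent loop-based implementation of
    its printed description on random 30 x 6 matrices."""
    counts = random_counts(n_genes=30, n_samples=6, seed=seed)
    x = counts.values.to_numpy()
    np.testing.assert_allclose(
        normalize(counts, "tc").values.to_numpy(), naive_tc(x), atol=1e-10
    )
    np.testing.assert_allclose(
        normalize(counts, "cpm").values.to_numpy(), naive_cpm(x), atol=1e-10
    )
    np.testing.assert_allclose(
        normalize(counts, "median").values.to_numpy(), naive_median(x), atol=1e-10
    )
    np.testing.assert_allclose(
        normalize(counts, "quantile").values.to_numpy(),
        naive_quantile(x),
        atol=1e-10,
    )
    np.testing.assert_allclose(
        upper_quartile_factors(counts).factors.to_numpy(),
        naive_uq_factors(x),
        atol=1e-10,
    )
    np.testing.assert_allclose(
        tmm_factors(counts).factors.to_numpy(), naive_tmm_factors(x), atol=1e-10
    )
    np.testing.assert_allclose(
        median_of_ratios_factors(counts).factors.to_numpy(),
        naive_mor_sizes(x),
        atol=1e-10,
    )


def test_factor_methods_match_reference_implementations(oracle_counts):
    """Frozen cross-check values from edgeR::calcNormFactors (upperquartile
    and TMM) and DESeq2::estimateSizeFactors on the fixture matrix."""
    edger_uq = [0.9683361624, 1.0410426615, 0.9803905221, 1.0118268926]
    edger_tmm = [0.9984516039, 0.9987258302, 1.0029929315, 0.9998361302]
    deseq2_mor = [0.9358260986, 0.4715723668, 1.8705703883, 1.2308781831]
    np.testing.assert_allclose(
        upper_quartile_factors(oracle_counts).factors.to_numpy(),
        edger_uq,
        atol=1e-9,
    )
    np.testing.assert_allclose(
        tmm_factors(oracle_counts).factors.to_numpy(), edger_tmm, atol=1e-9
    )
    np.testing.assert_allclose(
        median_of_ratios_factors(oracle_counts).factors.to_numpy(),
        deseq2_mor,
        atol=1e-9,
    )


# ---------------------------------------------------------------------------
# ordering invariances and errors
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", METHODS)
def test_gene_order_invariance_and_sample_equivariance(method, random_counts):
    counts = random_counts(seed=4)
    rng = np.random.default_rng(0)
    gperm = rng.permutation(counts.gene_ids)
    sperm = rng.permutation(counts.sample_ids)
    shuffled = CountMatrix(counts.values.loc[gperm, sperm])
    a = normalize(counts, method).values
    b = normalize(shuffled, method).values
    pd.testing.assert_frame_equal(
        a.loc[gperm, sperm], b, check_like=False, rtol=1e-12
    )


def test_error_messages_name_offenders():
    with pytest.raises(ValueError, match="s_bad"):
        normalize_total_count(
            CountMatrix(pd.DataFrame({"s_ok": [1, 2], "s_bad": [0, 0]}))
        )
    with pytest.raises(ValueError, match="zero median"):
        normalize_median(
            CountMatrix(pd.DataFrame({"a": [0, 0, 5], "b": [1, 2, 3]}))
        )
    with pytest.raises(ValueError, match=">= 2 samples"):
        quantile_normalize(CountMatrix(pd.DataFrame({"a": [1, 2]})))
    with pytest.raises(ValueError, match="sample set"):
        counts = CountMatrix(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))
        other = CountMatrix(pd.DataFrame({"x": [1, 2], "y": [3, 4]}))
        apply_factors(counts, upper_quartile_factors(other))
    with pytest.raises(ValueError, match="positive counts"):
        median_of_ratios_factors(
            CountMatrix(pd.DataFrame({"a": [1, 0], "b": [0, 1]}))
        )


def test_unknown_method_rejected(random_counts):
    with pytest.raises(ValueError, match="unknown"):
        normalize(random_counts(), "rma")
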