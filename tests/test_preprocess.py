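"""Background correction, masking, normalizers, rescaling, averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircodereg import preprocess as pp


# ---- MBC ------------------------------------------------------------------

def test_mbc_exact_powers_of_two():
    out, assumed = pp.background_correct_mbc(np.array([[1024.0]]),
                                             np.array([[4.0]]))
    assert out[0, 0] == pytest.approx(8.0)
    assert not assumed


def test_mbc_equal_channels_give_zero():
    out, _ = pp.background_correct_mbc(np.array([[7.0]]), np.array([[7.0]]))
    assert out[0, 0] == 0.0


def test_mbc_nonpositive_cells_become_nan():
    fg = np.array([[0.0, 4.0], [2.0, -1.0]])
    bg = np.array([[1.0, 0.0], [1.0, 1.0]])
    out, _ = pp.background_correct_mbc(fg, bg)
    assert np.isnan(out[0, 0]) and np.isnan(out[0, 1]) and np.isnan(out[1, 1])
    assert out[1, 0] == 1.0


def test_mbc_matches_scalar_loop(rng):
    fg = rng.uniform(0.5, 100, (5, 4))
    bg = rng.uniform(0.5, 10, (5, 4))
    out, _ = pp.background_correct_mbc(fg, bg)
    for i in range(5):
        for j in range(4):
            assert out[i, j] == pytest.approx(np.log2(fg[i, j] / bg[i, j]))


def test_mbc_without_background_flags_passthrough():
    out, assumed = pp.background_correct_mbc(np.array([[8.0, 0.0]]))
    assert assumed
    assert out[0, 0] == 3.0 and np.isnan(out[0, 1])


def test_mbc_shape_mismatch_fails():
    with pytest.raises(ValueError, match="shape"):
        pp.background_correct_mbc(np.ones((2, 2)), np.ones((2, 3)))


# ---- masking --------------------------------------------------------------

def test_mask_negative_keeps_zero_and_counts():
    out, n = pp.mask_negative(np.array([-1.0, 0.0, 2.0]))
    assert np.isnan(out[0]) and out[1] == 0.0 and out[2] == 2.0
    assert n == 1


def test_mask_negative_identity_on_positive(rng):
    m = rng.uniform(0, 5, (4, 3))
    out, n = pp.mask_negative(m)
    np.testing.assert_array_equal(out, m)
    assert n == 0


def test_mask_negative_count_matches_direct_census(rng):
    m = rng.normal(0, 1, (20, 10))
    _, n = pp.mask_negative(m)
    assert n == int((m < 0).sum())


# ---- quantile normalization ----------------------------------------------

def test_quantile_two_complete_columns_mean_profile():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    out = pp.quantile_normalize(m)
    np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])


def test_quantile_identity_on_identical_columns():
    col = np.array([5.0, 1.0, 3.0, 2.0])
    m = pd.DataFrame({"a": col, "b": col, "c": col})
    out = pp.quantile_normalize(m)
    np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), atol=1e-12)


def _quantile_oracle(arr):
    """Sort/average/unsort quantile normalization for complete matrices."""
    order = np.argsort(arr, axis=0)
    sorted_vals = np.sort(arr, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = ref
    return out


def test_quantile_matches_sort_average_unsort_oracle(rng):
    arr = rng.normal(0, 1, (6, 3))
    out = pp.quantile_normalize(pd.DataFrame(arr))
    np.testing.assert_allclose(out.to_numpy(), _quantile_oracle(arr),
                               atol=1e-12)


def test_quantile_sorted_values_identical_across_complete_columns(rng):
    arr = rng.normal(0, 2, (40, 6))
    out = pp.quantile_normalize(pd.DataFrame(arr)).to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, 6):
        np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)


def test_quantile_is_column_permutation_invariant(rng):
    arr = rng.normal(0, 1, (15, 4))
    m = pd.DataFrame(arr, columns=list("abcd"))
    out1 = pp.quantile_normalize(m)
    perm = ["c", "a", "d", "b"]
    out2 = pp.quantile_normalize(m[perm])
    pd.testing.assert_frame_equal(out1[perm], out2)


def test_quantile_preserves_nan_pattern(rng):
    arr = rng.normal(0, 1, (12, 4))
    arr[2, 1] = np.nan
    arr[5, 3] = np.nan
    out = pp.quantile_normalize(pd.DataFrame(arr)).to_numpy()
    np.testing.assert_array_equal(np.isnan(out), np.isnan(arr))


# ---- loess / rank-invariant ----------------------------------------------

@pytest.mark.parametrize("method", ["loess", "rank_invariant"])
def test_normalizer_near_identity_on_identical_columns(method):
    col = np.linspace(1.0, 9.0, 25)
    m = pd.DataFrame({"a": col, "b": col, "c": col})
    out = pp.normalize(m, method)
    np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), atol=1e-6)


@pytest.mark.parametrize("method", ["loess", "rank_invariant"])
def test_normalizer_removes_constant_offset(method, rng):
    base = np.sort(rng.uniform(2, 10, 60))
    m = pd.DataFrame({"a": base, "b": base + 1.5, "c": base - 0.5})
    out = pp.normalize(m, method)
    meds = out.median(axis=0)
    assert meds.max() - meds.min() < 0.35  # offsets largely removed


def test_unknown_method_lists_valid_ones():
    with pytest.raises(ValueError, match="quantile"):
        pp.normalize(pd.DataFrame(np.ones((3, 2))), "median_polish")


# ---- comparison report ----------------------------------------------------

def test_compare_normalizations_post_quantile_ks_zero(rng):
    arr = rng.normal(0, 1, (30, 4))
    normed = pp.quantile_normalize(pd.DataFrame(arr))
    report = pp.compare_normalizations(normed, methods=("quantile",))
    assert report.loc["none", "mean_ks_distance"] == pytest.approx(0.0)


def test_compare_normalizations_ranks_quantile_over_raw(rng):
    base = rng.normal(8, 1.5, 50)
    m = pd.DataFrame({
        "a": base + rng.normal(0, 0.2, 50),
        "b": base + 3.0 + rng.normal(0, 0.2, 50),  # strong batch offset
        "c": base - 2.0 + rng.normal(0, 0.2, 50),
    })
    report = pp.compare_normalizations(m, methods=("quantile",))
    assert (report.loc["quantile", "mean_ks_distance"]
            < report.loc["none", "mean_ks_distance"])


def test_compare_normalizations_deterministic(rng):
    m = pd.DataFrame(rng.normal(0, 1, (20, 3)))
    r1 = pp.compare_normalizations(m)
    r2 = pp.compare_normalizations(m)
    pd.testing.assert_frame_equal(r1, r2)


# ---- global-mean rescale --------------------------------------------------

def test_rescale_constant_matrix_to_ones():
    out = pp.global_mean_rescale(np.full((3, 3), 7.0))
    np.testing.assert_allclose(out, 1.0)


def test_rescale_direct_arithmetic():
    out = pp.global_mean_rescale(np.array([1.0, 3.0]))
    np.testing.assert_allclose(out, [0.5, 1.5])


def test_rescale_log2_exponentiate_identity(rng):
    """2^(log2(x/xbar)) equals x/xbar cellwise."""
    m = rng.uniform(0.5, 20, (6, 5))
    xbar = m.mean()
    out = pp.global_mean_rescale(m)
    np.testing.assert_allclose(out, 2 ** np.log2(m / xbar), rtol=1e-12)


def test_rescale_mean_is_one_and_idempotent(rng):
    m = rng.uniform(0.1, 50, (10, 8))
    m[2, 3] = np.nan
    out = pp.global_mean_rescale(m)
    assert np.nanmean(out) == pytest.approx(1.0, abs=1e-9)
    again = pp.global_mean_rescale(out)
    np.testing.assert_allclose(again[np.isfinite(again)],
                               out[np.isfinite(out)], atol=1e-9)


def test_rescale_rejects_nonpositive_mean():
    with pytest.raises(ValueError, match="positive"):
        pp.global_mean_rescale(np.array([1.0, -3.0]))


@given(st.lists(st.floats(min_value=0.01, max_value=1e4),
                min_size=2, max_size=30))
@settings(deadline=None, derandomize=True)
def test_rescale_mean_one_property(values):
    out = pp.global_mean_rescale(np.array(values))
    assert abs(np.nanmean(out) - 1.0) < 1e-9


# ---- replicate averaging --------------------------------------------------

def test_average_replicates_nan_ignoring_mean():
    m = pd.DataFrame([[2.0, 4.0], [4.0, np.nan]], index=["M", "M"],
                     columns=["s1", "s2"])
    out = pp.average_replicates(m)
    np.testing.assert_allclose(out.loc["M"], [3.0, 4.0])


def test_average_replicates_identity_without_duplicates(rng):
    m = pd.DataFrame(rng.normal(0, 1, (4, 3)), index=list("ABCD"))
    out = pp.average_replicates(m)
    pd.testing.assert_frame_equal(out, m.sort_index(), check_names=False)


def test_average_replicates_matches_scalar_loop(toy_matrix):
    out = pp.average_replicates(toy_matrix)
    for sym in set(toy_matrix.index):
        block = toy_matrix.loc[[sym]] if isinstance(
            toy_matrix.loc[sym], pd.Series) else toy_matrix.loc[sym]
        block = toy_matrix[toy_matrix.index == sym]
        for col in toy_matrix.columns:
            vals = [v for v in block[col] if np.isfinite(v)]
            expected = np.mean(vals) if vals else np.nan
            got = out.loc[sym, col]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


def test_average_replicates_all_nan_stays_nan():
    m = pd.DataFrame([[np.nan], [np.nan]], index=["M", "M"], columns=["s"])
    assert np.isnan(pp.average_replicates(m).loc["M", "s"])


def test_stage_sequence_validation():
    pp.validate_stage_sequence(["raw", "mbc", "masked", "normalized"])
    with pytest.raises(ValueError, match="order"):
        pp.validate_stage_sequence(["normalized", "mbc"])
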