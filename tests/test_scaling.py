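"""Median scaling, Z-scores and discriminator detection."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oryzabran import (
    AbundanceMatrix,
    ScaledMatrix,
    ValidationError,
    compute_zscores,
    find_discriminators,
    impute_missing,
    median_scale,
)


def row_matrix(*rows, missing=np.nan):
    df = pd.DataFrame(
        list(rows),
        index=[f"m{i}" for i in range(len(rows))],
        columns=[f"cv{j}" for j in range(len(rows[0]))],
    )
    return AbundanceMatrix(df)


# ---------------------------------------------------------------------------
# median_scale
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "row,expected",
    [
        ((2.0, 4.0, 6.0), (0.5, 1.0, 1.5)),
        ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
        ((1.0, 3.0, np.nan, 5.0, 7.0), (0.25, 0.75, np.nan, 1.25, 1.75)),
    ],
)
def test_median_scale_examples(row, expected):
    s = median_scale(row_matrix(row))
    np.testing.assert_allclose(s.values.iloc[0].to_numpy(), expected)


def test_median_scale_median_is_one_and_missing_preserved():
    ab = row_matrix((3.0, np.nan, 9.0, 27.0), (5.0, 5.0, np.nan, np.nan))
    s = median_scale(ab)
    assert np.allclose(s.values.median(axis=1, skipna=True), 1.0)
    assert s.values.isna().equals(ab.values.isna())


def test_median_scale_idempotent():
    rng = np.random.default_rng(5)
    vals = np.exp(rng.normal(size=(30, 7)))
    vals[rng.random(vals.shape) < 0.1] = np.nan
    vals[:, 0] = 1.0  # guarantee a present value per row
    ab = AbundanceMatrix(pd.DataFrame(vals, index=[f"m{i}" for i in range(30)]))
    once = median_scale(ab)
    twice = median_scale(once)
    pd.testing.assert_frame_equal(once.values, twice.values, atol=1e-9, rtol=0)


def test_median_scale_all_missing_row_named():
    df = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan]], index=["ok", "empty"])
    with pytest.raises(ValidationError, match="empty"):
        median_scale(ScaledMatrix(df))  # bypass AbundanceMatrix validation


def test_median_scale_zero_median_rejected():
    # majority-zero row: median 0 would put infinities everywhere downstream
    with pytest.raises(ValidationError, match="zero median"):
        median_scale(row_matrix((0.0, 0.0, 5.0)))


# ---------------------------------------------------------------------------
# impute_missing
# ---------------------------------------------------------------------------


def test_impute_policies():
    s = ScaledMatrix(pd.DataFrame([[0.5, np.nan, 1.5]], index=["m"], columns=list("abc")))
    filled = impute_missing(s, "min_impute")
    np.testing.assert_allclose(filled.values.loc["m"], [0.5, 0.5, 1.5])
    skipped = impute_missing(s, "skip")
    assert skipped.values.isna().to_numpy().sum() == 1
    # no-missing rows unchanged under either policy
    s2 = ScaledMatrix(pd.DataFrame([[0.5, 1.0, 1.5]], index=["m"], columns=list("abc")))
    for policy in ("min_impute", "skip"):
        pd.testing.assert_frame_equal(impute_missing(s2, policy).values, s2.values)
    with pytest.raises(ValueError):
        impute_missing(s, "zeros")


# ---------------------------------------------------------------------------
# compute_zscores
# ---------------------------------------------------------------------------


def test_zscore_hand_example_sample_sigma():
    s = ScaledMatrix(pd.DataFrame([[1.0, 1, 1, 1, 3]], index=["m"], columns=list("abcde")))
    z = compute_zscores(s, sigma_convention="sample")
    np.testing.assert_allclose(
        z.z.loc["m"], [-0.4472136, -0.4472136, -0.4472136, -0.4472136, 1.7888544], atol=1e-6
    )
    assert z.mu.loc["m"] == pytest.approx(1.4)
    assert z.sigma.loc["m"] == pytest.approx(0.8944272, abs=1e-6)


def test_zscore_row_mean_zero_sd_one():
    rng = np.random.default_rng(0)
    s = ScaledMatrix(pd.DataFrame(np.exp(rng.normal(size=(20, 17)))))
    z = compute_zscores(s, sigma_convention="sample")
    np.testing.assert_allclose(z.z.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.z.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_constant_row_flagged_and_zero():
    s = ScaledMatrix(pd.DataFrame([[1.0, 1, 1, 1]], index=["flat"], columns=list("abcd")))
    z = compute_zscores(s)
    assert z.constant_metabolites == ["flat"]
    np.testing.assert_array_equal(z.z.loc["flat"], 0.0)


def test_min_cultivars_exclusion_warns(caplog):
    df = pd.DataFrame(
        [[1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0]],
        index=["sparse", "dense"],
        columns=list("abcd"),
    )
    with caplog.at_level(logging.WARNING, logger="oryzabran.scaling"):
        z = compute_zscores(ScaledMatrix(df), min_cultivars=3)
    assert z.excluded_metabolites == ["sparse"]
    assert "sparse" in caplog.text
    assert list(z.z.index) == ["dense"]


def test_population_vs_sample_sigma():
    s = ScaledMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=list("abc")))
    zs = compute_zscores(s, sigma_convention="sample").z.loc["m"]
    zp = compute_zscores(s, sigma_convention="population").z.loc["m"]
    np.testing.assert_allclose(zp, zs * np.sqrt(3 / 2), atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    row=st.lists(st.floats(0.01, 100.0), min_size=5, max_size=17),
    factor=st.floats(0.01, 1000.0),
)
def test_zscore_invariant_to_positive_rescaling(row, factor):
    """Multiplying a metabolite's abundances by c > 0 leaves Z unchanged."""
    a = ScaledMatrix(pd.DataFrame([row], index=["m"]))
    b = ScaledMatrix(pd.DataFrame([[v * factor for v in row]], index=["m"]))
    za, zb = compute_zscores(a).z, compute_zscores(b).z
    if not za.loc["m"].isna().any():
        np.testing.assert_allclose(za.loc["m"], zb.loc["m"], atol=1e-7)


def test_single_outlier_bound_17_cultivars():
    """|Z| <= (c-1)/sqrt(c) ~= 3.880 for c = 17 under sample sigma."""
    rng = np.random.default_rng(123)
    vals = np.exp(rng.normal(size=(2000, 17)))
    # spike one random cell per row to force extremes
    vals[np.arange(2000), rng.integers(0, 17, 2000)] *= 1e6
    z = compute_zscores(ScaledMatrix(pd.DataFrame(vals)))
    bound = 16 / np.sqrt(17)
    assert np.nanmax(np.abs(z.z.to_numpy())) <= bound + 1e-9


# ---------------------------------------------------------------------------
# find_discriminators
# ---------------------------------------------------------------------------


def test_find_discriminators_basics():
    z = compute_zscores(
        ScaledMatrix(pd.DataFrame(np.ones((3, 5)), index=list("xyz"), columns=list("abcde")))
    )
    assert find_discriminators(z).n_entries == 0  # all-zero Z

    df = pd.DataFrame([[1.0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 50]], index=["m"])
    z2 = compute_zscores(ScaledMatrix(df))
    d = find_discriminators(z2)
    assert d.n_entries == 1
    entry = d.entries.iloc[0]
    assert entry["direction"] == "high" and entry["z_value"] > 2

    with pytest.raises(ValueError):
        find_discriminators(z2, threshold=0.0)


def test_threshold_monotonicity():
    rng = np.random.default_rng(9)
    z = compute_zscores(ScaledMatrix(pd.DataFrame(np.exp(rng.normal(size=(100, 17))))))
    sizes = [find_discriminators(z, threshold=t).n_entries for t in (1.0, 1.5, 2.0, 2.5, 3.0)]
    assert sizes == sorted(sizes, reverse=True)
    # entry sets are nested, not merely smaller
    lo = find_discriminators(z, threshold=1.5)
    hi = find_discriminators(z, threshold=2.5)
    lo_pairs = set(zip(lo.entries["metabolite_id"], lo.entries["cultivar_id"]))
    hi_pairs = set(zip(hi.entries["metabolite_id"], hi.entries["cultivar_id"]))
    assert hi_pairs <= lo_pairs


def test_strict_inequality_at_threshold():
    # a Z row with one cell exactly on the threshold
    z = pd.DataFrame([np.r_[np.full(9, -1 / 3), 3.0]], index=["m"])
    from oryzabran.scaling import ZScoreMatrix

    zm = ZScoreMatrix(z=z, mu=pd.Series([0.0], index=["m"]), sigma=pd.Series([1.0], index=["m"]))
    assert find_discriminators(zm, threshold=3.0).n_entries == 0  # |Z| == threshold excluded
    assert find_discriminators(zm, threshold=2.9).n_entries == 1
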