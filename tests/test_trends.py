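"""Binning, change points, folds, trends and correlations."""

import numpy as np
import pandas as pd
import pytest

from paleonts.features import FeatureProfile, SampleMeta
from paleonts.formulas import descriptor_frame, parse_formula
from paleonts.trends import (
    ChangePoint,
    ProxyRecord,
    bin_series,
    class_series,
    compare_groups,
    detect_change_point,
    detect_change_points,
    fold_change,
    proxy_correlation,
    trend_test,
    weighted_descriptor,
)
from conftest import make_binned


def _mk_profiles(intensity_rows, sample_ids, formulas=None):
    out = []
    for i, row in enumerate(intensity_rows):
        out.append(
            FeatureProfile(
                id=f"M{i}",
                mz=100.0,
                rt=5.0,
                formula=parse_formula(formulas[i]) if formulas else parse_formula("C4H6O4"),
                intensities=dict(zip(sample_ids, row)),
            )
        )
    return out


def test_bin_series_means_and_boundaries():
    samples = [
        SampleMeta("a", 0, 1801.0),
        SampleMeta("b", 0, 1803.0),
        SampleMeta("c", 0, 1805.0),  # exactly on an edge -> later bin
    ]
    profiles = _mk_profiles([[10.0, 30.0, 7.0]], ["a", "b", "c"])
    binned = bin_series(profiles, samples, bin_width=5, anchor_year=1800)
    assert list(binned.bin_years) == [1800, 1805]
    assert binned.matrix.iloc[0, 0] == 20.0
    assert binned.matrix.iloc[0, 1] == 7.0


def test_bin_series_missing_bins_are_nan():
    samples = [SampleMeta("a", 0, 1800.0), SampleMeta("b", 0, 1812.0)]
    profiles = _mk_profiles([[1.0, 2.0]], ["a", "b"])
    binned = bin_series(profiles, samples, bin_width=5, anchor_year=1800)
    assert np.isnan(binned.matrix.iloc[0, 1])  # 1805 bin empty
    with pytest.raises(ValueError):
        bin_series(profiles, [], 5)


def test_bin_count_for_default_record(default_binned):
    assert len(default_binned.bin_years) <= 37
    assert default_binned.bin_years[0] == 1800


def test_class_series_shares():
    binned = make_binned([[95.0, 95.0], [5.0, 5.0]], ids=["cho", "chno"])
    desc = descriptor_frame({"cho": parse_formula("C4H6O4"), "chno": parse_formula("C6H5NO3")})
    sums, bin_shares, total = class_series(binned, desc)
    assert total["CHO"] == pytest.approx(95.0)
    assert total["CHNO"] == pytest.approx(5.0)
    assert np.allclose(bin_shares.sum(axis=0), 100.0)


def test_weighted_descriptor_values():
    binned = make_binned([[10.0], [30.0]], ids=["a", "b"])
    desc = pd.DataFrame({"oc": [0.5, 1.0]}, index=["a", "b"])
    w = weighted_descriptor(binned, desc, "oc")
    assert w.values[0] == pytest.approx(0.875)
    # equal weights -> unweighted mean; single molecule -> identity
    eq = weighted_descriptor(make_binned([[7.0], [7.0]], ids=["a", "b"]), desc, "oc")
    assert eq.values[0] == pytest.approx(0.75)
    solo = weighted_descriptor(binned, desc, "oc", subset=["b"])
    assert solo.values[0] == pytest.approx(1.0)


def test_weighted_descriptor_scale_invariance_and_empty_bin():
    rng = np.random.default_rng(0)
    mat = rng.uniform(1, 10, (5, 4))
    desc = pd.DataFrame({"oc": rng.uniform(0.2, 1.0, 5)}, index=[f"M{i:03d}" for i in range(5)])
    w1 = weighted_descriptor(make_binned(mat), desc, "oc")
    w2 = weighted_descriptor(make_binned(mat * np.array([3.0, 0.5, 7.0, 1.0])), desc, "oc")
    assert np.allclose(w1.values, w2.values)
    lo = desc["oc"].min()
    hi = desc["oc"].max()
    assert np.all((w1.values >= lo) & (w1.values <= hi))
    zero = weighted_descriptor(make_binned(np.zeros((5, 2))), desc, "oc")
    assert np.isnan(zero.values).all()


def test_change_point_noiseless_step():
    s = pd.Series([1, 1, 1, 1, 2, 2, 2], index=1800 + 5 * np.arange(7), dtype=float)
    cp = detect_change_point(s)
    assert cp.year == 1820.0
    assert cp.significant


def test_change_point_constant_and_short():
    flat = pd.Series(np.ones(6), index=1800 + 5 * np.arange(6))
    cp = detect_change_point(flat)
    assert cp.sse_drop == 0.0 and not cp.significant
    with pytest.raises(ValueError):
        detect_change_point(pd.Series([1.0, 2.0, 3.0], index=[1800, 1805, 1810]))


def test_change_point_matches_naive_scan():
    """Cumulative-sum implementation equals a plain two-loop scan."""
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        x = rng.normal(0, 1, n)
        years = 1800.0 + 5 * np.arange(n)
        cp = detect_change_point(pd.Series(x, index=years))
        best_k, best_sse = None, np.inf
        for k in range(1, n):
            sse = ((x[:k] - x[:k].mean()) ** 2).sum() + ((x[k:] - x[k:].mean()) ** 2).sum()
            if sse < best_sse - 1e-12:
                best_k, best_sse = k, sse
        total = ((x - x.mean()) ** 2).sum()
        assert cp.year == years[best_k]
        assert cp.sse_drop == pytest.approx(total - best_sse, abs=1e-8)


def test_recursive_segmentation_finds_two_steps():
    years = 1800 + 5 * np.arange(30)
    x = np.concatenate([np.zeros(10), np.full(10, 3.0), np.full(10, 6.0)])
    cps = detect_change_points(pd.Series(x, index=years), penalty=0.5)
    assert [c.year for c in cps] == [1850.0, 1900.0]


def test_fold_change():
    years = 1800 + 5 * np.arange(8)
    s = pd.Series([10.0] * 4 + [14.0] * 4, index=years)
    assert fold_change(s, ChangePoint(1820.0, 1.0)) == pytest.approx(1.4)
    flat = pd.Series([10.0] * 8, index=years)
    assert fold_change(flat, ChangePoint(1820.0, 0.0)) == pytest.approx(1.0)
    zero_pre = pd.Series([0.0] * 4 + [5.0] * 4, index=years)
    assert np.isnan(fold_change(zero_pre, ChangePoint(1820.0, 1.0)))


def test_trend_test():
    years = np.arange(1800, 1900, 5, dtype=float)
    slope, p = trend_test(pd.Series(2.0 * years, index=years))
    assert slope == pytest.approx(2.0)
    assert p < 1e-10
    slope, p = trend_test(pd.Series(np.ones_like(years), index=years))
    assert slope == 0.0 and np.isnan(p)
    with pytest.raises(ValueError):
        trend_test(pd.Series([1.0, 2.0], index=[1800.0, 1805.0]))


def test_proxy_correlation_identity_and_sign():
    years = np.arange(1800, 1900, 5, dtype=float)
    vals = np.sin(years / 17.0)
    s = pd.Series(vals, index=years)
    proxy = ProxyRecord("p", tuple(years), tuple(vals))
    assert proxy_correlation(s, proxy) == pytest.approx(1.0)
    neg = ProxyRecord("n", tuple(years), tuple(-vals))
    assert proxy_correlation(s, neg) == pytest.approx(-1.0)
    short = ProxyRecord("s", (1800.0, 1805.0), (1.0, 2.0))
    with pytest.raises(ValueError):
        proxy_correlation(pd.Series(vals[:3], index=years[:3] + 400), short)


def test_proxy_interpolated_onto_bins():
    years = np.arange(1800.0, 1860.0, 5)
    s = pd.Series(np.linspace(0, 1, years.size), index=years)
    # coarse proxy at 20-year steps still correlates after interpolation
    proxy = ProxyRecord("coarse", (1800.0, 1820.0, 1840.0, 1860.0), (0.0, 1.0, 2.0, 3.0))
    assert proxy_correlation(s, proxy) == pytest.approx(1.0, abs=1e-9)


def test_compare_groups():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 40)
    assert compare_groups(a, a) == pytest.approx(1.0)
    b = rng.normal(5, 1, 40)
    p = compare_groups(a, b)
    assert p < 1e-10
    assert compare_groups(b, a) == pytest.approx(p)
    with pytest.raises(ValueError):
        compare_groups([1.0], [1.0, 2.0])
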