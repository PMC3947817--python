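"""LBP codes and variance-weighted histograms against brute-force oracles."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from veinverify.features_lbpv import (LBPParams, lbp_code, lbp_variance, lbp_code_map,
                                      lbp_variance_map, lbpv_histogram, build_lbpv_raw,
                                      fit_lbpv_stats, lbpv_sources)

P8 = LBPParams(P=8, R=1.0)


def oracle_ring(img, i, j, params):
    """Ring samples via scipy's bilinear resampler (independent path).

    Samples are rounded to 8 decimals, matching the library's tie-break
    for interpolated values that are mathematically equal to the center.
    """
    p = np.arange(params.P)
    a = 2 * np.pi * p / params.P
    rows = np.round(i - params.R * np.sin(a), 12)
    cols = np.round(j + params.R * np.cos(a), 12)
    return np.round(map_coordinates(img, [rows, cols], order=1), 8)


def oracle_code(img, i, j, params):
    ring = oracle_ring(img, i, j, params)
    return int(sum(int(g >= img[i, j]) << p for p, g in enumerate(ring)))


def oracle_var(img, i, j, params):
    ring = oracle_ring(img, i, j, params)
    u = ring.mean()
    return float(np.mean((ring - u) ** 2))


def oracle_histogram(img, params):
    """Literal double loop over pixels and codes: bin k sums VAR where code==k."""
    m = params.margin
    hist = np.zeros(params.n_codes)
    for i in range(m, img.shape[0] - m):
        for j in range(m, img.shape[1] - m):
            hist[oracle_code(img, i, j, params)] += oracle_var(img, i, j, params)
    return hist


def test_constant_image_codes_and_variance():
    img = np.full((10, 10), 0.4)
    codes = lbp_code_map(img, P8)
    assert np.all(codes == 2 ** 8 - 1)          # s(0) = 1 for every neighbour
    assert np.all(lbp_variance_map(img, P8) == 0.0)
    assert np.all(lbpv_histogram(img, P8) == 0.0)


def test_hand_worked_code_153():
    """Ring values [6,4,4,6,6,4,4,6] around center 5 set bits p=0,3,4,7:
    code 2^0 + 2^3 + 2^4 + 2^7 = 153. Corners are chosen so the bilinear
    diagonal samples fall on the stated side of the center."""
    img = np.array([[10.0, 4.0, 0.0],
                    [6.0, 5.0, 6.0],
                    [0.0, 4.0, 10.0]])
    assert lbp_code(img, (1, 1), P8) == 153
    assert lbp_code(img, (1, 1), P8) == oracle_code(img, 1, 1, P8)


def test_hand_worked_variance_integer_ring():
    """P=4 puts all neighbours on the integer grid: ring [4,6,4,6], mean 5,
    VAR = 1 by direct evaluation."""
    p4 = LBPParams(P=4, R=1.0)
    img = np.array([[0.0, 4.0, 0.0],
                    [6.0, 5.0, 4.0],
                    [0.0, 6.0, 0.0]])
    assert lbp_variance(img, (1, 1), p4) == pytest.approx(1.0, abs=1e-12)
    assert lbp_code(img, (1, 1), p4) == 12   # bits where ring >= 5: p=2,3


def test_pixel_outside_valid_region_rejected():
    img = np.zeros((8, 8))
    with pytest.raises(ValueError):
        lbp_code(img, (0, 3), P8)
    with pytest.raises(ValueError):
        lbpv_histogram(np.zeros((2, 2)), P8)


def test_gray_shift_invariance_and_scaling_covariance(rng):
    img = rng.integers(0, 256, size=(12, 12)).astype(float)
    assert np.array_equal(lbp_code_map(img, P8), lbp_code_map(img + 17.0, P8))
    # variance is homogeneous of degree 2, hence so is the histogram
    # (up to the 8-decimal interpolation snap, which is not scale-equivariant)
    assert np.allclose(lbpv_histogram(3.0 * img, P8), 9.0 * lbpv_histogram(img, P8),
                       rtol=1e-7, atol=1e-6)


def test_histogram_conservation(rng):
    for _ in range(5):
        img = rng.random((16, 16))
        hist = lbpv_histogram(img, P8)
        total = lbp_variance_map(img, P8).sum()
        assert hist.sum() == pytest.approx(total, rel=1e-9)
        assert np.all(hist >= 0)


def test_vectorized_matches_brute_force(rng):
    for _ in range(5):
        img = rng.integers(0, 256, size=(10, 10)).astype(float)
        m = P8.margin
        codes = lbp_code_map(img, P8)
        var = lbp_variance_map(img, P8)
        for i in range(m, 10 - m):
            for j in range(m, 10 - m):
                assert codes[i - m, j - m] == oracle_code(img, i, j, P8)
                assert var[i - m, j - m] == pytest.approx(oracle_var(img, i, j, P8),
                                                          rel=1e-9, abs=1e-12)
        assert np.allclose(lbpv_histogram(img, P8), oracle_histogram(img, P8),
                           rtol=1e-9, atol=1e-9)


def test_matches_skimage_reference(rng):
    """Independent library cross-check of the default LBP codes."""
    skimage = pytest.importorskip("skimage.feature")
    img = rng.integers(0, 256, size=(16, 16)).astype(float)
    ours = lbp_code_map(img, P8)
    theirs = skimage.local_binary_pattern(img, P=8, R=1.0, method="default")[1:-1, 1:-1]
    assert np.array_equal(ours, theirs)


def test_raw_vector_length_and_identity(rng):
    enhanced = rng.random((24, 24))
    ll1, ll2 = rng.random((8, 8)), rng.random((8, 8))
    rows = [lbpv_sources(enhanced, ll1, ll2, P8) for _ in range(3)]
    stats = fit_lbpv_stats(rows)
    v = build_lbpv_raw(enhanced, ll1, ll2, P8, stats)
    assert v.shape == (3 * 2 ** 8,)             # 768 for P=8
    assert np.array_equal(v, build_lbpv_raw(enhanced, ll1, ll2, P8, stats))


def test_constant_sources_give_znormed_zero_histograms(rng):
    # constant inputs: all three histograms are all-zero, so the raw vector
    # is exactly the Z-image of zero histograms under the fitted stats
    rows = [lbpv_sources(rng.random((16, 16)), rng.random((8, 8)),
                         rng.random((8, 8)), P8) for _ in range(4)]
    stats = fit_lbpv_stats(rows)
    const = np.full((16, 16), 0.3)
    v = build_lbpv_raw(const, np.full((8, 8), 1.0), np.full((8, 8), 2.0), P8, stats)
    from veinverify.features_wavelet import znorm_apply
    expected = np.concatenate([znorm_apply(np.zeros(256), stats[k])
                               for k in ("enhanced", "ll_db2", "ll_sym2")])
    assert np.allclose(v, expected, atol=1e-12)
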