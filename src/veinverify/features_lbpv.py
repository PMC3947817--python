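"""Local binary pattern variance (LBPV) features.

An LBP code compares P circular neighbours at radius R against the center
pixel: code = sum_p s(g_p - g_c) 2^p with s(x) = 1 for x >= 0.  Neighbour
p sits at (row, col) offset (-R sin(2 pi p / P), R cos(2 pi p / P)) and is
sampled by bilinear interpolation.  The LBPV histogram weights each pixel
by the variance of its ring samples instead of counting 1: bin k
accumulates VAR_{P,R} over all pixels whose code is k.  It is training
free and needs no quantization; total histogram mass equals the total
ring variance over the valid region.

The raw local descriptor of the pipeline concatenates three Z-normalized
LBPV histograms: of the enhanced image and of the two level-3 wavelet
approximation grids (each grid min-max scaled to [0, 1] first so the
variance weights are commensurate across sources).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from veinverify.synthgen import GrayImage
from veinverify.features_wavelet import ZNormStats, znorm_fit, znorm_apply

__all__ = ["LBPParams", "lbp_code", "lbp_variance", "lbp_code_map", "lbp_variance_map",
           "lbpv_histogram", "build_lbpv_raw", "fit_lbpv_stats", "lbpv_sources"]

SOURCE_ORDER = ("enhanced", "ll_db2", "ll_sym2")


@dataclass(frozen=True)
class LBPParams:
    """Circular neighbourhood: P neighbours at radius R (px), bilinear."""

    P: int = 8
    R: float = 1.0

    def __post_init__(self) -> None:
        if self.P < 4:
            raise ValueError("P must be >= 4")
        if self.R <= 0:
            raise ValueError("R must be positive")

    @property
    def n_codes(self) -> int:
        return 2 ** self.P

    @property
    def margin(self) -> int:
        return int(np.ceil(self.R))

    def offsets(self) -> np.ndarray:
        """(P, 2) array of (row, col) neighbour offsets."""
        p = np.arange(self.P)
        a = 2.0 * np.pi * p / self.P
        # snap to the grid where the circle hits integer coordinates
        return np.round(np.stack([-self.R * np.sin(a), self.R * np.cos(a)], axis=1), 12)


def _pixels(image: GrayImage | np.ndarray) -> np.ndarray:
    pix = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    if pix.ndim != 2:
        raise ValueError("expected a 2-D image")
    return pix.astype(float)


def _ring_samples(pix: np.ndarray, params: LBPParams) -> np.ndarray:
    """Bilinear ring samples over the valid region, shape (P, vr, vc)."""
    rows, cols = pix.shape
    m = params.margin
    if rows <= 2 * m or cols <= 2 * m:
        raise ValueError(f"image {pix.shape} too small for radius {params.R}")
    ii, jj = np.mgrid[m:rows - m, m:cols - m]
    out = np.empty((params.P,) + ii.shape)
    for p, (dy, dx) in enumerate(params.offsets()):
        y = ii + dy
        x = jj + dx
        y0 = np.floor(y).astype(int)
        x0 = np.floor(x).astype(int)
        wy = y - y0
        wx = x - x0
        y1 = np.minimum(y0 + 1, rows - 1)
        x1 = np.minimum(x0 + 1, cols - 1)
        # two-stage lerp: exact on constant neighbourhoods
        top = pix[y0, x0] + wx * (pix[y0, x1] - pix[y0, x0])
        bot = pix[y1, x0] + wx * (pix[y1, x1] - pix[y1, x0])
        out[p] = top + wy * (bot - top)
    # snap away 1-ulp interpolation fuzz: an interpolated sample that is
    # mathematically equal to the center must not flip the s() threshold
    return np.round(out, 8)


def lbp_code_map(image: GrayImage | np.ndarray, params: LBPParams = LBPParams()) -> np.ndarray:
    """Integer LBP codes over the valid (border-stripped) region."""
    pix = _pixels(image)
    m = params.margin
    center = pix[m:pix.shape[0] - m, m:pix.shape[1] - m]
    ring = _ring_samples(pix, params)
    weights = (2 ** np.arange(params.P)).reshape(-1, 1, 1)
    return ((ring >= center) * weights).sum(axis=0)


def lbp_variance_map(image: GrayImage | np.ndarray, params: LBPParams = LBPParams()) -> np.ndarray:
    """Ring variance VAR_{P,R} over the valid region.

    The ring is referenced to the center pixel before the variance is
    taken (a no-op mathematically) so constant neighbourhoods give an
    exact zero.
    """
    pix = _pixels(image)
    m = params.margin
    center = pix[m:pix.shape[0] - m, m:pix.shape[1] - m]
    ring = _ring_samples(pix, params) - center
    return ring.var(axis=0)


def _check_pixel(pix: np.ndarray, pixel: tuple[int, int], params: LBPParams) -> None:
    i, j = pixel
    m = params.margin
    if not (m <= i < pix.shape[0] - m and m <= j < pix.shape[1] - m):
        raise ValueError(f"pixel {pixel} outside the valid region (margin {m})")


def lbp_code(image: GrayImage | np.ndarray, pixel: tuple[int, int],
             params: LBPParams = LBPParams()) -> int:
    """LBP code of a single pixel (must lie in the valid region)."""
    pix = _pixels(image)
    _check_pixel(pix, pixel, params)
    m = params.margin
    return int(lbp_code_map(pix, params)[pixel[0] - m, pixel[1] - m])


def lbp_variance(image: GrayImage | np.ndarray, pixel: tuple[int, int],
                 params: LBPParams = LBPParams()) -> float:
    """Ring variance of a single pixel (must lie in the valid region)."""
    pix = _pixels(image)
    _check_pixel(pix, pixel, params)
    m = params.margin
    return float(lbp_variance_map(pix, params)[pixel[0] - m, pixel[1] - m])


def lbpv_histogram(image: GrayImage | np.ndarray, params: LBPParams = LBPParams()) -> np.ndarray:
    """Variance-weighted LBP histogram of length 2^P.

    Bin k is the sum of ring variances over valid pixels with code k;
    border pixels (within ceil(R) of the frame) are skipped, not padded.
    """
    codes = lbp_code_map(image, params)
    var = lbp_variance_map(image, params)
    return np.bincount(codes.ravel(), weights=var.ravel(), minlength=params.n_codes)


def _minmax01(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)


def lbpv_sources(enhanced: GrayImage | np.ndarray, ll_db2: np.ndarray, ll_sym2: np.ndarray,
                 params: LBPParams = LBPParams()) -> dict[str, np.ndarray]:
    """The three LBPV histograms entering the local channel.

    Wavelet coefficient grids are min-max scaled per image before LBP:
    codes are scale invariant but the variance weights are not, and
    rescaling makes the three histograms commensurate.
    """
    return {
        "enhanced": lbpv_histogram(enhanced, params),
        "ll_db2": lbpv_histogram(_minmax01(np.asarray(ll_db2, dtype=float)), params),
        "ll_sym2": lbpv_histogram(_minmax01(np.asarray(ll_sym2, dtype=float)), params),
    }


def fit_lbpv_stats(source_rows: list[dict[str, np.ndarray]]) -> dict[str, ZNormStats]:
    """Per-source Z-norm statistics from enrollment histogram rows."""
    return {
        name: znorm_fit(np.stack([row[name] for row in source_rows]))
        for name in SOURCE_ORDER
    }


def build_lbpv_raw(enhanced: GrayImage | np.ndarray, ll_db2: np.ndarray, ll_sym2: np.ndarray,
                   params: LBPParams, stats: dict[str, ZNormStats]) -> np.ndarray:
    """Raw local-channel vector: three Z-normalized histograms, concatenated.

    Order: enhanced image, db2 approximation, sym2 approximation; length
    3 * 2^P (768 for P = 8).
    """
    src = lbpv_sources(enhanced, ll_db2, ll_sym2, params)
    return np.concatenate([znorm_apply(src[name], stats[name]) for name in SOURCE_ORDER])
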