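"""Global wavelet features (the WLPP front-end).

The global descriptor of an enhanced vein image is built from the level-3
approximation (LL) subbands of two discrete wavelet transforms, Daubechies
db2 and Symlet sym2.  Each flattened LL grid is Z-normalized per dimension
with statistics fitted on the enrollment split only, and the two
normalized vectors are concatenated (db2 part first).  The result is the
raw input of the LPP projection for the WLPP channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from veinverify.synthgen import GrayImage

__all__ = ["WaveletSpec", "ZNormStats", "wavelet_approx", "znorm_fit", "znorm_apply",
           "build_wlpp_raw", "fit_wlpp_stats"]


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet decomposition settings for the global feature."""

    wavelets: tuple[str, ...] = ("db2", "sym2")
    level: int = 3
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        for w in self.wavelets:
            if w not in pywt.wavelist(kind="discrete"):
                raise ValueError(f"unknown wavelet {w!r}")


@dataclass(frozen=True)
class ZNormStats:
    """Per-dimension mean/sd from the enrollment split.

    Zero-variance dimensions are flagged and map to 0 on apply.
    """

    mean: np.ndarray
    sd: np.ndarray

    @property
    def zero_sd(self) -> np.ndarray:
        return self.sd == 0.0


def wavelet_approx(image: GrayImage | np.ndarray, spec: WaveletSpec, wavelet: str) -> np.ndarray:
    """LL subband after ``spec.level`` cascaded 2-D DWT steps."""
    pix = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    w = pywt.Wavelet(wavelet)
    min_len = pywt.dwt_coeff_len(1, w.dec_len, spec.boundary_mode)
    if min(pix.shape) < 2 ** spec.level:
        raise ValueError(f"image shape {pix.shape} too small for level {spec.level}")
    coeffs = pywt.wavedec2(pix, w, mode=spec.boundary_mode, level=spec.level)
    return coeffs[0]


def znorm_fit(train: np.ndarray) -> ZNormStats:
    """Column-wise mean/sd (population sd) on the training matrix."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("train must be a nonempty (samples, dims) matrix")
    return ZNormStats(mean=train.mean(axis=0), sd=train.std(axis=0))


def znorm_apply(v: np.ndarray, stats: ZNormStats) -> np.ndarray:
    """(v - mean) / sd per dimension; zero-sd dimensions map to 0."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != stats.mean.shape[0]:
        raise ValueError(f"dimension mismatch: {v.shape[-1]} vs {stats.mean.shape[0]}")
    sd = np.where(stats.zero_sd, 1.0, stats.sd)
    out = (v - stats.mean) / sd
    return np.where(stats.zero_sd, 0.0, out)


def _raw_approx_vector(image: GrayImage | np.ndarray, spec: WaveletSpec, wavelet: str) -> np.ndarray:
    return wavelet_approx(image, spec, wavelet).ravel(order="C")


def fit_wlpp_stats(train_images: list[GrayImage], spec: WaveletSpec) -> dict[str, ZNormStats]:
    """Per-wavelet Z-norm statistics fitted on the enrollment images."""
    stats = {}
    for w in spec.wavelets:
        mat = np.stack([_raw_approx_vector(im, spec, w) for im in train_images])
        stats[w] = znorm_fit(mat)
    return stats


def build_wlpp_raw(image: GrayImage | np.ndarray, spec: WaveletSpec,
                   stats: dict[str, ZNormStats]) -> np.ndarray:
    """Raw WLPP vector: Z-normalized flattened LL grids, concatenated.

    Flattening is row-major; concatenation follows ``spec.wavelets`` order
    (db2 then sym2 by default).  Pure function of (image, spec, stats).
    """
    parts = [znorm_apply(_raw_approx_vector(image, spec, w), stats[w]) for w in spec.wavelets]
    return np.concatenate(parts)
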