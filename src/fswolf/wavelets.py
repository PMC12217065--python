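"""Multilevel 2-D discrete wavelet transform and texture features.

The analysis bank is the classical orthonormal fast DWT with periodic
(wrap-around) boundary handling. Analysis is correlation-form:

    a[k] = sum_n h[n] * x[(2k + n) mod N]
    d[k] = sum_n g[n] * x[(2k + n) mod N]

with h the scaling (father) filter and g its quadrature mirror
g[n] = (-1)^n h[L-1-n] (the mother filter; zero-sum, so detail bands
annihilate constants). Synthesis is the adjoint, which inverts exactly
because the shifted filters form an orthonormal basis for any even
signal length. Odd lengths are handled by one periodic pad sample,
which keeps the round trip exact.

Texture features are four statistics per subband: mean absolute
coefficient, standard deviation, energy (mean squared coefficient) and
Shannon entropy of the normalized |coeff| histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from fswolf.preprocess import LabeledImageSet

__all__ = [
    "WaveletSpec",
    "WaveletDecomposition",
    "make_wavelet",
    "fdwt2",
    "ifdwt2",
    "subband_statistics",
    "extract_features",
    "SUPPORTED_WAVELETS",
    "SUBBAND_STATISTIC_NAMES",
]

SUPPORTED_WAVELETS = ("haar", "db2", "db4")
SUBBAND_STATISTIC_NAMES = ("mean_abs", "std", "energy", "entropy")

#: ITU-R 601 luminance weights for RGB reduction
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class WaveletSpec:
    """Orthonormal analysis filter pair (father lowpass, mother highpass)."""

    name: str
    lowpass: np.ndarray
    highpass: np.ndarray


@dataclass
class WaveletDecomposition:
    """Level-J smooth band plus per-level (horizontal, vertical, diagonal) details.

    ``details[j]`` holds level j+1 (level 1 = finest, computed from the
    input). ``shapes`` records the input shape at each level so the
    synthesis bank can undo the odd-length periodic padding.
    """

    wavelet: WaveletSpec
    levels: int
    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    shapes: list[tuple[int, int]]
    boundary: str = "periodic"


def make_wavelet(name: str) -> WaveletSpec:
    """Return the filter pair for a supported wavelet family member.

    The lowpass taps sum to sqrt(2); the highpass taps sum to 0 (the
    discrete admissibility condition that makes detail bands annihilate
    constant signals).
    """
    if name not in SUPPORTED_WAVELETS:
        raise ValueError(f"unknown wavelet {name!r}; supported: {SUPPORTED_WAVELETS}")
    h = np.asarray(pywt.Wavelet(name).rec_lo, dtype=np.float64)
    # quadrature mirror: g[n] = (-1)^n h[L-1-n]
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return WaveletSpec(name=name, lowpass=h, highpass=g)


def _analysis_1d(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Correlation-form periodic filter + dyadic decimation along ``axis``."""
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    if n % 2 == 1:  # one periodic pad sample keeps the bank orthonormal
        x = np.concatenate([x, x[:1]], axis=0)
        n += 1
    starts = np.arange(0, n, 2)
    out = np.zeros((n // 2,) + x.shape[1:], dtype=np.float64)
    for t, tap in enumerate(taps):
        out += tap * x[(starts + t) % n]
    return np.moveaxis(out, 0, axis)


def _synthesis_1d(
    a: np.ndarray, d: np.ndarray, spec: WaveletSpec, length: int, axis: int
) -> np.ndarray:
    """Adjoint of `_analysis_1d`: upsample, filter, wrap, truncate."""
    a = np.moveaxis(a, axis, 0)
    d = np.moveaxis(d, axis, 0)
    n = 2 * a.shape[0]
    out = np.zeros((n,) + a.shape[1:], dtype=np.float64)
    starts = np.arange(0, n, 2)
    for t, (h_t, g_t) in enumerate(zip(spec.lowpass, spec.highpass)):
        idx = (starts + t) % n
        np.add.at(out, idx, h_t * a + g_t * d)
    out = out[:length]
    return np.moveaxis(out, 0, axis)


def _dwt2_step(
    image: np.ndarray, spec: WaveletSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    lo_r = _analysis_1d(image, spec.lowpass, axis=1)
    hi_r = _analysis_1d(image, spec.highpass, axis=1)
    ll = _analysis_1d(lo_r, spec.lowpass, axis=0)
    lh = _analysis_1d(lo_r, spec.highpass, axis=0)  # highpass along rows
    hl = _analysis_1d(hi_r, spec.lowpass, axis=0)
    hh = _analysis_1d(hi_r, spec.highpass, axis=0)
    # horizontal detail: highpass along columns (x), lowpass along rows (y)
    return ll, hl, lh, hh


def _idwt2_step(
    ll: np.ndarray,
    horizontal: np.ndarray,
    vertical: np.ndarray,
    diagonal: np.ndarray,
    spec: WaveletSpec,
    shape: tuple[int, int],
) -> np.ndarray:
    # synthesis undoes the analysis axes in reverse order; truncation to the
    # recorded shape drops the odd-length periodic pad sample exactly
    lo_r = _synthesis_1d(ll, vertical, spec, shape[0], axis=0)
    hi_r = _synthesis_1d(horizontal, diagonal, spec, shape[0], axis=0)
    return _synthesis_1d(lo_r, hi_r, spec, shape[1], axis=1)


def fdwt2(
    image: np.ndarray, wavelet: WaveletSpec | str, levels: int
) -> WaveletDecomposition:
    """Multilevel separable 2-D analysis bank (recursion on the smooth band)."""
    if isinstance(wavelet, str):
        wavelet = make_wavelet(wavelet)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("fdwt2 expects a 2-D grayscale matrix")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    max_levels = int(np.floor(np.log2(min(image.shape))))
    if levels < 1 or levels > max_levels:
        raise ValueError(
            f"levels must be in [1, {max_levels}] for a {image.shape} image"
        )
    details = []
    shapes = []
    approx = image
    for _ in range(levels):
        shapes.append(approx.shape)
        approx, hor, ver, diag = _dwt2_step(approx, wavelet)
        details.append((hor, ver, diag))
    return WaveletDecomposition(
        wavelet=wavelet,
        levels=levels,
        approximation=approx,
        details=details,
        shapes=shapes,
    )


def ifdwt2(decomp: WaveletDecomposition) -> np.ndarray:
    """Synthesis bank: exact inverse of `fdwt2` up to floating point."""
    if len(decomp.details) != decomp.levels or len(decomp.shapes) != decomp.levels:
        raise ValueError("inconsistent decomposition: level count mismatch")
    approx = decomp.approximation
    for j in range(decomp.levels - 1, -1, -1):
        hor, ver, diag = decomp.details[j]
        if not (hor.shape == ver.shape == diag.shape):
            raise ValueError(f"mismatched subband shapes at level {j + 1}")
        approx = _idwt2_step(approx, hor, ver, diag, decomp.wavelet, decomp.shapes[j])
    return approx


def _entropy(coeffs: np.ndarray, bins: int = 64) -> float:
    """Shannon entropy (nats) of the normalized |coeff| histogram; 0 log 0 := 0."""
    mags = np.abs(coeffs).ravel()
    top = mags.max()
    if top <= 0:
        return 0.0
    hist, _ = np.histogram(mags, bins=bins, range=(0.0, top))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _stats(band: np.ndarray) -> list[float]:
    flat = band.ravel()
    return [
        float(np.mean(np.abs(flat))),
        float(np.std(flat)),
        float(np.mean(flat**2)),
        _entropy(flat),
    ]


def subband_statistics(decomp: WaveletDecomposition) -> tuple[np.ndarray, list[str]]:
    """Four statistics per subband, flattened with stable names.

    Order: per level 1..J the horizontal, vertical, diagonal details,
    then the level-J approximation; within a subband the statistics
    follow `SUBBAND_STATISTIC_NAMES`. Length = (3J + 1) * 4.
    """
    values: list[float] = []
    names: list[str] = []
    for j, (hor, ver, diag) in enumerate(decomp.details, start=1):
        for orient, band in (("horizontal", hor), ("vertical", ver), ("diagonal", diag)):
            for stat, val in zip(SUBBAND_STATISTIC_NAMES, _stats(band)):
                names.append(f"L{j}_{orient}_{stat}")
                values.append(val)
    for stat, val in zip(SUBBAND_STATISTIC_NAMES, _stats(decomp.approximation)):
        names.append(f"L{decomp.levels}_approx_{stat}")
        values.append(val)
    return np.asarray(values, dtype=np.float64), names


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Reduce RGB to luminance with ITU-R 601 weights (grayscale passthrough)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ _LUMA
    raise ValueError("expected HxW or HxWx3 image")


def extract_features(
    images: LabeledImageSet, wavelet: WaveletSpec | str = "haar", levels: int = 3
):
    """Wavelet texture feature table for an image set.

    Returns ``(features, labels, names)`` with one row per sample in the
    set's order; column names are stable across runs.
    """
    if isinstance(wavelet, str):
        wavelet = make_wavelet(wavelet)
    rows = []
    names: list[str] | None = None
    for sid, img in zip(images.ids, images.images):
        try:
            decomp = fdwt2(to_luminance(img), wavelet, levels)
        except ValueError as exc:
            raise ValueError(f"sample {sid!r}: {exc}") from exc
        vals, names = subband_statistics(decomp)
        rows.append(vals)
    return np.vstack(rows), images.labels.copy(), names
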