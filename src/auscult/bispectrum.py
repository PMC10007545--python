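"""Bispectrum imaging of conditioned signals.

The bispectrum B(f1, f2) is the 2-D Fourier transform of the third-order cumulant
sequence C(tau1, tau2). It vanishes for Gaussian processes and peaks at (f1, f2) when
components at f1, f2 and f1+f2 are quadratically phase coupled, which makes it a
natural fixed-size image representation for murmurs and adventitious lung sounds.

Estimation is indirect: the biased cumulant estimate

    C(tau1, tau2) = (1/N) * sum_n x(n) x(n+tau1) x(n+tau2)

over lags |tau| <= L (default L = 127, so the (2L+1)-point support fits the 256-point
FFT grid), tapered by a separable 2-D Hann lag window, zero-padded to 256x256 and
transformed. Frequency origin convention: pixel (0, 0) is (f1, f2) = (0, 0) and
frequencies increase along rows/columns up to the 1 kHz Nyquist (FFT order, no shift),
so images are directly comparable across runs. The full plane is kept — no principal
domain cropping — and magnitudes are log-compressed then min-max scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.signal.windows import hann

from .preprocess import CleanSignal

IMAGE_SIZE = 256
DEFAULT_MAX_LAG = 127


@dataclass
class BispecImage:
    """256x256 scaled bispectrum-magnitude image with its class label."""

    pixels: np.ndarray
    label: str
    source_id: str
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}")


def third_order_cumulant(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased third-order cumulant estimate on a (2L+1)x(2L+1) lag grid.

    The input is mean-removed first (third-order cumulants are defined on the
    centered process). Row/column index i corresponds to lag tau = i - L.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    L = int(max_lag)
    if not 0 < L < n / 2:
        raise ValueError(f"max_lag must be in (0, {n / 2}), got {L}")
    x = x - x.mean()
    # shifted[i] holds x(n + tau_i) with zeros outside the record
    lags = np.arange(-L, L + 1)
    shifted = np.zeros((2 * L + 1, n))
    for i, tau in enumerate(lags):
        if tau >= 0:
            shifted[i, : n - tau] = x[tau:]
        else:
            shifted[i, -tau:] = x[: n + tau]
    c = (shifted * x) @ shifted.T / n
    return c


def bispectrum_indirect(c: np.ndarray, nfft: int = IMAGE_SIZE,
                        lag_window: bool = True) -> np.ndarray:
    """2-D DFT of the (windowed) cumulant matrix, zero-padded to ``nfft``.

    Returns the complex bispectrum with the zero-frequency origin at element
    (0, 0) (FFT corner convention).
    """
    c = np.asarray(c, dtype=np.float64)
    m = c.shape[0]
    if c.ndim != 2 or c.shape[1] != m or m % 2 == 0:
        raise ValueError("cumulant matrix must be square with odd side 2L+1")
    L = m // 2
    if m > nfft:
        raise ValueError(f"lag support {m} exceeds FFT size {nfft}")
    if lag_window:
        w = hann(m, sym=True)
        c = c * np.outer(w, w)
    grid = np.zeros((nfft, nfft))
    idx = np.arange(-L, L + 1) % nfft  # lag 0 lands on index 0
    grid[np.ix_(idx, idx)] = c
    return np.fft.fft2(grid)


def to_image(b: np.ndarray, label: str = "", source_id: str = "",
             log_compress: bool = True, synthetic: bool = False) -> BispecImage:
    """Min-max scale (log-compressed) bispectrum magnitude to [0, 1]."""
    mag = np.abs(np.asarray(b))
    if mag.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ValueError(f"expected a {IMAGE_SIZE}x{IMAGE_SIZE} matrix")
    if log_compress:
        mag = np.log1p(mag)
    lo, hi = float(mag.min()), float(mag.max())
    if hi <= lo:  # degenerate (e.g. all-zero signal): keep an all-zero image
        pixels = np.zeros_like(mag)
    else:
        pixels = (mag - lo) / (hi - lo)
    return BispecImage(pixels=pixels.astype(np.float32), label=label,
                       source_id=source_id, synthetic=synthetic)


def signal_to_image(sig: CleanSignal, max_lag: int = DEFAULT_MAX_LAG,
                    segments: int = 1, log_compress: bool = True) -> BispecImage:
    """CleanSignal -> BispecImage.

    ``segments > 1`` averages cumulant estimates over that many equal sub-segments
    (lower variance, coarser frequency support); the default uses the whole record
    as a single segment.
    """
    x = sig.samples
    if segments <= 1:
        c = third_order_cumulant(x, max_lag)
    else:
        pieces = np.array_split(x, segments)
        c = np.mean([third_order_cumulant(p, max_lag) for p in pieces], axis=0)
    b = bispectrum_indirect(c)
    return to_image(b, label=sig.label, source_id=sig.source_id,
                    log_compress=log_compress, synthetic=sig.synthetic)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def save_png(img: BispecImage, path: str | Path) -> None:
    """8-bit grayscale PNG (for inspection; training uses the float arrays)."""
    q = np.round(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(q, mode="L").save(Path(path))


def load_png(path: str | Path, label: str = "", source_id: str = "") -> BispecImage:
    arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=np.float32) / 255.0
    return BispecImage(pixels=arr, label=label, source_id=source_id)


def save_float(img: BispecImage, path: str | Path) -> None:
    np.save(Path(path), img.pixels)
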