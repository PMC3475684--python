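"""Fourier power-spectrum statistics: intercept and slope.

Natural scenes have approximately power-law spatial-frequency spectra,
P(f) ~ a * f^s with s near -2.  The two-parameter spectral signature of an
image is obtained by rotationally averaging the 2D power spectrum into
integer radial-frequency annuli and fitting an ordinary least-squares line
to log10(power) versus log10(frequency).  The slope is the power-law
exponent; the intercept is log10 power extrapolated to 1 cycle/image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .stimuli import StimulusImage

CROP_PIXELS = 16  # strip from each side before the FFT (edge artifacts)
FIT_FMIN = 2.0  # cycles/image
FIT_FMAX_FRACTION = 0.8  # of the radial Nyquist frequency


class DegenerateSpectrumError(ValueError):
    pass


@dataclass
class PowerSpectrumFit:
    intercept: float  # log10 power at 1 cycle/image
    slope: float
    frequency_bins: np.ndarray
    radial_spectrum: np.ndarray


def radial_average_power(
    pixels: np.ndarray, crop: int = CROP_PIXELS
) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged power spectrum over integer-frequency annuli.

    The largest concentric square (minus a ``crop``-pixel border) is
    transformed; |F|^2 is averaged over orientation within unit-width
    annuli at integer radial frequencies (cycles/image).  DC is excluded.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a 2D grayscale raster")
    h, w = pixels.shape
    side = min(h, w) - 2 * crop
    if side < 4:
        raise ValueError("image too small after cropping")
    y0 = (h - side) // 2
    x0 = (w - side) // 2
    img = pixels[y0 : y0 + side, x0 : x0 + side]

    power = np.abs(np.fft.fft2(img)) ** 2
    fy = np.fft.fftfreq(side) * side  # cycles/image
    fx = np.fft.fftfreq(side) * side
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    rbin = np.round(radius).astype(int)
    n_bins = side // 2 + 1
    flat_bins = rbin.ravel()
    keep = (flat_bins >= 1) & (flat_bins < n_bins)
    sums = np.bincount(flat_bins[keep], weights=power.ravel()[keep], minlength=n_bins)
    counts = np.bincount(flat_bins[keep], minlength=n_bins)
    freqs = np.arange(1, n_bins, dtype=np.float64)
    spectrum = sums[1:] / np.maximum(counts[1:], 1)
    return freqs, spectrum


def fit_spectrum_line(
    frequency_bins: np.ndarray,
    radial_spectrum: np.ndarray,
    fmin: float = FIT_FMIN,
    fmax_fraction: float = FIT_FMAX_FRACTION,
) -> PowerSpectrumFit:
    """OLS line through the log-log spectrum over the configured band."""
    f = np.asarray(frequency_bins, dtype=np.float64)
    p = np.asarray(radial_spectrum, dtype=np.float64)
    fmax = fmax_fraction * f.max()
    sel = (f >= fmin) & (f <= fmax) & (p > 0)
    if sel.sum() < 3:
        raise DegenerateSpectrumError("fewer than 3 positive-power bins in fit range")
    logf, logp = np.log10(f[sel]), np.log10(p[sel])
    slope, intercept = np.polyfit(logf, logp, 1)
    return PowerSpectrumFit(float(intercept), float(slope), f, p)


def fourier_stats(pixels: np.ndarray) -> PowerSpectrumFit:
    """Intercept and slope of the rotationally averaged power spectrum."""
    freqs, spectrum = radial_average_power(pixels)
    return fit_spectrum_line(freqs, spectrum)


def fourier_stats_table(images: Iterable[StimulusImage]) -> pd.DataFrame:
    rows = []
    for im in images:
        fit = fourier_stats(im.pixels)
        rows.append(
            {
                "image_id": im.image_id,
                "category_id": im.category_id,
                "intercept": fit.intercept,
                "slope": fit.slope,
            }
        )
    return pd.DataFrame(rows)
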