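"""Synthetic calibration set for noise-threshold estimation.

Noise floors for minimum-reliable-scale selection are estimated from a
separate, fixed set of naturalistic images.  This package ships a fully
synthetic, deterministic calibration set mixing three image types in equal
parts: quick dead-leaves scenes, spectrally shaped (1/f amplitude) noise,
and low-contrast smoothed noise (the fog/sky-like flat scenes that real
photographic collections contain).  The first two share the approximately
scale-invariant second-order statistics of natural scenes; the third adds
the large between-image contrast diversity of real photo sets, which is
what drives the spread (and hence the noise thresholds, defined as half
the across-image SD of mean contrast).  Thresholds still differ
numerically from any calibration on real photographs; any user-supplied
list of grayscale rasters can be passed to
:func:`deadleaves.contrast.calibrate_noise_thresholds` instead.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .contrast import FilterBankSpec, NoiseThresholds, calibrate_noise_thresholds

#: internal seed of the packaged calibration set (fixed: the set is an input,
#: not a source of run-to-run randomness)
CALIBRATION_SEED = 20120
CALIBRATION_SIZE = 256
N_CALIBRATION = 200


def _dead_leaves_image(size: int, rng: np.random.Generator) -> np.ndarray:
    """Minimal opaque dead-leaves scene with power-law radii on [4, 64]."""
    img = np.full((size, size), 0.5)
    covered = np.zeros((size, size), dtype=bool)
    n = 0
    while n < 4000:
        cx, cy = rng.uniform(-64, size + 64, size=2)
        u = rng.random()
        r = (4.0**-2 - u * (4.0**-2 - 64.0**-2)) ** -0.5
        x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, size)
        y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, size)
        if x0 >= x1 or y0 >= y1:
            n += 1
            continue
        yy = np.arange(y0, y1)[:, None] - cy
        xx = np.arange(x0, x1)[None, :] - cx
        inside = yy * yy + xx * xx <= r * r
        patch = img[y0:y1, x0:x1]
        patch[inside] = rng.uniform(0.1, 0.9)
        covered[y0:y1, x0:x1] |= inside
        n += 1
        if n % 64 == 0 and covered.mean() > 0.995:
            break
    return img


def _pink_noise_image(size: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with 1/f amplitude spectrum, rescaled to [0, 1]."""
    white = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size)[:, None] ** 2 + np.fft.fftfreq(size)[None, :] ** 2
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / np.sqrt(f[f > 0])
    shaped = np.fft.ifft2(np.fft.fft2(white) * amp).real
    lo, hi = shaped.min(), shaped.max()
    return (shaped - lo) / (hi - lo)


def _flat_scene_image(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-contrast smooth scene: heavily blurred noise around mid-gray."""
    from scipy import ndimage

    base = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 16)
    base /= max(np.abs(base).max(), 1e-12)
    amplitude = rng.uniform(0.02, 0.15)
    return 0.5 + amplitude * base


def calibration_images(
    n: int = N_CALIBRATION,
    size: int = CALIBRATION_SIZE,
    seed: int = CALIBRATION_SEED,
) -> list[np.ndarray]:
    """The deterministic synthetic calibration set (cycling image types)."""
    rng = np.random.default_rng(seed)
    makers = (_dead_leaves_image, _pink_noise_image, _flat_scene_image)
    return [makers[k % 3](size, rng) for k in range(n)]


@lru_cache(maxsize=4)
def default_thresholds(bank: FilterBankSpec) -> NoiseThresholds:
    """Noise thresholds of the packaged calibration set (cached per bank)."""
    return calibrate_noise_thresholds(calibration_images(), bank)
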