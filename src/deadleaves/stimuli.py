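"""Dead-leaves stimulus synthesis.

A dead-leaves image is built by sequentially compositing randomly placed
disks until the frame is (almost) fully covered, mimicking the occlusion
structure of natural scenes.  Sixteen parametric categories are defined by
crossing four disk properties:

* opacity      -- disks overwrite (opaque) or alpha-blend (transparent)
* depth        -- flat interior (2D) or radially decaying intensity (3D)
* size class   -- small / medium / large radius range (power-law sizes)
* distribution -- power-law (12 categories) or exponential radii with the
                  medium size range (4 categories)

Each category contributes 16 unique 512x512 grayscale images, for a set of
256 images in total.  Generation is fully deterministic given a master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

FRAME_SIZE = 512

#: radius intervals [r_min, r_max] in pixels per size class
RADIUS_RANGES = {
    "small": (4.0, 16.0),
    "medium": (8.0, 64.0),
    "large": (24.0, 80.0),
}

POWER_LAW_EXPONENT = 3.0

OPACITY_MODES = ("opaque", "transparent")
DEPTH_MODES = ("flat_2d", "decay_3d")
SIZE_CLASSES = ("small", "medium", "large")
RADIUS_DISTRIBUTIONS = ("power_law", "exponential")


class GenerationError(RuntimeError):
    """Raised when a stimulus cannot be generated within the disk budget."""


@dataclass(frozen=True)
class CategorySpec:
    """One of the 16 dead-leaves categories."""

    category_id: int
    opacity_mode: str
    depth_mode: str
    size_class: str
    radius_distribution: str

    def __post_init__(self) -> None:
        if self.opacity_mode not in OPACITY_MODES:
            raise ValueError(f"bad opacity_mode {self.opacity_mode!r}")
        if self.depth_mode not in DEPTH_MODES:
            raise ValueError(f"bad depth_mode {self.depth_mode!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"bad size_class {self.size_class!r}")
        if self.radius_distribution not in RADIUS_DISTRIBUTIONS:
            raise ValueError(f"bad radius_distribution {self.radius_distribution!r}")


@dataclass(frozen=True)
class DiskSpec:
    """A single disk: continuous center, radius, gray level and opacity."""

    center_x: float
    center_y: float
    radius: float
    base_intensity: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not 0.0 <= self.base_intensity <= 1.0:
            raise ValueError("base_intensity must be in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class StimulusImage:
    """A rendered 512x512 grayscale stimulus with its provenance."""

    pixels: np.ndarray
    category_id: int
    image_index: int
    seed: int
    spec: CategorySpec | None = None
    n_disks: int = 0
    coverage: float = 1.0  # fraction of pixels touched by at least one disk

    @property
    def image_id(self) -> str:
        return f"cat{self.category_id:02d}_img{self.image_index:02d}"


@dataclass(frozen=True)
class StimulusConfig:
    """Tunable generator settings (defaults define the reference stimulus set)."""

    frame_size: int = FRAME_SIZE
    power_law_exponent: float = POWER_LAW_EXPONENT
    radius_ranges: dict = field(default_factory=lambda: dict(RADIUS_RANGES))
    transparency_alpha: float = 0.5
    background: float = 0.5
    intensity_range: tuple = (0.1, 0.9)
    #: None draws gray levels uniformly over intensity_range; a (a, b) pair
    #: draws Beta(a, b) rescaled to the range (a < b skews dark, matching the
    #: dark-heavy luminance histograms of natural scenes)
    intensity_beta: tuple | None = None
    coverage_target: float = 0.999
    min_coverage: float = 0.99
    max_disks: int = 10_000
    #: fraction of the radius over which a 3D disk keeps full intensity
    #: before the quadratic decay toward the rim begins
    decay_core: float = 0.5
    #: rate of the exponential radius law; None matches the mean radius of
    #: the medium power-law class, which makes the exponential categories
    #: nearly indistinguishable from medium power-law ones — the default
    #: rate keeps the mean radius between the medium and large classes
    exponential_rate: float | None = 0.08


DEFAULT_CONFIG = StimulusConfig()


def category_specs() -> list[CategorySpec]:
    """The 16 category definitions, in fixed category_id order (1..16).

    Categories 1-12 cross opacity x depth x size with power-law radii;
    13-16 cross opacity x depth with exponential, medium-sized radii.
    """
    specs = []
    cid = 1
    for opacity, depth, size in product(OPACITY_MODES, DEPTH_MODES, SIZE_CLASSES):
        specs.append(CategorySpec(cid, opacity, depth, size, "power_law"))
        cid += 1
    for opacity, depth in product(OPACITY_MODES, DEPTH_MODES):
        specs.append(CategorySpec(cid, opacity, depth, "medium", "exponential"))
        cid += 1
    return specs


def truncated_power_law_mean(r_min: float, r_max: float, alpha: float) -> float:
    """Analytic mean of f(r) ∝ r^(−alpha) truncated to [r_min, r_max]."""
    if alpha == 2.0:
        num = np.log(r_max / r_min)
    else:
        num = (r_max ** (2 - alpha) - r_min ** (2 - alpha)) / (2 - alpha)
    den = (r_max ** (1 - alpha) - r_min ** (1 - alpha)) / (1 - alpha)
    return num / den


def truncated_exponential_mean(r_min: float, r_max: float, rate: float) -> float:
    """Analytic mean of f(r) ∝ exp(−rate·r) truncated to [r_min, r_max]."""
    span = r_max - r_min
    q = np.exp(-rate * span)
    return r_min + 1.0 / rate - span * q / (1.0 - q)


def exponential_rate(config: StimulusConfig = DEFAULT_CONFIG) -> float:
    """Rate of the exponential radius law.

    An explicit ``config.exponential_rate`` wins; otherwise the rate is
    solved so the truncated-exponential mean matches the medium power-law
    mean radius.
    """
    if config.exponential_rate is not None:
        return config.exponential_rate
    r_min, r_max = config.radius_ranges["medium"]
    target = truncated_power_law_mean(r_min, r_max, config.power_law_exponent)
    return brentq(
        lambda lam: truncated_exponential_mean(r_min, r_max, lam) - target,
        1e-4,
        10.0,
        xtol=1e-12,
    )


def sample_radius(
    distribution: str,
    size_class: str,
    rng: np.random.Generator,
    n: int | None = None,
    config: StimulusConfig = DEFAULT_CONFIG,
) -> float | np.ndarray:
    """Draw disk radii from the truncated power-law or exponential law.

    Inverse-CDF sampling on the interval mapped to by ``size_class``.
    """
    r_min, r_max = config.radius_ranges[size_class]
    if r_min <= 0 or r_min > r_max:
        raise ValueError(f"invalid radius interval [{r_min}, {r_max}]")
    u = rng.random(n) if n is not None else rng.random()
    if r_min == r_max:
        return np.full_like(u, r_min) if n is not None else r_min
    if distribution == "power_law":
        a = config.power_law_exponent - 1.0  # CDF exponent, alpha > 1 assumed
        lo, hi = r_min ** (-a), r_max ** (-a)
        return (lo - u * (lo - hi)) ** (-1.0 / a)
    if distribution == "exponential":
        lam = exponential_rate(config)
        span = r_max - r_min
        return r_min - np.log(1.0 - u * (1.0 - np.exp(-lam * span))) / lam
    raise ValueError(f"unknown distribution {distribution!r}")


def render_disk(
    pixels: np.ndarray,
    disk: DiskSpec,
    depth_mode: str,
    opacity_mode: str,
    coverage: np.ndarray | None = None,
    decay_core: float = 0.0,
) -> np.ndarray:
    """Composite one disk into ``pixels`` (in place) and return the array.

    Opaque flat disks overwrite the interior with ``base_intensity``;
    transparent disks alpha-blend; 3D ("decay") disks multiply the disk
    value by a radial profile that is 1 over the central ``decay_core``
    fraction of the radius and then falls quadratically (1 − u²) to 0 at
    the rim.  Disks extending beyond the frame are clipped.  ``coverage``
    (boolean, same shape) is OR-ed with the disk footprint.
    """
    h, w = pixels.shape
    r = disk.radius
    x0 = max(int(np.floor(disk.center_x - r)), 0)
    x1 = min(int(np.ceil(disk.center_x + r)) + 1, w)
    y0 = max(int(np.floor(disk.center_y - r)), 0)
    y1 = min(int(np.ceil(disk.center_y + r)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return pixels
    yy = np.arange(y0, y1, dtype=np.float64)[:, None] - disk.center_y
    xx = np.arange(x0, x1, dtype=np.float64)[None, :] - disk.center_x
    d2 = yy * yy + xx * xx
    inside = d2 <= r * r
    if not inside.any():
        return pixels
    if depth_mode == "decay_3d":
        core = decay_core * r
        d = np.sqrt(d2)
        u = np.clip((d - core) / max(r - core, 1e-12), 0.0, 1.0)
        profile = np.clip(1.0 - u * u, 0.0, None)
        value = disk.base_intensity * profile
    else:
        value = disk.base_intensity
    patch = pixels[y0:y1, x0:x1]
    if opacity_mode == "opaque":
        new = np.where(inside, value, patch)
    else:
        blended = disk.alpha * value + (1.0 - disk.alpha) * patch
        new = np.where(inside, blended, patch)
    pixels[y0:y1, x0:x1] = new
    if coverage is not None:
        coverage[y0:y1, x0:x1] |= inside
    return pixels


def _image_seed(master_seed: int, spec: CategorySpec, image_index: int) -> np.random.SeedSequence:
    # Opacity is deliberately excluded: opaque/transparent counterparts share
    # the identical disk sequence so their layouts are directly comparable.
    key = (
        DEPTH_MODES.index(spec.depth_mode),
        SIZE_CLASSES.index(spec.size_class),
        RADIUS_DISTRIBUTIONS.index(spec.radius_distribution),
        image_index,
    )
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def generate_image(
    spec: CategorySpec,
    image_index: int,
    master_seed: int,
    config: StimulusConfig = DEFAULT_CONFIG,
) -> StimulusImage:
    """Render one stimulus: add disks until coverage >= target or budget."""
    size = config.frame_size
    ss = _image_seed(master_seed, spec, image_index)
    rng = np.random.default_rng(ss)
    seed_id = int(ss.generate_state(1)[0])

    pixels = np.full((size, size), config.background, dtype=np.float64)
    coverage = np.zeros((size, size), dtype=bool)
    _, r_max = config.radius_ranges[spec.size_class]
    margin = r_max
    lo_i, hi_i = config.intensity_range
    n_pixels = size * size
    alpha = config.transparency_alpha if spec.opacity_mode == "transparent" else 1.0

    n_disks = 0
    covered = 0
    while n_disks < config.max_disks:
        cx = rng.uniform(-margin, size + margin)
        cy = rng.uniform(-margin, size + margin)
        radius = float(sample_radius(spec.radius_distribution, spec.size_class, rng, config=config))
        if config.intensity_beta is None:
            intensity = rng.uniform(lo_i, hi_i)
        else:
            a_i, b_i = config.intensity_beta
            intensity = lo_i + (hi_i - lo_i) * rng.beta(a_i, b_i)
        disk = DiskSpec(cx, cy, radius, intensity, alpha)
        render_disk(
            pixels, disk, spec.depth_mode, spec.opacity_mode, coverage,
            decay_core=config.decay_core,
        )
        n_disks += 1
        if n_disks % 64 == 0:
            covered = int(coverage.sum())
            if covered >= config.coverage_target * n_pixels:
                break
    covered = int(coverage.sum())
    if covered < config.min_coverage * n_pixels:
        raise GenerationError(
            f"category {spec.category_id} image {image_index}: coverage "
            f"{covered / n_pixels:.4f} below {config.min_coverage} after "
            f"{n_disks} disks"
        )
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return StimulusImage(
        pixels, spec.category_id, image_index, seed_id, spec, n_disks,
        covered / n_pixels,
    )


def generate_stimulus_set(
    master_seed: int,
    config: StimulusConfig = DEFAULT_CONFIG,
    specs: Sequence[CategorySpec] | None = None,
    images_per_category: int = 16,
) -> list[StimulusImage]:
    """Generate the full deterministic stimulus set (16 categories x 16 images)."""
    specs = list(specs) if specs is not None else category_specs()
    images = []
    for spec in specs:
        for idx in range(1, images_per_category + 1):
            images.append(generate_image(spec, idx, master_seed, config))
    return images


def image_sha256(image: StimulusImage) -> str:
    """Stable content hash of the 8-bit quantized pixel raster."""
    as_u8 = np.round(image.pixels * 255.0).astype(np.uint8)
    return hashlib.sha256(as_u8.tobytes()).hexdigest()


def manifest(images: Iterable[StimulusImage]) -> pd.DataFrame:
    rows = []
    for im in images:
        spec = im.spec
        rows.append(
            {
                "image_id": im.image_id,
                "category_id": im.category_id,
                "image_index": im.image_index,
                "seed": im.seed,
                "opacity_mode": spec.opacity_mode if spec else "",
                "depth_mode": spec.depth_mode if spec else "",
                "size_class": spec.size_class if spec else "",
                "radius_distribution": spec.radius_distribution if spec else "",
                "n_disks": im.n_disks,
            }
        )
    return pd.DataFrame(rows)


def save_images(images: Iterable[StimulusImage], outdir) -> pd.DataFrame:
    """Write 8-bit grayscale PNGs plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = list(images)
    for im in images:
        arr = np.round(im.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(outdir / f"{im.image_id}.png")
    mf = manifest(images)
    mf.to_csv(outdir / "manifest.csv", index=False)
    return mf


def category_labels(images: Sequence[StimulusImage]) -> np.ndarray:
    return np.array([im.category_id for im in images])
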