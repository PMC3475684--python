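import numpy as np
import pytest

from deadleaves import calibration, contrast, stimuli


@pytest.fixture(scope="session")
def small_config():
    """Reduced generator config for fast structural tests (128 px frames)."""
    return stimuli.StimulusConfig(
        frame_size=128,
        radius_ranges={"small": (2.0, 8.0), "medium": (4.0, 32.0), "large": (16.0, 64.0)},
        max_disks=4000,
    )


@pytest.fixture(scope="session")
def tiny_calibration_thresholds():
    """Noise thresholds from a 12-image calibration subset (both banks)."""
    imgs = calibration.calibration_images(n=12, size=128)
    return (
        contrast.calibrate_noise_thresholds(imgs, contrast.BETA_BANK),
        contrast.calibrate_noise_thresholds(imgs, contrast.GAMMA_BANK),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
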