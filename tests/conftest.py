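import numpy as np
import pytest

from lungperf import (BlindSpotDenoiser, BSNConfig, NoiseSpec, PhantomSpec,
                      TrainConfig, make_phantom_bundle)
from lungperf.preprocess import (auto_baseline_frames, background_subtract,
                                 select_peak_frame)


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default 12x64x64 phantom with correlated, gain-modulated noise."""
    return make_phantom_bundle(seed=5)


@pytest.fixture(scope="session")
def enhanced_peak(phantom_bundle):
    """(enhanced peak volume, matching clean enhancement volume, bundle)."""
    b = phantom_bundle
    frames = auto_baseline_frames(b.noisy_series, b.lung_mask)
    enhanced = background_subtract(b.noisy_series, frames)
    t = select_peak_frame(enhanced, b.lung_mask)
    curve = np.asarray(b.spec.enhancement_curve)
    return enhanced.volume(t), b.enhancement * curve[t], b


@pytest.fixture(scope="session")
def tiny_results(enhanced_peak):
    """A very small trained denoiser for structural/contract tests."""
    volume, _, _ = enhanced_peak
    model = BlindSpotDenoiser(list(volume[4:8]),
                              BSNConfig(channels=8, n_dilated_blocks=1))
    return model.fit(TrainConfig(epochs=2, steps_per_epoch=4, batch_size=1,
                                 patch_size=30, seed=0))
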