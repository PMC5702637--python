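import numpy as np
import pytest

import pulsecam as pc


@pytest.fixture(scope="session")
def steady_truth():
    """Noise-free, modulation-free beat train: 150 IBIs of exactly 800 ms."""
    cfg = pc.SynthConfig(
        base_hp=800.0, rsa_amp=0.0, lf_amp=0.0, beat_noise_sd=0.0,
        duration=120.0, transit_jitter_sd=0.0, transit_delay=200.0, seed=0,
    )
    return pc.generate_ibi_series(cfg)


@pytest.fixture(scope="session")
def modulated_truth():
    """300 s resting-adult train with RSA and LF modulation plus beat noise."""
    cfg = pc.SynthConfig(duration=300.0, seed=9, transit_jitter_sd=10.0)
    return pc.generate_ibi_series(cfg)


def nearest_abs_diff(truth_times: np.ndarray, detected: np.ndarray) -> np.ndarray:
    """Per true beat, absolute time offset to the nearest detected peak (s)."""
    if len(detected) == 0:
        return np.full(len(truth_times), np.inf)
    idx = np.clip(np.searchsorted(detected, truth_times), 1, len(detected) - 1)
    best = np.minimum(
        np.abs(detected[idx] - truth_times), np.abs(detected[idx - 1] - truth_times)
    )
    return best
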