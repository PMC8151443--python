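import numpy as np
import pytest

import sleepband as sb


@pytest.fixture(scope="session")
def profiles():
    return sb.default_profiles()


@pytest.fixture(scope="session")
def small_cohort():
    """Three preprocessed synthetic subjects, 0.5 h each (60 epochs)."""
    cfg = sb.SyntheticCohortConfig(n_subjects=3, record_hours=0.5, seed=42)
    return [
        sb.preprocess_recording(s.recording, s.hypnogram)
        for s in sb.generate_cohort(cfg)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_epoch(ch1: np.ndarray, ch2: np.ndarray) -> np.ndarray:
    """Stack two 750-sample channels into one (750, 2) epoch."""
    return np.stack([ch1, ch2], axis=1)


def sine(freq: float, amp: float = 1.0, n: int = 750, fs: float = 25.0, phase: float = 0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
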