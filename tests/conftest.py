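import numpy as np
import pytest

import semgfog as sf


@pytest.fixture(scope="session")
def cohort_analysis() -> sf.pipeline.CohortReport:
    """Full-pipeline analysis of the fixed three-session cohort (8 episodes)."""
    return sf.analyze_cohort()


@pytest.fixture(scope="session")
def cohort_true_leads() -> list[float]:
    """Ground-truth precursor lead times of the fixed cohort, in session order."""
    leads = []
    for spec in sf.synth.cohort_specs():
        leads.extend(ep.precursor_lead_s for ep in spec.episodes)
    return leads


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_recording(data: np.ndarray, fs: float = 1000.0, t0: float = 0.0) -> sf.Recording:
    """Wrap a (channels x samples) array with generic thigh channel metadata."""
    data = np.atleast_2d(data)
    labels = ["quadriceps_right", "hamstring_right", "tibialis_anterior_left",
              "gastrocnemius_left", "biceps_left"]
    channels = [sf.ChannelMeta.from_label(labels[i]) for i in range(data.shape[0])]
    return sf.Recording(sample_rate=fs, channels=channels, data=data, t0=t0)
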