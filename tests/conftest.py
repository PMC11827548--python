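import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from caninesleep.hypnogram import Hypnogram
from caninesleep.simulate import SimParams, gen_eeg, gen_hypnogram
from caninesleep.spectral import ArtifactMask


@pytest.fixture(scope="session")
def worked_hypnogram() -> Hypnogram:
    """The 9-epoch hand-enumerable hypnogram used throughout the docs."""
    return Hypnogram(tuple("WWDNNRNWW"), epoch_s=20.0)


def small_params(**overrides) -> SimParams:
    """Fast single-channel generator settings for detector tests.

    ~22 artifact-free non-REM minutes at 256 Hz; everything else defaults.
    """
    base = dict(
        recording_minutes=25.0,
        sample_rate_hz=256.0,
        channels=("Fz",),
        spindle_channels=("Fz",),
        stage_dwell_means={"W": 0.5, "D": 0.5, "N": 10.0, "R": 0.5},
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def spindle_recording():
    """One 25-min mostly-NREM recording with mixed slow+fast spindles."""
    p = small_params(spindle_density_slow=2.0, spindle_density_fast=2.0)
    h = gen_hypnogram(p, seed=3)
    rec, truth = gen_eeg(h, p, seed=4)
    mask = ArtifactMask(tuple(truth.artifact_intervals))
    return p, h, rec, truth, mask
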