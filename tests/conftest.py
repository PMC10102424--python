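import numpy as np
import pytest

import timegen as tg
from timegen.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def ladder_ms():
    return tg.build_ladder(0.4, 7, 0.1)


@pytest.fixture(scope="session")
def ladder_s():
    return tg.build_ladder(2.0, 7, 0.1)


@pytest.fixture
def observer_ms():
    """A typical millisecond-range observer at the calibrated population means."""
    return tg.ObserverParams(
        pse_rest_s=0.405,
        wf_true=0.27,
        amplitude=0.85,
        baseline=0.05,
        running_gain=0.366 / 0.405,
        participant_id="P001",
    )


@pytest.fixture
def tiny_config():
    """A scaled-down pipeline configuration for fast smoke tests."""
    return PipelineConfig(
        master_seed=11, n_visual=3, n_auditory=3, n_both=2, n_blocks=1
    )


def make_curve(ladder, mu_log10, sigma, amplitude, baseline, n_per_level):
    """Noiseless generalization curve from known parameters (counts rounded)."""
    x = np.log10(np.asarray(ladder.durations_s))
    p = baseline + amplitude * np.exp(-0.5 * ((x - mu_log10) / sigma) ** 2)
    n = np.full(len(x), n_per_level, dtype=int)
    return tg.GeneralizationCurve(np.asarray(ladder.durations_s), np.round(p * n).astype(int), n)
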