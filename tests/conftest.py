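import numpy as np
import pytest

from assrpac.synth import (
    CouplingSpec,
    NoiseSpec,
    ParadigmSpec,
    TrialEnsemble,
    synthesize_session,
)
from assrpac.preprocess import select_analysis_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_paradigm():
    """Short, low-rate paradigm for fast unit tests."""
    return ParadigmSpec(
        sampling_rate_hz=250.0, n_trials_total=10, n_oddball=2, n_blocks=5
    )


@pytest.fixture
def noise_free():
    return NoiseSpec(noise_sd=0.0, assr_amplitude=0.0)


@pytest.fixture
def tiny_ensemble(rng):
    """8 trials of structured noise at 250 Hz, epoch -1.5..1.5 s."""
    sfreq = 250.0
    t = np.arange(-375, 376) / sfreq
    data = rng.standard_normal((8, t.size))
    return TrialEnsemble(data, t, sfreq, condition_label="test")


@pytest.fixture
def coupled_ensemble():
    """Entrainment-free session with strong (6, 40) coupling, 250 Hz."""
    spec = ParadigmSpec(sampling_rate_hz=250.0, n_trials_total=40, n_oddball=0, n_blocks=4)
    coupling = CouplingSpec(modulation_depth=0.9)
    noise = NoiseSpec(noise_sd=0.5, assr_amplitude=0.0)
    return select_analysis_trials(synthesize_session(spec, coupling, noise, seed=7))
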