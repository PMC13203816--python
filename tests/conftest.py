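import numpy as np
import pytest

from macross import (
    Epoch,
    MRCPModel,
    NoiseModel,
    ParadigmConfig,
    TrialRecord,
    simulate_session,
)


@pytest.fixture(scope="session")
def small_session():
    """A 6-GO-trial session at default conditions, shared across tests."""
    return simulate_session(ParadigmConfig(n_go_trials=6, seed=11))


@pytest.fixture(scope="session")
def high_snr_session():
    """Strong MRCP, weak noise: the regime where detection should be easy."""
    return simulate_session(
        ParadigmConfig(n_go_trials=6, seed=11),
        mrcp=MRCPModel(trough_amp_uv=-10.0),
        noise=NoiseModel(noise_sd_uv=0.5),
    )


def make_epoch(samples, rate=300.0, start=-6.0, end=5.0, trial_index=0):
    """Wrap a raw sample array as an epoch anchored at preparation onset."""
    trial = TrialRecord(index=trial_index, prep_onset=10.0,
                        cue_label="cue_go", cue_onset=12.0)
    return Epoch(trial=trial, samples=np.asarray(samples, dtype=float),
                 rate=rate, epoch_start=start, epoch_end=end)


@pytest.fixture
def flat_epoch():
    n = int(round(11.0 * 300))
    return make_epoch(np.zeros(n))
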