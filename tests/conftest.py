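import numpy as np
import pandas as pd
import pytest

from acephys.types import (
    ConnectionSpec,
    EvokedSpec,
    LaminarLFPSpec,
    NetworkSpec,
    PsychometricSpec,
    UnitSpec,
)
from acephys import synth

MASTER_SEED = 20240917


@pytest.fixture(scope="session")
def master_seed() -> int:
    return MASTER_SEED


@pytest.fixture(scope="session")
def psych_spec() -> PsychometricSpec:
    return PsychometricSpec(
        midpoint_db=45.0, slope_per_db=1.0, lapse=0.0, catch_fa=0.1,
        intensities_db=(30.0, 40.0, 50.0, 60.0, 70.0),
    )


@pytest.fixture(scope="session")
def behavior_session(psych_spec):
    return synth.gen_behavior_session(psych_spec, 100, 50, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def passive_events() -> pd.DataFrame:
    """100-ms noise pulses at 5 intensities, 100 repetitions each, 0.5-s ISI."""
    rng = np.random.default_rng(MASTER_SEED)
    intensities = np.repeat([30.0, 40.0, 50.0, 60.0, 70.0], 100)
    rng.shuffle(intensities)
    onsets = 1.0 + np.arange(intensities.size) * 0.6
    return pd.DataFrame({"onset_s": onsets, "intensity_db": intensities})


@pytest.fixture(scope="session")
def unconnected_pair():
    net = NetworkSpec(
        units=[UnitSpec(unit_id=0, baseline_rate_hz=5.0),
               UnitSpec(unit_id=1, baseline_rate_hz=5.0)],
        duration_s=600.0,
    )
    return synth.gen_coupled_spike_trains(net, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def excitatory_pair():
    net = NetworkSpec(
        units=[UnitSpec(unit_id=0, baseline_rate_hz=5.0),
               UnitSpec(unit_id=1, baseline_rate_hz=5.0)],
        connections=[ConnectionSpec(0, 1, +1, 1.5, 0.2)],
        duration_s=600.0,
    )
    return synth.gen_coupled_spike_trains(net, seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def inhibitory_pair():
    net = NetworkSpec(
        units=[UnitSpec(unit_id=0, baseline_rate_hz=10.0),
               UnitSpec(unit_id=1, baseline_rate_hz=10.0)],
        connections=[ConnectionSpec(0, 1, -1, 0.1, 0.8, inhibition_window_ms=4.0)],
        duration_s=600.0,
    )
    return synth.gen_coupled_spike_trains(net, seed=MASTER_SEED + 2)


@pytest.fixture(scope="session")
def laminar_events() -> pd.DataFrame:
    return pd.DataFrame({"onset_s": np.arange(1.0, 59.0, 0.7)})


@pytest.fixture()
def lfp_spec() -> LaminarLFPSpec:
    return LaminarLFPSpec(
        n_channels=16, channel_spacing_um=50.0, sampling_rate=1000.0,
        sink_channel=8, sink_amplitude=50.0, noise_sd=1.0,
    )
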