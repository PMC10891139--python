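import numpy as np
import pytest

from diplisten import behavior as bh
from diplisten import simulate as sim
from diplisten.stimulus import StimulusConfig


@pytest.fixture(scope="session")
def stim_config():
    return StimulusConfig()


@pytest.fixture(scope="session")
def small_trials():
    """A ~100-trial session from a plausible stochastic agent."""
    agent = bh.make_psychometric_agent(
        {-10.0: 0.82, 0.0: 0.88, 10.0: 0.93}, far=0.12, seed=11)
    return bh.schedule_session(100, agent, rng_seed=7)


def flat_profile(rate_hz=20.0, depth=0.0, **kw):
    """Unit with no target response; locking depth configurable."""
    return sim.UnitProfile(
        unit_id=0, baseline_rate_hz=rate_hz, locking_depth=depth,
        onset_gain={}, offset_gain={}, sustained_gain={},
        locking_suppression={s: 0.0 for s in (-10.0, 0.0, 10.0)}, **kw)


@pytest.fixture(scope="session")
def locked_nogo_trains():
    """60 NoGo trains from a fully locked (depth 1) 20 Hz unit."""
    prof = flat_profile(rate_hz=20.0, depth=1.0)
    t, lam = sim.intensity_function(prof, "NoGo", -np.inf, "passive")
    rng = np.random.default_rng(0)
    return [sim.sample_spike_train(t, lam, 0.0, rng, trial_index=i)
            for i in range(60)]
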