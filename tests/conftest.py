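import numpy as np
import pytest
from hypothesis import settings

from hhcable import (AxonGeometry, CableModel, SimControl, StimulusTrain)

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_model():
    return CableModel()


@pytest.fixture(scope="session")
def suprathreshold_result():
    """One propagated spike at the measuring point (default axon)."""
    model = CableModel(ctl=SimControl(ts=20.0))
    return model.simulate(StimulusTrain(NoStim=1, Amp=12000.0, Dur=0.2,
                                        Delay=1.0))


@pytest.fixture(scope="session")
def single_compartment_run():
    """Space-clamped patch: small cylinder, nseg = 1, step current."""
    geom = AxonGeometry(L=100.0, diam=50.0, nseg=1)
    ctl = SimControl(dt=0.025, ts=20.0)
    model = CableModel(geom, ctl=ctl)
    stim = StimulusTrain(NoStim=1, Amp=15.0, Dur=1.0, Delay=1.0)
    return model, stim, model.simulate(stim)
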