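import numpy as np
import pytest

from dopaquant.synth import TraceSpec, generate_trace
from dopaquant.traces import Trace


@pytest.fixture(scope="session")
def single_transient():
    """One noiseless 2 µM transient at 0.5 s (10 kHz, 2 s)."""
    spec = TraceSpec(
        duration_s=2.0,
        stimulus_times_s=(0.5,),
        amplitude_um=(2.0,),
        tau_rise_ms=1.0,
        tau_decay_ms=40.0,
        seed=0,
    )
    current, conc, truth = generate_trace(spec)
    return spec, current, conc, truth


@pytest.fixture
def flat_trace():
    return Trace(np.full(20_001, 1.0), 10_000.0, 0.0, "uM")
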