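import numpy as np
import pytest

from nirskinetics import Segment, SessionProtocol, default_spec, generate_session


@pytest.fixture
def protocol():
    return SessionProtocol(sprint_starts=[0.0, 270.0, 540.0, 810.0, 1080.0], condition="NOR")


@pytest.fixture(scope="session")
def noiseless_session():
    spec = default_spec("BFR", noise_sd=0.0, drift_sd=0.0)
    return generate_session(spec, seed=101)


@pytest.fixture(scope="session")
def noisy_session():
    return generate_session(default_spec("NOR"), seed=202)


def make_recovery_segment(t, y, sprint_index=1, condition="NOR"):
    return Segment(
        kind="recovery",
        sprint_index=sprint_index,
        t_start=30.0,
        t_end=30.0 + float(t[-1]) + 1.0,
        time=np.asarray(t, dtype=float),
        tsi=np.asarray(y, dtype=float),
        condition=condition,
    )


def make_deoxy_window(y, sprint_index=1, condition="NOR"):
    y = np.asarray(y, dtype=float)
    return Segment(
        kind="deoxy_window",
        sprint_index=sprint_index,
        t_start=0.0,
        t_end=9.0,
        time=np.arange(y.size, dtype=float),
        tsi=y,
        condition=condition,
    )
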