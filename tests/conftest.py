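import numpy as np
import pytest

from gpcrbias.assaysim import (
    KineticScenario,
    LigandPathwayParams,
    NoiseModel,
)
from gpcrbias.traces import KineticTrace


@pytest.fixture
def glp1_minigs_params():
    """Full-agonist operational parameters for a mini-G_s-style pathway."""
    return LigandPathwayParams("GLP-1", "miniGs", Em=100.0, log_tau=1.0, log_KA=-8.0)


@pytest.fixture
def sustained_scenario():
    """Sustained association with a 1.5-min half-time (k = ln2 / 1.5)."""
    return KineticScenario(onset_rate=float(np.log(2) / 1.5))


@pytest.fixture
def quiet_noise():
    return NoiseModel()


def make_trace(times, signal, channel="signal", **kw):
    return KineticTrace(
        well_id=kw.pop("well_id", "W1"),
        times=np.asarray(times, float),
        channels={channel: np.asarray(signal, float)},
        **kw,
    )
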