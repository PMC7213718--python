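import numpy as np
import pytest

from cardiofit.cellmodel import TOY_BASELINE_PARAMS, toy_ap
from cardiofit.waveform import BaselineSet

# The toy recovery experiment's study conditions: restitution extremes plus
# the experimentally recorded PCLs, and a modest parameter perturbation.
TOY_TRUTH_MULT = np.array([1.15, 0.9, 1.2, 0.8])
TOY_PCLS = (217.0, 300.0, 500.0, 1000.0, 2000.0)


@pytest.fixture(scope="session")
def toy_truth():
    return TOY_TRUTH_MULT.copy()


@pytest.fixture(scope="session")
def toy_baselines():
    """Noise-free absolute-mV toy baselines generated from the truth."""
    params = TOY_BASELINE_PARAMS * TOY_TRUTH_MULT
    traces = {pcl: toy_ap(params, pcl) for pcl in TOY_PCLS}
    return BaselineSet(traces=traces, mode="absolute")


@pytest.fixture(scope="session")
def settled_state():
    """ORd state after 20 s of 1-Hz pacing (cheap shared starting point)."""
    from cardiofit.cellmodel import pace_to_steady_state
    res = pace_to_steady_state(settle=20.0, pcl=1000.0)
    assert res.ok
    return res.state
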