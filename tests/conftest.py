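import numpy as np
import pytest

from metafoot.fitting import TimeSeries
from metafoot.kinetics import SigmoidParams, eval_sigmoid

#: sampling design of the batch experiment the package targets: sterile
#: medium at 0 h plus four destructive harvests with three replicate flasks
DESIGN_TIMES = np.array([0.0, 17.0, 19.0, 22.0, 24.0])


@pytest.fixture
def lactate_params() -> SigmoidParams:
    """A well-characterised mid-course depletion curve (lactate)."""
    return SigmoidParams(a=7.34, t50=17.90, w=1.09, o=17.60)


def make_series(p: SigmoidParams, noise_sd: float = 0.0, seed: int = 0,
                times: np.ndarray = DESIGN_TIMES, replicates: int = 3,
                name: str = "synthetic") -> TimeSeries:
    """Sample a sigmoid on the experimental design, single t=0 analysis."""
    rng = np.random.default_rng(seed)
    obs = []
    for i, t in enumerate(times):
        n = 1 if i == 0 else replicates
        y = eval_sigmoid(p, t) * np.exp(rng.normal(0.0, noise_sd, n))
        obs.append(y)
    return TimeSeries(name, times, obs)


@pytest.fixture
def series_factory():
    return make_series
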