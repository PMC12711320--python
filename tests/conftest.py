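import numpy as np
import pytest

from brdtr import StageSample, make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


def random_stage_sample(seed, n=None, d=3, neg_risk=False, p=0.5):
    """Small random stage sample for solver tests."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(10, 36))
    lo = -1.0 if neg_risk else 0.05
    return StageSample(
        H=rng.normal(size=(n, d)),
        A=rng.choice([-1.0, 1.0], n),
        W=rng.uniform(0.0, 2.0, n),
        R=rng.uniform(lo, 2.0, n),
        P=np.full(n, p),
    )
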