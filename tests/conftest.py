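import numpy as np
import pytest

from pumprisk.distributions import (
    FittedDistributions,
    LogNormalParams,
    PositivePoissonParams,
    TruncNormParams,
)
from pumprisk.exposure import ExposureSample, Measurement


@pytest.fixture(scope="session")
def published_dists() -> FittedDistributions:
    """The fully parameterized consumer exposure-factor distributions."""
    return FittedDistributions(
        concentration=LogNormalParams(mu=-5.73, sigma=0.98),
        fill_time=TruncNormParams(mean=3.08, sd=1.56, lower=0.5, upper=6.0),
        fill_frequency=PositivePoissonParams(lam=2.0),
    )


def make_sample(
    consumer_id="C001",
    benzene=3.24,
    initial_vacuum=30.0,
    final_vacuum=14.6,
    fills_per_month=2,
    leaked=False,
    **compounds,
) -> ExposureSample:
    """Convenience builder for a resolved exposure sample."""
    defaults = {
        "benzene": benzene,
        "toluene": 9.5,
        "ethylbenzene": 2.0,
        "xylene": 7.3,
        "tvoc": 480.0,
    }
    defaults.update(compounds)
    return ExposureSample(
        consumer_id=consumer_id,
        measurements={k: Measurement(v, censored=False, lod=0.1) for k, v in defaults.items()},
        initial_vacuum=initial_vacuum,
        final_vacuum=final_vacuum,
        fills_per_month=fills_per_month,
        leaked=leaked,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
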