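import numpy as np
import pytest

from kogrowth.growth import GrowthCurve
from kogrowth.synthetic import SyntheticConfig


def make_curve(times, od, blank=0.0, strain="s1", medium="LB", replicate=1,
               plate="p1", well="A1"):
    return GrowthCurve(
        strain=strain, medium=medium, replicate=replicate, plate=plate,
        well=well, times=np.asarray(times, float), od=np.asarray(od, float),
        blank=blank,
    )


def exponential_curve(mu, times, od0=0.01, blank=0.0, **kw):
    times = np.asarray(times, float)
    return make_curve(times, od0 * np.exp(mu * times) + blank, blank=blank, **kw)


@pytest.fixture
def small_config():
    """A fast generator configuration for module-level tests."""
    return SyntheticConfig(n_genes=400, seed=11)
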