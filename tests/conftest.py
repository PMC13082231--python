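import numpy as np
import pytest
from hypothesis import settings

from tidepulse.core import AbundanceTable, Sample

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_samples(depth_m=25.0, months=None, origin=(2014, 11)):
    """Samples at one depth on consecutive (or given) month offsets."""
    months = range(24) if months is None else months
    oy, om = origin
    out = []
    for t in months:
        y = oy + (om - 1 + t) // 12
        m = (om - 1 + t) % 12 + 1
        out.append(Sample(
            sample_id=f"S{int(depth_m)}m_t{t:03d}", cruise_id=f"C{t:03d}",
            year=y, month=m, depth_m=depth_m,
        ))
    return out


@pytest.fixture
def toy_table():
    """3 taxa x 2 samples counts table from the basic contract example."""
    samples = make_samples(months=[0, 1])
    return AbundanceTable(
        taxa=["t1", "t2", "t3"],
        samples=samples,
        values=np.array([[5.0, 0.0], [0.0, 2.0], [1.0, 2.0]]),
        mode="counts",
    )
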