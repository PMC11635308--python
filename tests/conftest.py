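import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from thermolv import (
    Community,
    IntegrationControl,
    Species,
    TPCParams,
    default_community,
    make_tpc,
)


@pytest.fixture
def community():
    """Default three-species community (S1/S2/S3, equal K, equal n0)."""
    return default_community()


@pytest.fixture
def control():
    return IntegrationControl()


@pytest.fixture
def single_species_community():
    curve = make_tpc(TPCParams(t_min=0.0, t_opt=37.0, t_max=41.0, r_peak=1.0))
    return Community(species=(Species(id="A", curve=curve, k=1.0),), n0=(0.01,))


def random_community(rng: np.random.Generator, n: int, equal_n0: bool = False):
    """Random valid equal-capacity community with broad, staggered curves."""
    species = []
    for i in range(n):
        t_opt = float(rng.uniform(28.0, 40.0))
        params = TPCParams(
            t_min=t_opt - float(rng.uniform(20.0, 40.0)),
            t_opt=t_opt,
            t_max=t_opt + float(rng.uniform(2.0, 8.0)),
            r_peak=float(rng.uniform(0.2, 1.5)),
        )
        species.append(Species(id=f"sp{i}", curve=make_tpc(params), k=1.0))
    if equal_n0:
        n0 = tuple(0.01 for _ in range(n))
    else:
        n0 = tuple(float(x) for x in rng.uniform(0.001, 0.02, n))
    return Community(species=tuple(species), n0=n0)
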