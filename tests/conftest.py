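import numpy as np
import pytest

from phlink.occupancy import OccupancyTrajectory, SiteDefinition
from phlink.synthetic import (
    TitrationModelSpec,
    demo_study_specs,
    dimerize,
    enumerate_exact,
)

PH_KNOTS = np.arange(3.0, 8.01, 1.0)


@pytest.fixture(scope="session")
def demo_specs():
    """The shipped 4-site monomer/dimer synthetic study."""
    return demo_study_specs()


@pytest.fixture(scope="session")
def chain3_spec():
    """3-site chain of acids with repulsive nearest-neighbour couplings.

    The outer pair has no direct coupling, so its correlation is mediated
    through the middle site: outer pair positive, both inner pairs
    negative.
    """
    sites = (
        SiteDefinition("ASP1", "acid"),
        SiteDefinition("ASP2", "acid"),
        SiteDefinition("ASP3", "acid"),
    )
    W = np.array(
        [[0.0, 6.0, 0.0], [6.0, 0.0, 6.0], [0.0, 6.0, 0.0]]
    )
    return TitrationModelSpec(sites=sites, pkas=(4.5, 4.5, 4.5), coupling=W)


@pytest.fixture(scope="session")
def exact_demo(demo_specs):
    m, d = demo_specs
    return enumerate_exact(m, PH_KNOTS), enumerate_exact(d, PH_KNOTS)


def bernoulli_trajectory(p, n_frames, seed, label="ASP1", kind="acid", pH=4.0):
    rng = np.random.default_rng(seed)
    occ = (rng.random((n_frames, 1)) < p).astype(np.uint8)
    return OccupancyTrajectory(
        sites=(SiteDefinition(label, kind),),
        times=np.arange(1.0, n_frames + 1.0),
        occupancies=occ,
        pH=pH,
    )


@pytest.fixture
def toy_trajectory():
    """3-site, 6-frame deterministic trajectory."""
    sites = (
        SiteDefinition("ASP1", "acid"),
        SiteDefinition("GLU2", "acid"),
        SiteDefinition("HIS3", "base"),
    )
    occ = np.array(
        [
            [1, 0, 1],
            [1, 1, 1],
            [0, 1, 1],
            [0, 0, 0],
            [1, 0, 1],
            [0, 1, 0],
        ],
        dtype=np.uint8,
    )
    return OccupancyTrajectory(
        sites=sites,
        times=10.0 * np.arange(1, 7),
        occupancies=occ,
        pH=4.5,
        replicate_id="r1",
    )
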