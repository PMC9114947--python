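import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from epiclover.data import (
    BinaryMarkerMatrix,
    DistanceMatrix,
    MsapProfilePair,
    SampleRecord,
    SiteRecord,
)
from epiclover.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast integration tests: 2 habitats x 3 pops x 6
    individuals, 30 AFLP loci, 25 MSAP fragments."""
    return SimulationConfig(
        n_groups=2, pops_per_group=3, n_per_pop=6,
        n_aflp_loci=30, n_msap_fragments=25, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study (2 x 5 x 16, 124 loci, 159 fragments)."""
    return simulate_study(SimulationConfig(seed=7))


def random_binary_matrix(rng, n=8, m=10, label="AFLP") -> BinaryMarkerMatrix:
    return BinaryMarkerMatrix(
        [f"s{i}" for i in range(n)],
        [f"m{j}" for j in range(m)],
        (rng.random((n, m)) < 0.5).astype(int),
        label=label,
    )


def random_profile_pair(rng, n=6, f=8) -> MsapProfilePair:
    """Random valid HpaII/MspI pair via random u/m/h/absent states."""
    states = rng.integers(0, 4, size=(n, f))
    calls = {0: (1, 1), 1: (0, 1), 2: (1, 0), 3: (0, 0)}
    hpa = np.array([[calls[s][0] for s in row] for row in states])
    msp = np.array([[calls[s][1] for s in row] for row in states])
    ids = [f"s{i}" for i in range(n)]
    frags = [f"f{j}" for j in range(f)]
    return MsapProfilePair(
        hpa=BinaryMarkerMatrix(ids, frags, hpa, label="HpaII"),
        msp=BinaryMarkerMatrix(ids, frags, msp, label="MspI"),
    )


def random_distance_matrix(rng, n=10, name="") -> DistanceMatrix:
    pts = rng.standard_normal((n, 2))
    return DistanceMatrix([f"x{i}" for i in range(n)], squareform(pdist(pts)), name=name)


def two_habitat_samples(n_groups=2, pops_per_group=2, n_per_pop=4):
    samples = []
    for g in range(n_groups):
        hab = ("CG", "OM")[g] if n_groups == 2 else f"H{g}"
        for k in range(pops_per_group):
            pop = f"g{g}p{k}"
            for i in range(n_per_pop):
                samples.append(SampleRecord(f"{pop}_i{i}", pop, hab))
    return samples
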