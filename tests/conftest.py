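import numpy as np
import pytest

from dyntopo import ParcellatedTimeSeries, SyntheticSpec, generate_modular_bold


@pytest.fixture
def labels10():
    return [f"r{i}" for i in range(10)]


@pytest.fixture
def random_ts():
    rng = np.random.default_rng(7)
    return ParcellatedTimeSeries(
        data=rng.standard_normal((60, 5)),
        tr=2.2,
        region_labels=[f"r{i}" for i in range(5)],
    )


@pytest.fixture(scope="session")
def strong_modular_run():
    """Strong-contrast planted 4-module run shared by recovery tests."""
    spec = SyntheticSpec(
        n_regions=40,
        module_sizes=(10, 10, 10, 10),
        n_frames=500,
        within_coupling=0.8,
        between_coupling_by_state={"rest": 0.1},
        seed=11,
    )
    return generate_modular_bold(spec)


def two_clique_graph():
    """Two disjoint 3-cliques of unit positive weight; planted 2-module split."""
    w = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    planted = np.array([1, 1, 1, 2, 2, 2])
    return w, planted
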