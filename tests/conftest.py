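import warnings

import numpy as np
import pytest

from netnet import (
    Network,
    NoisyOracleClassifier,
    build_bsi,
    build_mt,
    generate_web_collection,
    make_fixture_suite,
    parse_topology,
    reference_registry,
)


@pytest.fixture
def path3():
    return Network(["a", "b", "c"], np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))


@pytest.fixture
def k3():
    return Network(["x", "y", "z"], np.ones((3, 3)) - np.eye(3))


@pytest.fixture
def k22():
    adj = np.zeros((4, 4))
    adj[:2, 2:] = adj[2:, :2] = 1.0
    return Network(
        ["p1", "p2", "q1", "q2"], adj, bipartite_partition=(["p1", "p2"], ["q1", "q2"])
    )


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(0)


@pytest.fixture(scope="session")
def registry():
    return reference_registry()


@pytest.fixture(scope="session")
def webs():
    return generate_web_collection(4, seed=7)


@pytest.fixture(scope="session")
def bsi_small(webs):
    return build_bsi(webs, seed=7)


@pytest.fixture(scope="session")
def mt_small(bsi_small):
    """Meta-table from a strong and a weak synthetic base classifier."""
    strong = NoisyOracleClassifier(parse_topology("MLP 18:18-8-1:1"), accuracy=0.85, seed=7)
    weak = NoisyOracleClassifier(parse_topology("LNN 16:16-1:1"), accuracy=0.15, seed=8)
    x = bsi_small[[c for c in bsi_small.columns if c.startswith(("Sh_", "dSh_"))]]
    y = bsi_small["A_ij"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strong.fit(x, y)
        weak.fit(x, y)
    return build_mt(bsi_small, [strong, weak])
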