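import numpy as np
import pytest

from grip import PPINetwork, RegulationProblem, SyntheticSpec, generate_instance
import networkx as nx


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def path_graph_net():
    """A - B - C path as a physical PPI network."""
    g = nx.Graph()
    g.add_edge("A", "B", interaction_type="physical")
    g.add_edge("B", "C", interaction_type="physical")
    return PPINetwork(graph=g)


def make_problem(rng, m=8, n=5, rho=1.0, lam=0.0, k=2, metric_S=True):
    """Small random problem; S is a planar L1 metric so it is a true metric."""
    X = rng.standard_normal((m, n))
    beta = np.zeros(n)
    beta[: min(2, n)] = [1.0, -0.7][: min(2, n)]
    y = X @ beta + 0.3 * rng.standard_normal(m)
    if metric_S:
        pts = rng.random((n, 2)) * 3
        S = np.abs(pts[:, None, :] - pts[None, :, :]).sum(axis=2)
    else:
        S = np.zeros((n, n))
    np.fill_diagonal(S, 0.0)
    return RegulationProblem(y=y, X=X, tf_ids=[f"T{i}" for i in range(n)],
                             S=S, rho=rho, lam=lam, k=k)


@pytest.fixture
def small_problem(rng):
    return make_problem(rng)


@pytest.fixture(scope="session")
def default_instance():
    """One planted instance under the default study conditions."""
    return generate_instance(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_instance():
    return generate_instance(
        SyntheticSpec(seed=11, noise_sd=0.0, decoy={"enabled": False}))
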