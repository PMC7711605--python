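import warnings

import numpy as np
import pytest

import tagnet as tg


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def two_node_model():
    m = tg.PathModel(nodes=["x1", "x2"])
    m.add_edge("x1", "x2")
    return m


@pytest.fixture
def chain_model():
    m = tg.PathModel(nodes=["x1", "x2", "x3"])
    m.add_edge("x1", "x2")
    m.add_edge("x2", "x3")
    return m


def random_path_model(rng: np.random.Generator, q: int) -> tuple:
    """Random acyclic path model with unit error variances; returns
    (model, theta)."""
    nodes = [f"v{i}" for i in range(q)]
    m = tg.PathModel(nodes=nodes)
    weights = []
    for j in range(q):
        for i in range(j):
            if rng.random() < 0.4:
                m.add_edge(nodes[i], nodes[j])
                weights.append(rng.uniform(-0.7, 0.7))
    theta = np.array(weights + [1.0] * q)
    return m, theta


@pytest.fixture
def random_model_factory():
    return random_path_model


def sample_cov(model, theta, n, seed):
    df, _ = tg.gen_sem_data(model, theta, n, seed)
    return np.cov(df.to_numpy(), rowvar=False, ddof=1), df
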