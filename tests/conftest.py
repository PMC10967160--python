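import numpy as np
import pandas as pd
import pytest

from nssinet import SimConfig, make_true_network, sample_likert
from nssinet.ggm import network_from_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_world():
    """A 10-node simulated world (8 function items + the two total-score
    nodes) small enough for fast estimation tests."""
    labels = tuple(f"F{i}" for i in range(1, 9)) + ("PHQ9", "GAD7")
    comm = {f: "nssi_function" for f in labels[:8]}
    comm.update({"PHQ9": "depressive", "GAD7": "anxious"})
    cfg = SimConfig(
        n=600, seed=42, node_labels=labels, communities=comm, sparsity=10 / 45
    )
    truth = make_true_network(cfg)
    table = sample_likert(truth, cfg)
    return cfg, truth, table


@pytest.fixture
def toy_table():
    """Six participants, four GAD items — tiny deterministic table."""
    frame = pd.DataFrame(
        {
            "GAD1": [0, 1, 2, 3, 1, 2],
            "GAD2": [1, 1, 3, 2, 0, 2],
            "GAD3": [3, 0, 2, 2, 1, 1],
            "GAD4": [0, 2, 1, 3, 3, 0],
        }
    )
    return frame


def random_network(rng, p, density=0.5, communities=None, negative_frac=0.3):
    """A random symmetric weighted network for metric tests."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.uniform() < density:
                w = rng.uniform(0.05, 0.9)
                if rng.uniform() < negative_frac:
                    w = -w
                W[i, j] = W[j, i] = w
    return network_from_weights(W, communities=communities)
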