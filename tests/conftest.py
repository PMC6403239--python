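import numpy as np
import pandas as pd
import pytest

from lopnet.graphs import BinaryGraph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def graph_from_adj(adj) -> BinaryGraph:
    adj = np.asarray(adj, dtype=np.uint8)
    density = adj.sum() / (adj.shape[0] * (adj.shape[0] - 1))
    return BinaryGraph(adjacency=adj, density=float(density))


def make_response_table(yes_matrix, rt=900.0) -> pd.DataFrame:
    """Build a ResponseTable from a participants x events 0/1 matrix."""
    yes_matrix = np.asarray(yes_matrix)
    P, E = yes_matrix.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(1, P + 1), E),
            "event_id": np.tile(np.arange(1, E + 1), P),
            "response": np.where(yes_matrix.ravel() > 0, "yes", "no"),
            "rt_ms": rt,
        }
    )
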