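import math

import numpy as np
import pytest

from clockmorph.traces import NeuronTrace, TraceNode


def random_trace(rng: np.random.Generator, n_nodes: int = 30,
                 neuron_class: str = "sLNv", start_id: int = 1) -> NeuronTrace:
    """Random tree trace with strictly positive x-y edge lengths."""
    nodes = [TraceNode(start_id, 1, float(rng.normal(0, 5)),
                       float(rng.normal(0, 5)), 0.0, 0.5, None)]
    for i in range(1, n_nodes):
        parent = nodes[rng.integers(0, len(nodes))]
        angle = rng.uniform(0, 2 * math.pi)
        step = rng.uniform(0.5, 4.0)
        nodes.append(
            TraceNode(
                start_id + i, 2,
                parent.x + step * math.cos(angle),
                parent.y + step * math.sin(angle),
                float(rng.normal(0, 1)),
                float(rng.uniform(0.1, 1.0)),
                parent.node_id,
            )
        )
    return NeuronTrace(nodes, neuron_class, f"rand_{start_id}")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
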