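import numpy as np
import pytest

from nucleoshift.array_io import NUCLEOSOMAL, SignalSet
from nucleoshift.synthetic_data import simulate_layout


@pytest.fixture
def tiny_layout():
    """Two 600-bp windows tiled with twelve 50-bp probes each."""
    return simulate_layout(2, span=600, probe_length=50, step=50, seed=0)


@pytest.fixture
def one_window_layout():
    return simulate_layout(1, span=600, probe_length=50, step=50, seed=0)


def make_signal(layout, values, genotype="WT", channel=NUCLEOSOMAL, replicate_ids=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if replicate_ids is None:
        replicate_ids = [f"pool{i + 1}" for i in range(values.shape[1])]
    return SignalSet(
        genotype=genotype,
        channel=channel,
        replicate_ids=list(replicate_ids),
        probe_ids=layout.probe_ids,
        values=values,
    )


@pytest.fixture
def signal_factory():
    return make_signal
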