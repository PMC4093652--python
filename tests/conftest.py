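import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def periodic_pair_stream(
    n_cycles: int,
    cycle: int = 20,
    lag: int = 5,
    p_second: float = 1.0,
    n_events: int = 2,
    seed: int = 0,
):
    """Event A at the start of every cycle; event B ``lag`` iterations later
    with probability ``p_second``. Returns the (T, K) stream and the
    iterations at which B was due but omitted."""
    rng = np.random.default_rng(seed)
    stream = np.zeros((n_cycles * cycle, n_events))
    omitted = []
    for c in range(n_cycles):
        t0 = c * cycle
        stream[t0, 0] = 1
        if rng.random() < p_second:
            stream[t0 + lag, 1] = 1
        else:
            omitted.append(t0 + lag)
    return stream, np.array(omitted, dtype=int)
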