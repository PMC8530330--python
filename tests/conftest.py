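import numpy as np
import pytest

from pupilkinetics import SimulationSpec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_video():
    """A short synthetic video shared by tests that only need a plausible signal."""
    return simulate(SimulationSpec(seed=11, duration_s=120.0, n_reactions=3))


def forward_fill_oracle(sparse, total):
    """Independent two-pass fill: forward fill, then leading backfill."""
    pupil = [None] * total
    limbus = [None] * total
    last = None
    for i in range(total):
        if i in sparse:
            last = sparse[i]
        if last is not None:
            pupil[i], limbus[i] = last
    first = sparse[min(sparse)]
    for i in range(total):
        if pupil[i] is None:
            pupil[i], limbus[i] = first
    return np.array(pupil), np.array(limbus)
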