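import numpy as np
import pytest

from citrusect.synthetic import FruitSpec, render_fruit


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_fruit():
    """One default-spec rendered fruit, shared across tests (read-only)."""
    spec = FruitSpec()
    image, masks = render_fruit(spec, np.random.default_rng(7))
    return spec, image, masks


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
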