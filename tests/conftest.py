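import numpy as np
import pytest

from spatfda import (
    MarkedPointPattern,
    ObservationWindow,
    PatternSimConfig,
    simulate_pattern,
    toy4,
)


@pytest.fixture
def toy4_pattern() -> MarkedPointPattern:
    return toy4()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_marked_pattern(seed: int, n_max: int = 50) -> MarkedPointPattern:
    """Small random two-type marked pattern for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = rng.integers(8, n_max + 1)
    win = ObservationWindow(0.0, 1.0, 0.0, 1.5)
    x = rng.uniform(win.xmin, win.xmax, n)
    y = rng.uniform(win.ymin, win.ymax, n)
    types = np.where(rng.uniform(size=n) < 0.5, "a", "b").astype(object)
    # guarantee both types present with >= 2 points each
    types[:2] = "a"
    types[2:4] = "b"
    marks = {"m": rng.normal(size=n)}
    return MarkedPointPattern(x=x, y=y, types=types, marks=marks, window=win)


@pytest.fixture
def poisson_pattern() -> MarkedPointPattern:
    cfg = PatternSimConfig(process="random_labeling", intensity=500.0)
    return simulate_pattern(cfg, seed=42)
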