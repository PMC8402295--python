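import numpy as np
import pytest

from tristage.data_io import Dataset


def make_dataset(X, y, names=None) -> Dataset:
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    return Dataset(X, np.asarray(y), np.asarray(names, dtype=object))


@pytest.fixture
def balanced_binary():
    """40 samples, 6 features: f0 equals the class, f1 constant, f2 a copy
    of f0, f3-f5 seeded noise. Labels alternate A/B."""
    rng = np.random.default_rng(7)
    y = np.array(["A", "B"] * 20, dtype=object)
    code = (y == "B").astype(float)
    X = np.column_stack(
        [code, np.full(40, 3.0), code, rng.normal(size=(40, 3)).T[0],
         rng.normal(size=40), rng.normal(size=40)]
    )
    return make_dataset(X, y)


class StubRng:
    """Deterministic stand-in for numpy Generator in update-rule tests."""

    def __init__(self, values):
        self.values = list(values)

    def _next(self):
        return self.values.pop(0)

    def random(self, size=None):
        if size is None:
            return self._next()
        size = (size,) if np.isscalar(size) else tuple(size)
        return np.array([self._next() for _ in range(int(np.prod(size)))]).reshape(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        raw = self.random(size)
        return low + (high - low) * raw
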