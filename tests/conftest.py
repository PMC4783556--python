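import numpy as np
import pytest

from catfuzz import CategoricalDataset


@pytest.fixture
def toy4() -> CategoricalDataset:
    """Four records over two features: F1 in {x, y}, F2 in {a, b}."""
    return CategoricalDataset.from_cells(
        [["x", "a"], ["x", "a"], ["x", "b"], ["y", "b"]]
    )


def random_dataset(rng: np.random.Generator, n=30, s=3, max_p=5) -> CategoricalDataset:
    """A small random categorical dataset for property tests."""
    cells = np.empty((n, s), dtype=object)
    for l in range(s):
        p = int(rng.integers(2, max_p + 1))
        cells[:, l] = [f"v{c}" for c in rng.integers(p, size=n)]
    return CategoricalDataset.from_cells(cells)
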