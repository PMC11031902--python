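"""Shared fixtures: the worked-example network and small random helpers.

The demo network is the worked two-layer example over 7 binary inputs:
three first-layer boxes reading 3, 2 and 2 features, with explicitly
stated truth tables, used throughout as a ground-truth fixture.
"""

import numpy as np
import pytest

from noisecut import (
    Dataset,
    FNStructure,
    FunctionalNetwork,
    TruthTable,
    enumerate_dataset,
)

# truth tables in decimal-code order (code 1 = all-zero input)
DEMO_F1 = (0, 0, 1, 1, 1, 0, 1, 0)
DEMO_F2 = (1, 0, 1, 1)
DEMO_F3 = (1, 1, 0, 0)
DEMO_FO = (0, 0, 1, 1, 1, 0, 1, 0)
DEMO_BOXES = (3, 2, 2)


@pytest.fixture(scope="session")
def demo_network() -> FunctionalNetwork:
    structure = FNStructure(DEMO_BOXES)
    return FunctionalNetwork(
        structure,
        (TruthTable(3, DEMO_F1), TruthTable(2, DEMO_F2), TruthTable(2, DEMO_F3)),
        TruthTable(3, DEMO_FO),
    )


@pytest.fixture(scope="session")
def demo_enumeration(demo_network) -> Dataset:
    return enumerate_dataset(demo_network)


def random_dataset(
    rng: np.random.Generator, n_samples: int, boxes: tuple[int, ...]
) -> tuple[Dataset, FNStructure]:
    """Random binary rows with random labels (not network-generated)."""
    structure = FNStructure(boxes)
    X = rng.integers(0, 2, size=(n_samples, structure.n_features))
    y = rng.integers(0, 2, size=n_samples)
    return Dataset(X, y), structure
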