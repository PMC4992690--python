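import numpy as np
import pytest

from metmaxstruct import Collection, MoleculeRecord, worked_example_set


def naive_bit_counts(bits_a, bits_b):
    """Independent per-position oracle for (a, b, c) overlap counts."""
    a = b = c = 0
    for x, y in zip(bits_a, bits_b):
        if x and y:
            c += 1
        elif x:
            a += 1
        elif y:
            b += 1
    return a, b, c


def collection_with_mws(mws, label, seed=0, density=0.3):
    """Synthetic collection with prescribed molecular weights."""
    rng = np.random.default_rng(seed)
    mws = np.asarray(mws, dtype=float)
    matrix = (rng.random((mws.size, 166)) < density).astype(np.uint8)
    records = [
        MoleculeRecord(f"{label}{i:05d}", "", float(w), label)
        for i, w in enumerate(mws)
    ]
    return Collection(records, matrix, "synthetic")


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_set()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
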