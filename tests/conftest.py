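import numpy as np
import pytest

from qtyshift import (
    SyntheticProteinSpec,
    generate_helix_coords,
    generate_membrane_protein,
)


@pytest.fixture(scope="session")
def synthetic_records():
    """50 seeded synthetic membrane proteins with varied architecture."""
    records = []
    for seed in range(50):
        spec = SyntheticProteinSpec(
            n_tm_segments=6 + seed % 7,
            tm_length=18 + seed % 5,
            loop_length=10 + seed % 25,
            livf_fraction_tm=0.3 + 0.4 * ((seed * 7) % 10) / 10.0,
            seed=seed,
        )
        records.append(generate_membrane_protein(spec))
    return records


@pytest.fixture(scope="session")
def helix100():
    return generate_helix_coords(100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
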