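import numpy as np
import pandas as pd
import pytest

from rngxe.synthdata import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Small but structured herd-book: enough herds for a usable gradient."""
    return SimulationConfig(
        n_herds=30, n_sires=40, daughters_per_sire=6, records_per_cow=5, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def trio_pedigree():
    """Sire, dam, offspring — the textbook A-inverse case."""
    return pd.DataFrame({
        "animal_id": [1, 2, 3],
        "sire_id": [0, 0, 1],
        "dam_id": [0, 0, 2],
        "sex": ["M", "F", "F"],
        "birth_date": ["2000-01-01", "2000-01-01", "2003-05-01"],
    })


def random_pedigree(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random acyclic pedigree: parents always have lower ids."""
    sires, dams = [], []
    for i in range(n):
        if i < 2 or rng.random() < 0.3:
            sires.append(0)
            dams.append(0)
        else:
            sires.append(int(rng.integers(1, i + 1)))
            d = int(rng.integers(1, i + 1))
            dams.append(0 if d == sires[-1] else d)
    return pd.DataFrame({
        "animal_id": np.arange(1, n + 1), "sire_id": sires, "dam_id": dams,
    })
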