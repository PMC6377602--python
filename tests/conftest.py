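import numpy as np
import pandas as pd
import pytest

from cooccur.community import CommunityMatrix, PresenceMatrix
from cooccur.synthetic import generate_landscape, mdv_like_config, mdv_occupancy_from_counts


def make_presence(arr, species=None) -> PresenceMatrix:
    arr = np.asarray(arr, dtype=np.int8)
    species = species or [f"sp{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=species,
                      index=[f"s{i}" for i in range(arr.shape[0])])
    return PresenceMatrix(df, filtered=bool((arr.sum(axis=1) > 0).all()))


def make_community(arr, species=None) -> CommunityMatrix:
    arr = np.asarray(arr, dtype=float)
    species = species or [f"sp{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, columns=species,
                      index=[f"s{i}" for i in range(arr.shape[0])])
    return CommunityMatrix(df)


@pytest.fixture(scope="session")
def mdv_matrix() -> PresenceMatrix:
    """Reconstructed 314 x 3 occupancy matrix (published cell counts)."""
    return mdv_occupancy_from_counts()


@pytest.fixture(scope="session")
def mdv_landscape():
    """One mdv_like synthetic landscape, shared across tests."""
    return generate_landscape(mdv_like_config(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
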