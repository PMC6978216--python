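import numpy as np
import pytest

from svdnet.connectome import ConnectivityMatrix, Parcellation


@pytest.fixture
def abc_parcellation():
    return Parcellation(("A", "B", "C"))


@pytest.fixture
def small_rich_parcellation():
    """Four regions, two of them rich-club."""
    return Parcellation(("R1", "R2", "P1", "P2"), rich_club_labels=("R1", "R2"))


def random_matrix(rng, n, density=0.5, rich_labels=()):
    """Random symmetric weighted matrix over n regions."""
    labels = tuple(f"r{i}" for i in range(n))
    parc = Parcellation(labels, tuple(labels[i] for i in rich_labels))
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    vals = rng.uniform(0.2, 5.0, iu.size) * present
    w[iu, ju] = vals
    w += w.T
    return ConnectivityMatrix(w, parc)


@pytest.fixture
def matrix_factory():
    return random_matrix
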