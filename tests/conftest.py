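import numpy as np
import pandas as pd
import pytest

from panmarker import GroupLabels, PresenceAbsenceMatrix


def random_matrix_and_labels(rng, n_genomes=None, n_clusters=None, p=0.5):
    """A random presence/absence matrix with a random two-group split."""
    n_genomes = n_genomes or int(rng.integers(4, 31))
    n_clusters = n_clusters or int(rng.integers(2, 16))
    cells = (rng.random((n_genomes, n_clusters)) < p).astype(np.int8)
    genomes = [f"g{i:03d}" for i in range(n_genomes)]
    clusters = [f"c{j:03d}" for j in range(n_clusters)]
    matrix = PresenceAbsenceMatrix(
        pd.DataFrame(cells, index=genomes, columns=clusters))
    # guarantee both groups non-empty
    n_target = int(rng.integers(1, n_genomes))
    labels = GroupLabels({g: ("target" if i < n_target else "background")
                          for i, g in enumerate(genomes)})
    return matrix, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture
def small_matrix():
    return PresenceAbsenceMatrix(pd.DataFrame(
        [[1, 1, 0, 1],
         [1, 1, 0, 0],
         [1, 0, 1, 1],
         [0, 0, 1, 0],
         [1, 0, 1, 0]],
        index=["gA", "gB", "gC", "gD", "gE"],
        columns=["c1", "c2", "c3", "c4"]))


@pytest.fixture
def small_labels():
    return GroupLabels(
        {"gA": "target", "gB": "target",
         "gC": "background", "gD": "background", "gE": "background"},
        {"gC": "delta", "gD": "delta"})
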