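import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from perturbnuc.simulate import SimConfig, make_fixture, simulate_experiment
from perturbnuc.types import (
    CellByFeatureCounts,
    GenomicInterval,
    GuideLibrary,
    GuideRecord,
)


@pytest.fixture(scope="session")
def well_separated():
    """One vector per cell, signal far above ambient: assignment is easy."""
    return make_fixture("well_separated_assignment")


@pytest.fixture(scope="session")
def edited_all():
    """Every assigned cell edited at its target (edit rate 1)."""
    return make_fixture("edited_all")


@pytest.fixture(scope="session")
def chimera_stress():
    """20% chimeric amplicon reads recorded in truth."""
    return make_fixture("chimera_stress")


@pytest.fixture(scope="session")
def two_pair_library():
    """A minimal hand-built two-pair library with one NT control pair."""
    win = lambda s: GenomicInterval("chr1", s, s + 30)
    return GuideLibrary(
        [
            GuideRecord("A-g1", "A" * 10 + "C" * 10, "A", "g1", "geneA", "targeting", win(100)),
            GuideRecord("A-g2", "C" * 10 + "G" * 10, "A", "g2", "geneA", "targeting", win(300)),
            GuideRecord("B-g1", "G" * 10 + "T" * 10, "B", "g1", "geneB", "targeting", win(900)),
            GuideRecord("B-g2", "T" * 10 + "A" * 10, "B", "g2", "geneB", "targeting", win(1100)),
        ]
    )


def random_counts(rng, n_cells=20, n_features=5, modality="guide", lam=2.0):
    mat = rng.poisson(lam, size=(n_cells, n_features))
    return CellByFeatureCounts(
        sparse.csr_matrix(mat),
        [f"c{i}" for i in range(n_cells)],
        [f"f{j}" for j in range(n_features)],
        modality,
    )
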