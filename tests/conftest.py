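import numpy as np
import pandas as pd
import pytest

from floraleaf import diffexpr, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A 2-chromosome genome with 60 genes, shared across read-only tests."""
    return simulate.make_genome(2, 200_000, 60, seed=101)


@pytest.fixture(scope="session")
def design():
    return diffexpr.SampleDesign.default()


@pytest.fixture(scope="session")
def de_counts(design):
    """Counts with balanced up/down planted clusters plus nulls."""
    profiles = np.array([
        [1.0, 4.0, 4.0, 4.0],
        [4.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 1.0, 1.0],
    ])
    feats = [f"f{i:04d}" for i in range(600)]
    assignment = np.array([0] * 150 + [1] * 150 + [2] * 300)
    counts, truth = simulate.make_counts(
        feats, design, profiles, dispersion=0.1, seed=77,
        cluster_assignment=assignment)
    return counts, truth
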