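import numpy as np
import pandas as pd
import pytest

from domnet.synthetic import PlantedStructure, StudyDesign, generate_feature_matrix


@pytest.fixture(scope="session")
def default_run():
    """Default study design and planted structure: 200 features x 120
    leachate samples with three planted blocks plus background."""
    matrix, meta, truth = generate_feature_matrix()
    return matrix, meta, truth


@pytest.fixture(scope="session")
def noise_free_run():
    structure = PlantedStructure(noise_sigma=0.0)
    matrix, meta, truth = generate_feature_matrix(structure=structure)
    return matrix, meta, truth


@pytest.fixture(scope="session")
def small_design():
    """A reduced design for round-trip and pipeline tests."""
    return StudyDesign(
        litter_types=("beech", "oak"),
        sites=("hainich",),
        replicates=1,
        time_points=(0, 2, 22),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["mz", "intensity", "sn"])
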