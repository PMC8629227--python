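import numpy as np
import pandas as pd
import pytest

from traitrank.genome import build_genome_map, simulate_f2
from traitrank.traits import build_architectures, simulate_phenotypes


@pytest.fixture(scope="session")
def default_map():
    return build_genome_map()


@pytest.fixture(scope="session")
def default_table(default_map):
    """One full-size replicate: 500 F2 individuals, 11 traits, scenario 1."""
    genotypes = simulate_f2(default_map, 500, seed=11)
    archs = build_architectures(1, default_map, seed=11)
    return simulate_phenotypes(genotypes, archs, seed=12)


@pytest.fixture(scope="session")
def linear_xy():
    """Small regression problem with one informative predictor."""
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
    y = 2.0 * X["a"].to_numpy()
    return X, y
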