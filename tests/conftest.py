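import numpy as np
import pandas as pd
import pytest

from jloe import SynthConfig, generate_population


@pytest.fixture(scope="session")
def population():
    """Default synthetic screen population with its truth table."""
    return generate_population(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def colorectal(population):
    """(BF submatrix, expression, truth) for the first synthetic tissue."""
    bf, expr, ann, truth = population
    screens = ann.screens_for_tissue("colorectal")
    return bf[screens], expr, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_bf():
    """Hand-built 4-gene x 3-screen BF matrix with known hit structure.

    Hits at BF >= 10: s1 -> {g1, g2}; s2 -> {g2, g3}; s3 -> {g2}.
    """
    return pd.DataFrame(
        {
            "s1": [12.0, 15.0, -5.0, -20.0],
            "s2": [3.0, 11.0, 10.0, -20.0],
            "s3": [-1.0, 30.0, 2.0, -20.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene"),
    )
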