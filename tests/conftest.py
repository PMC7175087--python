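import numpy as np
import pytest

from ribodeplete import (
    Alignment,
    AlignmentRecipe,
    NNParameterTable,
    gap_mask,
    make_alignment,
)


@pytest.fixture(scope="session")
def nn_table():
    return NNParameterTable.default()


@pytest.fixture(scope="session")
def blockish_alignment():
    """8-species alignment with ten conserved 40-nt blocks, divergent spacers."""
    recipe = AlignmentRecipe.evenly_spaced(seed=11)
    a, blocks = make_alignment(recipe)
    return a, gap_mask(a), blocks


@pytest.fixture(scope="session")
def conserved_alignment():
    """Fully conserved, gap-free 8-species alignment (one admissible run)."""
    a, _ = make_alignment(AlignmentRecipe(
        n_species=8, total_length=200, conserved_blocks=((0, 200),), seed=3,
    ))
    return a, gap_mask(a)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
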