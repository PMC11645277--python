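import numpy as np
import pytest

from vesselfish import (
    CodebookSpec,
    make_codebook,
    make_random_scene,
    render_rounds,
)


@pytest.fixture(scope="session")
def codebook30():
    """Mid-size codebook shared across decoding tests."""
    return make_codebook(CodebookSpec(n_genes=30, n_unused=8, seed=5))


@pytest.fixture(scope="session")
def clean_scene(codebook30):
    """Noise-free, offset-free scene plus rendered stacks and truth."""
    scene = make_random_scene(
        codebook30.genes, 60, shape=(128, 128, 10), seed=5, noise_sd=0.0
    )
    stacks, truth = render_rounds(scene, codebook30)
    return scene, stacks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
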