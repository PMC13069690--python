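import numpy as np
import pytest

from nichegrad import SyntheticTissueConfig, fixture_config, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """The shipped small fixture: 400 cells x 60 genes, nested-disc layout."""
    return generate_tissue(fixture_config("small"))


@pytest.fixture(scope="session")
def gradient_tissue():
    """Half-plane layout with strong gradient genes for power/sign checks."""
    cfg = SyntheticTissueConfig(
        n_cells=400, layout="half_planes", n_marker_genes=0,
        n_gradient_genes=50, n_null_genes=950, gradient_slope=2.0,
        noise_sd=0.5, dropout_rate=0.2, seed=7,
    )
    return generate_tissue(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
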