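import numpy as np
import pytest

from mirburst import synthio


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down study: 12 planted miRNAs on one 40-kb scaffold."""
    return synthio.SimConfig(
        seed=42,
        n_scaffolds=1,
        scaffold_length=60_000,
        n_mirnas=12,
        n_families=2,
        family_size=3,
        family_spacing_bp=("uniform", 3_000),
        n_tissue_specific=3,
        n_conserved=4,
        reads_per_library=6_000,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Genome + truth + expression for the scaled-down study."""
    genome, truth = synthio.generate_genome(small_cfg)
    expression = synthio.generate_expression(truth, small_cfg)
    return genome, truth, expression


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
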