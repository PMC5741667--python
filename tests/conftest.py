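import numpy as np
import pytest

from repeatburst.simulate import TEFamilySpec, plant_copies_in_genome, simulate_te_copies


@pytest.fixture(scope="session")
def planted_single_family():
    """30 exact copies of a 2 kb repeat planted in unique background."""
    spec = TEFamilySpec("famA", 2000, [0.0], [30], 0.3)
    fam = simulate_te_copies(spec, seed=5)
    genome, truth = plant_copies_in_genome(
        130000, fam.copies, seed=1, family_ids=["famA"] * 30
    )
    return fam, genome, truth


@pytest.fixture(scope="session")
def two_burst_family():
    """Two-burst family (ages 0.1/0.6, rate 0.3, 50+50 copies of 2 kb)."""
    spec = TEFamilySpec("famB", 2000, [0.1, 0.6], [50, 50], 0.3)
    return simulate_te_copies(spec, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
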