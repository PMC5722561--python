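import logging

import numpy as np
import pytest

from biomepair import (
    AbundanceTable,
    GeneratorConfig,
    TaxonLineage,
    filter_low_depth_pairs,
    simulate_cohort,
)

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size simulated cohort, depth-filtered, with its ground truth."""
    cohort, truth = simulate_cohort(GeneratorConfig(seed=1))
    cohort, _ = filter_low_depth_pairs(cohort)
    return cohort, truth


SMALL_CONFIG = GeneratorConfig(
    n_patients=10,
    n_bacterial_phyla=6,
    n_fungal_phyla=3,
    n_bacterial_genera=18,
    n_fungal_genera=8,
    planted_effects=((0, 1.0), (2, -1.5), (20, 1.0)),
    seed=5,
)


@pytest.fixture(scope="session")
def small_cohort():
    """10-pair, 26-genus cohort for fast end-to-end tests."""
    cohort, truth = simulate_cohort(SMALL_CONFIG)
    cohort, _ = filter_low_depth_pairs(cohort)
    return cohort, truth


@pytest.fixture
def toy_table():
    """3 taxa x 2 samples with counts [[5,0],[1,2],[0,7]]."""
    taxa = [
        TaxonLineage("bacteria|GenA", "bacteria", "P1", "GenA"),
        TaxonLineage("bacteria|GenB", "bacteria", "P1", "GenB"),
        TaxonLineage("bacteria|GenC", "bacteria", "P2", "GenC"),
    ]
    return AbundanceTable(
        taxa=taxa,
        samples=["s1", "s2"],
        counts=np.array([[5, 0], [1, 2], [0, 7]]),
        rank="genus",
    )
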