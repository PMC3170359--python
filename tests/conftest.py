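import numpy as np
import pytest

from volescape.data_io import GenotypeTable
from volescape.synthetic_data import SimulationConfig, simulate_metapopulation


@pytest.fixture
def toy_two_pop() -> GenotypeTable:
    """Small two-population, two-locus table used by hand oracles."""
    calls = np.array(
        [
            # pop1
            [[1, 1], [3, 3]],
            [[1, 2], [3, 4]],
            [[2, 2], [4, 4]],
            [[1, 2], [3, 4]],
            # pop2
            [[2, 2], [4, 4]],
            [[2, 2], [3, 4]],
            [[1, 2], [4, 4]],
            [[2, 2], [4, 4]],
        ]
    )
    return GenotypeTable(
        sample_id=[f"s{i}" for i in range(8)],
        population=np.array(["p1"] * 4 + ["p2"] * 4, dtype=object),
        calls=calls,
        locus_names=["locA", "locB"],
    )


@pytest.fixture(scope="session")
def study_shape_dataset():
    """A 7-deme, 10-locus dataset with the survey's shape, plus truth."""
    cfg = SimulationConfig(
        seed=42,
        n_demes=7,
        deme_size=60,
        generations=150,
        migration="kernel",
        sigma_f=4000.0,
        sigma_m=4000.0,
        n_loci=10,
        mu_nuc=5e-4,
        sample_size=20,
        mt_sample_size=7,
        mt_length=256,
        mu_mt=2e-5,
    )
    return simulate_metapopulation(cfg)
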