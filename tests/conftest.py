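import numpy as np
import pytest

from mirratio.core_io import CountMatrix
from mirratio.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 miRs x 4 samples, no zeros, two of each class."""
    counts = np.array([
        [40, 50, 60, 70],
        [19, 21, 23, 25],
        [100, 110, 120, 130],
    ])
    return CountMatrix(
        mir_ids=["miR-a", "miR-b", "miR-c"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=counts,
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A complete synthetic cohort small enough for per-test pipelines."""
    cfg = GeneratorConfig(seed=7, n_mirs=15, n_differential_pairs=2,
                          n_duplicate_pairs=1)
    return generate_cohort(cfg)
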