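import numpy as np
import pandas as pd
import pytest

import mmresponse as mm


@pytest.fixture(scope="session")
def default_labels() -> pd.Series:
    return mm.generate_labels(mm.SyntheticConfig(n_probes=10, seed=0))


@pytest.fixture(scope="session")
def small_cohort() -> mm.SyntheticCohort:
    """118 samples, 300 probes, default planted effects — the desk-scale
    cohort most discovery tests run on."""
    return mm.generate_cohort(mm.SyntheticConfig(n_probes=300, seed=1))


@pytest.fixture(scope="session")
def cr_vs_rest(small_cohort) -> mm.BinaryContrast:
    return mm.make_contrast(small_cohort.labels, {"CR"}, {"nCR", "VGPR", "PR", "SD"})


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    """3 probes x 4 samples with simple values."""
    return pd.DataFrame(
        np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.0, 1.0, 4.0, 3.0]]),
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture
def separable_matrix() -> tuple[pd.DataFrame, mm.BinaryContrast]:
    """Two probes that perfectly separate 8 positive from 10 negative samples."""
    rng = np.random.default_rng(7)
    n_pos, n_neg = 8, 10
    pos = rng.normal([10.0, 4.0], 0.1, size=(n_pos, 2))
    neg = rng.normal([4.0, 10.0], 0.1, size=(n_neg, 2))
    samples = [f"S{i}" for i in range(n_pos + n_neg)]
    matrix = pd.DataFrame(
        np.vstack([pos, neg]).T, index=["PA", "PB"], columns=samples
    )
    contrast = mm.BinaryContrast(
        positive=tuple(samples[:n_pos]), negative=tuple(samples[n_pos:])
    )
    return matrix, contrast
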