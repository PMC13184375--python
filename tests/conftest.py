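import numpy as np
import pandas as pd
import pytest

from atrophyclust import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale 2-subtype cohort used by several integration tests."""
    return CohortConfig(
        grid_shape=(8, 8, 8),
        n_controls=40,
        n_patients_per_subtype=(15, 15),
        n_subtypes=2,
        effect_size=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 3-subtype study cohort (16^3 grid, 100 controls, 3x40)."""
    return generate_cohort(CohortConfig(seed=11))


def make_blobs(centers: np.ndarray, n_per: int, sd: float, seed: int) -> tuple:
    """Well-separated Gaussian blobs in score space, with true labels."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(c, sd, size=(n_per, len(c))) for c in centers]
    )
    y = np.repeat(np.arange(1, len(centers) + 1), n_per)
    return X, y


def covariate_frame(n: int, seed: int = 0, prefix: str = "s") -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i:03d}" for i in range(n)],
            "age": rng.uniform(55, 80, n),
            "sex": rng.integers(0, 2, n),
            "tiv": rng.normal(1400, 120, n),
            "scanner": rng.integers(0, 2, n),
        }
    )
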