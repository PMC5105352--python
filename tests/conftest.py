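import numpy as np
import pandas as pd
import pytest

from restfc.parcellation import ParcellationScheme


@pytest.fixture
def scheme10() -> ParcellationScheme:
    return ParcellationScheme.synthetic(10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160429)


def make_cohort_frame(n_male: int, n_female: int, seed: int = 0, **extra) -> pd.DataFrame:
    """Deterministic cohort table for regression tests."""
    rng = np.random.default_rng(seed)
    n = n_male + n_female
    sex = np.array(["M"] * n_male + ["F"] * n_female)
    rng.shuffle(sex)
    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{k:04d}" for k in range(n)],
            "sex": sex,
            "age_years": rng.uniform(22, 36, n),
        }
    )
    for name, values in extra.items():
        df[name] = values
    return df


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return upper | upper.T
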