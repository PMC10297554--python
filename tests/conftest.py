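import numpy as np
import pandas as pd
import pytest

from gastwin.cohort import generate_cohort
from gastwin.oracle import simulate_batch
from gastwin.cohort import split_cohort


@pytest.fixture(scope="session")
def healthy_state() -> dict:
    """A physiologically normal adult reference state."""
    return dict(v_sR=0.0, v_inR=1.0, v_sVR=0.0, v_inVR=1.0, v_nc=0,
                asht=0.02, RQ=0.8, VO2=0.25, VD_phys=0.15, CO=5.0,
                IE_ratio=0.5, Hb=9.0, FiO2=21.0, PEEP=5.0, P_EI=20.0,
                SvO2=75.0, RR=12.0, Vt=500.0, BE_a=0.0)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(400, seed=11)


@pytest.fixture(scope="session")
def labelled_cohort(small_cohort) -> pd.DataFrame:
    return simulate_batch(small_cohort)


@pytest.fixture(scope="session")
def labelled_splits(labelled_cohort):
    return split_cohort(labelled_cohort, (0.8, 0.1, 0.1), seed=5)


@pytest.fixture(scope="session")
def linear_problem():
    """Toy learnability target: outputs are a fixed linear map plus tiny noise.

    The least-squares fit bounds the achievable error, so a working trainer
    must reach a small MAE on it.
    """
    rng = np.random.default_rng(123)
    n = 2000
    X = rng.standard_normal((n, 19))
    A = rng.standard_normal((19, 4)) * 0.4
    Y = X @ A + 0.01 * rng.standard_normal((n, 4))
    from gastwin.cohort import INPUT_COLUMNS, OUTPUT_COLUMNS
    df = pd.DataFrame(X, columns=list(INPUT_COLUMNS))
    for j, c in enumerate(OUTPUT_COLUMNS):
        df[c] = Y[:, j]
    return df
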