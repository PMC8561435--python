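import numpy as np
import pytest

from ccscreen import CaseCohortData, CohortData


def make_cohort(n=40, p=3, beta=(0.5, 0.0, -0.3), censor_upper=3.0, seed=3):
    """Small Cox-model cohort with complete covariates."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    T = rng.exponential(size=n) / np.exp(Z @ np.asarray(beta))
    C = rng.uniform(0, censor_upper, size=n)
    X = np.minimum(T, C)
    Delta = (T <= C).astype(int)
    return CohortData(X=X, Delta=Delta, Z=Z, true_active=np.flatnonzero(beta))


@pytest.fixture
def small_cohort():
    return make_cohort()


@pytest.fixture
def full_cc(small_cohort):
    """Full cohort viewed as a case-cohort sample (pi = 1, no masking)."""
    return CaseCohortData.from_full_cohort(small_cohort)


@pytest.fixture
def tiny_cc():
    """10-subject case-cohort fixture with pi = 0.5 and real masking."""
    rng = np.random.default_rng(7)
    n = 10
    Z = rng.standard_normal((n, 3))
    T = rng.exponential(size=n) / np.exp(0.6 * Z[:, 0])
    C = rng.uniform(0, 2.0, size=n)
    X = np.minimum(T, C)
    Delta = (T <= C).astype(int)
    xi = (rng.uniform(size=n) < 0.5).astype(int)
    Zm = Z.copy()
    Zm[(Delta == 0) & (xi == 0)] = np.nan
    return CaseCohortData(X=X, Delta=Delta, xi=xi, Z_obs=Zm, pi=0.5)


@pytest.fixture
def hand_cc():
    """Four-subject fixture with hand-computable pi_hat values."""
    X = np.array([1.0, 2.0, 3.0, 4.0])
    Delta = np.array([1, 0, 0, 0])
    xi = np.array([0, 1, 0, 1])
    Z = np.arange(4, dtype=float).reshape(-1, 1)
    Zm = Z.copy()
    Zm[(Delta == 0) & (xi == 0)] = np.nan
    return CaseCohortData(X=X, Delta=Delta, xi=xi, Z_obs=Zm, pi=0.5)
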