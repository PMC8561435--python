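"""Synthetic cohort generator for case-cohort screening studies.

Generates full cohorts from a Cox proportional-hazards model with
equicorrelated Gaussian covariates, censoring times uniform on
``(0, tau)`` with ``tau`` calibrated by Monte-Carlo bisection to hit a
target failure rate, and Bernoulli subcohort sampling.

Two covariance presets are supported:

``exchangeable_all``
    All ``p`` covariates are standard normal with common pairwise
    correlation ``rho`` (one-factor representation).
``exchangeable_block_plus_independent``
    The first ``p - 1`` covariates form an equicorrelated block; the
    last covariate is independent standard normal.  Combined with a
    large coefficient on the first covariate and a moderate one on the
    last, this makes the last covariate a *hidden* active covariate:
    jointly important, but marginally almost uncorrelated with survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import CaseCohortData, CohortData

__all__ = [
    "SimulationDesign",
    "generate_cohort",
    "calibrate_tau",
    "draw_case_cohort",
    "pi_for_ratio",
]

_COV_STRUCTURES = ("exchangeable_all", "exchangeable_block_plus_independent")


@dataclass
class SimulationDesign:
    """Parameters of one simulated cohort design.

    Attributes
    ----------
    n : int
        Full-cohort size.
    p : int
        Covariate dimension.
    alpha : ndarray, shape (p,)
        True log-hazard-ratio vector.
    rho : float
        Common pairwise correlation of the equicorrelated covariates,
        in [0, 1).
    target_failure_rate : float
        Desired fraction of subjects with an observed event, in (0, 1).
    tau : float or None
        Censoring upper bound; censoring times are Uniform(0, tau).
        ``None`` means "calibrate to the target failure rate".
    noncase_to_case_ratio : float
        Expected sampled-noncase : case ratio used to pick the Bernoulli
        subcohort probability (1 gives a 1:1 case-cohort sample).
    cov_structure : str
        One of ``exchangeable_all`` or
        ``exchangeable_block_plus_independent``.
    """

    n: int
    p: int
    alpha: np.ndarray
    rho: float = 0.0
    target_failure_rate: float = 0.2
    tau: float | None = None
    noncase_to_case_ratio: float = 1.0
    cov_structure: str = "exchangeable_all"
    baseline_hazard: float = 1.0
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.n < 2:
            raise ValueError("cohort size n must be at least 2")
        if self.alpha.shape != (self.p,):
            raise ValueError("alpha must have length p")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 < self.target_failure_rate < 1.0):
            raise ValueError("target_failure_rate must lie in (0, 1)")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.cov_structure not in _COV_STRUCTURES:
            raise ValueError(
                f"unknown cov_structure {self.cov_structure!r}; "
                f"expected one of {_COV_STRUCTURES}"
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    @property
    def true_active(self) -> np.ndarray:
        """0-based indices of nonzero coefficients."""
        return np.flatnonzero(self.alpha != 0.0)

    @property
    def pi(self) -> float:
        """Bernoulli subcohort probability implied by the noncase:case ratio."""
        return pi_for_ratio(self.target_failure_rate, self.noncase_to_case_ratio)

    @classmethod
    def example1(
        cls,
        n: int = 500,
        p: int = 2000,
        rho: float = 0.5,
        target_failure_rate: float = 0.2,
        noncase_to_case_ratio: float = 1.0,
        tau: float | None = None,
        seed: int | None = None,
    ) -> "SimulationDesign":
        """Design with four strong covariates and one hidden one.

        alpha = (1, 1, 1, 1, -2, 0, ..., 0), all covariates
        equicorrelated.  The fifth covariate cancels against the first
        four marginally, making it hidden from marginal screening.
        """
        if p < 5:
            raise ValueError("example1 requires p >= 5")
        alpha = np.zeros(p)
        alpha[:4] = 1.0
        alpha[4] = -2.0
        return cls(
            n=n,
            p=p,
            alpha=alpha,
            rho=rho,
            target_failure_rate=target_failure_rate,
            noncase_to_case_ratio=noncase_to_case_ratio,
            cov_structure="exchangeable_all",
            tau=tau,
            seed=seed,
        )

    @classmethod
    def example2(
        cls,
        n: int = 500,
        p: int = 2000,
        rho: float = 0.0,
        target_failure_rate: float = 0.2,
        noncase_to_case_ratio: float = 1.0,
        tau: float | None = None,
        seed: int | None = None,
    ) -> "SimulationDesign":
        """Design with one dominant covariate and one independent hidden one.

        alpha = (10, 0, ..., 0, 1); the first p - 1 covariates are
        equicorrelated, the last is independent standard normal.  Only
        the first and last covariates are active.
        """
        if p < 2:
            raise ValueError("example2 requires p >= 2")
        alpha = np.zeros(p)
        alpha[0] = 10.0
        alpha[-1] = 1.0
        return cls(
            n=n,
            p=p,
            alpha=alpha,
            rho=rho,
            target_failure_rate=target_failure_rate,
            noncase_to_case_ratio=noncase_to_case_ratio,
            cov_structure="exchangeable_block_plus_independent",
            tau=tau,
            seed=seed,
        )


def _draw_covariates(design: SimulationDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    """Equicorrelated Gaussians via the one-factor representation.

    Z_j = sqrt(rho) * W + sqrt(1 - rho) * eps_j with a shared scalar
    factor W per subject gives unit variances and pairwise correlation
    rho without factorizing a p x p matrix.
    """
    p, rho = design.p, design.rho
    eps = rng.standard_normal((n, p))
    if rho == 0.0:
        return eps
    w = rng.standard_normal((n, 1))
    if design.cov_structure == "exchangeable_all":
        return math.sqrt(rho) * w + math.sqrt(1.0 - rho) * eps
    # block of p-1 equicorrelated + independent last column
    Z = np.empty((n, p))
    Z[:, : p - 1] = math.sqrt(rho) * w + math.sqrt(1.0 - rho) * eps[:, : p - 1]
    Z[:, p - 1] = eps[:, p - 1]
    return Z


def _linear_predictor_sample(
    design: SimulationDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw alpha' Z without materializing covariates (for calibration).

    Under either covariance preset alpha' Z is Gaussian with mean 0 and
    a variance that the one-factor representation makes explicit, so we
    sample it directly.
    """
    a = design.alpha
    rho = design.rho
    if design.cov_structure == "exchangeable_all":
        block = a
        extra_var = 0.0
    else:
        block = a[:-1]
        extra_var = a[-1] ** 2
    s = block.sum()
    var = rho * s**2 + (1.0 - rho) * (block**2).sum() + extra_var
    return math.sqrt(var) * rng.standard_normal(n)


def generate_cohort(design: SimulationDesign, rng: np.random.Generator | int | None = None) -> CohortData:
    """Simulate a full cohort from the Cox model of the design.

    With a constant baseline hazard ``lambda0`` the failure time is
    ``T = E / (lambda0 * exp(alpha' Z))`` with ``E ~ Exp(1)`` (inverse
    cumulative hazard).  Censoring is ``C ~ Uniform(0, tau)``;
    ``X = min(T, C)`` and ``Delta = 1{T <= C}``.  If ``tau`` is unset it
    is calibrated first (with a stream spawned from ``rng``).
    """
    rng = np.random.default_rng(rng if rng is not None else design.seed)
    if design.tau is None:
        design = replace(design, tau=calibrate_tau(design, rng=rng))
    Z = _draw_covariates(design, design.n, rng)
    eta = Z @ design.alpha
    E = rng.exponential(size=design.n)
    T = E / (design.baseline_hazard * np.exp(eta))
    C = rng.uniform(0.0, design.tau, size=design.n)
    X = np.minimum(T, C)
    Delta = (T <= C).astype(int)
    # Uniform(0, tau) censoring can produce X == 0 at double precision;
    # nudge to keep observed times strictly positive.
    X = np.maximum(X, np.finfo(float).tiny)
    return CohortData(X=X, Delta=Delta, Z=Z, true_active=design.true_active)


def calibrate_tau(
    design: SimulationDesign,
    n_mc: int = 20_000,
    rng: np.random.Generator | int | None = None,
    tol: float = 0.005,
) -> float:
    """Censoring bound tau hitting the target failure rate, by bisection.

    Uses common random numbers: one Monte-Carlo sample of failure times
    ``T`` and uniforms ``U`` is drawn, and the failure rate
    ``P(T <= U * tau)`` is a monotone increasing step function of tau
    on that sample, so bisection converges.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000 for a stable calibration")
    rng = np.random.default_rng(rng)
    target = design.target_failure_rate
    eta = _linear_predictor_sample(design, n_mc, rng)
    T = rng.exponential(size=n_mc) / (design.baseline_hazard * np.exp(eta))
    U = rng.uniform(size=n_mc)

    def rate(tau: float) -> float:
        return float(np.mean(T <= U * tau))

    lo, hi = 0.0, 1.0
    for _ in range(200):
        if rate(hi) >= target:
            break
        hi *= 2.0
    else:
        raise ValueError(
            f"target failure rate {target} unreachable; "
            f"achievable supremum approx {rate(hi):.4f}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) <= tol:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def pi_for_ratio(failure_rate: float, ratio: float = 1.0) -> float:
    """Bernoulli subcohort probability giving the desired noncase:case ratio.

    Solves ``E[(1 - FR) * n * pi] = ratio * E[FR * n]`` for pi, i.e.
    ``pi = ratio * FR / (1 - FR)``.
    """
    if not (0.0 < failure_rate < 1.0):
        raise ValueError("failure_rate must lie in (0, 1)")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pi = ratio * failure_rate / (1.0 - failure_rate)
    if pi >= 1.0:
        raise ValueError(
            f"implied subcohort probability {pi:.4f} >= 1; "
            "lower the ratio or the failure rate"
        )
    return pi


def draw_case_cohort(
    cohort: CohortData,
    pi: float,
    rng: np.random.Generator | int | None = None,
) -> CaseCohortData:
    """Bernoulli subcohort sample; covariates masked outside cases+subcohort."""
    if not (0.0 < pi <= 1.0):
        raise ValueError("pi must lie in (0, 1]")
    rng = np.random.default_rng(rng)
    xi = (rng.uniform(size=cohort.n) < pi).astype(int)
    Z_obs = cohort.Z.copy()
    Z_obs[(cohort.Delta == 0) & (xi == 0)] = np.nan
    return CaseCohortData(
        X=cohort.X,
        Delta=cohort.Delta,
        xi=xi,
        Z_obs=Z_obs,
        pi=pi,
        true_active=cohort.true_active,
    )
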