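"""Data containers for full-cohort and case-cohort survival records.

A *case-cohort* study measures expensive covariates only on the subjects
who experience the event of interest (the cases, ``Delta == 1``) and on a
Bernoulli-sampled random subset of the cohort (the subcohort,
``xi == 1``).  Observation times, event indicators and subcohort
indicators are known for everyone; covariate rows outside
``cases | subcohort`` are masked (stored as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CohortData:
    """Full-cohort survival records with complete covariates.

    Attributes
    ----------
    X : ndarray, shape (n,)
        Observed time, the minimum of the failure and censoring times.
    Delta : ndarray, shape (n,)
        Event indicator (1 = failure observed, 0 = censored).
    Z : ndarray, shape (n, p)
        Covariate matrix, fully observed.
    true_active : ndarray or None
        0-based indices of covariates with nonzero effect.  Simulation
        metadata; ``None`` for real data.
    """

    X: np.ndarray
    Delta: np.ndarray
    Z: np.ndarray
    true_active: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=int)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.X.ndim != 1:
            raise ValueError("X must be one-dimensional")
        n = self.X.shape[0]
        if self.Delta.shape != (n,) or self.Z.shape[0] != n:
            raise ValueError("X, Delta and Z must agree on the number of subjects")
        if np.any(self.X <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(self.Delta, (0, 1)).all():
            raise ValueError("Delta must be binary")
        if np.isnan(self.Z).any():
            raise ValueError("full-cohort covariates must not contain missing values")
        if self.true_active is not None:
            self.true_active = np.asarray(self.true_active, dtype=int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def failure_rate(self) -> float:
        return float(self.Delta.mean())


@dataclass
class CaseCohortData:
    """Case-cohort sample: full-cohort times plus masked covariates.

    ``Z_obs`` has a non-missing row exactly for subjects with
    ``Delta == 1`` or ``xi == 1``; all other rows are NaN.  ``pi`` is the
    Bernoulli subcohort selection probability used by the design (may be
    ``None`` for real data where it is unknown).
    """

    X: np.ndarray
    Delta: np.ndarray
    xi: np.ndarray
    Z_obs: np.ndarray
    pi: float | None = None
    true_active: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=int)
        self.xi = np.asarray(self.xi, dtype=int)
        self.Z_obs = np.asarray(self.Z_obs, dtype=float)
        n = self.X.shape[0]
        if self.Delta.shape != (n,) or self.xi.shape != (n,) or self.Z_obs.shape[0] != n:
            raise ValueError("X, Delta, xi and Z_obs must agree on the number of subjects")
        if np.any(self.X <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(self.Delta, (0, 1)).all():
            raise ValueError("Delta must be binary")
        if not np.isin(self.xi, (0, 1)).all():
            raise ValueError("xi must be binary")
        if self.pi is not None and not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must lie in (0, 1]")
        row_missing = np.isnan(self.Z_obs).any(axis=1)
        observed = self.observed
        if np.any(row_missing & observed):
            bad = int(np.flatnonzero(row_missing & observed)[0])
            raise ValueError(
                f"subject {bad} is a case or subcohort member but has missing covariates"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.Z_obs.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask: covariates observed (case or subcohort member)."""
        return (self.Delta == 1) | (self.xi == 1)

    @property
    def n_cc(self) -> int:
        """Case-cohort sample size: number of subjects with observed covariates."""
        return int(self.observed.sum())

    @property
    def n_events(self) -> int:
        return int(self.Delta.sum())

    @classmethod
    def from_full_cohort(cls, cohort: CohortData) -> "CaseCohortData":
        """Treat a fully observed cohort as a case-cohort sample with pi = 1."""
        return cls(
            X=cohort.X,
            Delta=cohort.Delta,
            xi=np.ones(cohort.n, dtype=int),
            Z_obs=cohort.Z,
            pi=1.0,
            true_active=cohort.true_active,
        )
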