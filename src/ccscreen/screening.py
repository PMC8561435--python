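"""Conditional weighted screening of ultrahigh-dimensional covariates.

The screening utility of candidate covariate ``Z_j`` given a
conditioning set ``C`` is the Wald-type statistic

    M_{C,j} = |beta_hat_j| / sigma_hat_j,

where ``beta_hat_j`` solves the weighted marginal estimating equation
and ``sigma_hat_j^2`` is the last diagonal element of the inverse
information matrix.  Candidates are ranked by ``M_{C,j}`` descending
and the top ``d0`` (default ``ceil(n_cc / log n_cc)`` with ``n_cc`` the
case-cohort sample size) are retained; alternatively all candidates
with ``M_{C,j} >= gamma`` for a fixed threshold.

The model/results pair follows the fitted-model idiom: build a
:class:`ConditionalScreening` from data, call :meth:`fit`, inspect the
returned :class:`ScreeningResults`.  Convenience functions implement
the named procedures:

``cwsis``    weighted conditional screening (the main method)
``mwsis``    weighted marginal (univariate) screening
``ncwsis``   unweighted conditional screening on the observed subset
``csmple_srs`` unweighted conditional screening on a simple random
             sample of matched size drawn from the full cohort
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CaseCohortData, CohortData
from .wee import MarginalFit, batched_marginal_fits

__all__ = [
    "ConditionalScreening",
    "ScreeningResults",
    "default_d0",
    "utility",
    "cwsis",
    "mwsis",
    "ncwsis",
    "csmple_srs",
]


def default_d0(n_cc: int) -> int:
    """Retained model size ceil(n_cc / log n_cc), natural logarithm."""
    if n_cc < 2:
        raise ValueError("case-cohort sample size must be at least 2")
    return int(math.ceil(n_cc / math.log(n_cc)))


def utility(fit: MarginalFit) -> float:
    """Screening utility |beta_j| / sigma_j; 0 for degenerate fits."""
    if not fit.converged or not np.isfinite(fit.sigma2_j) or fit.sigma2_j <= 0:
        return 0.0
    return abs(fit.beta_j) / math.sqrt(fit.sigma2_j)


class ConditionalScreening:
    """Screening model for case-cohort (or fully observed) survival data.

    Parameters
    ----------
    data : CaseCohortData or CohortData
        Survival records; a full cohort is treated as a case-cohort
        sample with pi = 1.
    cond_set : sequence of int
        0-based indices of covariates assumed active a priori (may be
        empty, giving marginal screening).
    weighted : bool
        If True, risk-set sums are inverse-probability weighted with
        the estimated time-varying sampling probability; if False the
        observed subset is treated as a simple random sample.
    candidates : sequence of int, optional
        Candidate indices to screen; defaults to every index outside
        the conditioning set.
    """

    def __init__(
        self,
        data: CaseCohortData | CohortData,
        cond_set: tuple[int, ...] = (),
        weighted: bool = True,
        candidates: np.ndarray | None = None,
    ):
        if isinstance(data, CohortData):
            data = CaseCohortData.from_full_cohort(data)
        self.data = data
        self.cond_set = tuple(int(c) for c in cond_set)
        if len(set(self.cond_set)) != len(self.cond_set):
            raise ValueError("conditioning set contains duplicates")
        for c in self.cond_set:
            if not 0 <= c < data.p:
                raise ValueError(f"conditioning index {c} out of range for p={data.p}")
        self.weighted = bool(weighted)
        if candidates is None:
            candidates = np.setdiff1d(np.arange(data.p), self.cond_set)
        else:
            candidates = np.asarray(candidates, dtype=int)
            if np.intersect1d(candidates, self.cond_set).size:
                raise ValueError("candidates overlap the conditioning set")
        if candidates.size == 0:
            raise ValueError("empty candidate set")
        self.candidates = candidates

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cond_set: tuple[int, ...] = (),
        weighted: bool = True,
        time_col: str = "X",
        event_col: str = "Delta",
        subcohort_col: str = "xi",
        pi: float | None = None,
    ) -> "ConditionalScreening":
        """Build from a tidy frame: time, event and subcohort columns plus covariates."""
        meta = {time_col, event_col, subcohort_col, "subject_id"}
        cov_cols = [c for c in df.columns if c not in meta]
        data = CaseCohortData(
            X=df[time_col].to_numpy(float),
            Delta=df[event_col].to_numpy(int),
            xi=df[subcohort_col].to_numpy(int),
            Z_obs=df[cov_cols].to_numpy(float),
            pi=pi,
        )
        model = cls(data, cond_set=cond_set, weighted=weighted)
        model.covariate_names = list(cov_cols)
        return model

    def fit(
        self,
        d0: int | None = None,
        gamma: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 50,
    ) -> "ScreeningResults":
        """Fit every marginal conditional model and rank the candidates.

        Exactly one of ``d0`` / ``gamma`` is used; with neither given,
        ``d0 = ceil(n_cc / log n_cc)``.  Degenerate fits are assigned
        utility 0 (ranked last) rather than aborting the screen.
        """
        if d0 is not None and gamma is not None:
            raise ValueError("give either d0 or gamma, not both")
        data = self.data
        q = len(self.cond_set)
        if q + 1 >= data.n_events:
            warnings.warn(
                f"{q + 1} parameters with only {data.n_events} events; "
                "marginal fits may be unstable",
                stacklevel=2,
            )
        out = batched_marginal_fits(
            data,
            self.cond_set,
            self.candidates,
            weighted=self.weighted,
            tol=tol,
            max_iter=max_iter,
        )
        beta_j = out["beta"][:, q]
        sigma2 = out["sigma2"]
        good = out["converged"] & np.isfinite(sigma2) & (sigma2 > 0)
        utilities = np.where(good, np.abs(beta_j) / np.sqrt(np.where(good, sigma2, 1.0)), 0.0)
        n_degen = int((~good).sum())
        if n_degen:
            warnings.warn(f"{n_degen} degenerate marginal fits assigned utility 0", stacklevel=2)

        order = np.lexsort((self.candidates, -utilities))
        ranking = self.candidates[order]
        n_cc = data.n_cc
        if gamma is not None:
            sel_mask = utilities[order] >= gamma
            selected = ranking[sel_mask]
            d0_used = None
        else:
            d0_used = d0 if d0 is not None else default_d0(n_cc)
            selected = ranking[:d0_used]
        return ScreeningResults(
            model=self,
            method=self._method_name(),
            cond_set=self.cond_set,
            candidates=self.candidates,
            params=beta_j,
            bse=np.sqrt(np.where(sigma2 > 0, sigma2, np.nan)),
            beta_cond=out["beta"][:, :q],
            utilities=utilities,
            ranking=ranking,
            selected=selected,
            d0=d0_used,
            gamma=gamma,
            n_cc=n_cc,
            n_events=int(out["n_events"]),
            converged=out["converged"],
            n_degenerate=n_degen,
        )

    def _method_name(self) -> str:
        if self.weighted:
            return "CWSIS" if self.cond_set else "MWSIS"
        return "NCWSIS" if self.cond_set else "NWSIS"


@dataclass
class ScreeningResults:
    """Ranked screening utilities and the selected covariate set.

    ``params``, ``bse``, ``utilities`` and ``converged`` are aligned
    with ``candidates``; ``ranking`` lists candidates by utility
    descending (ties broken by ascending index); ``selected`` is the
    prefix of length ``d0`` (or the super-threshold set when a
    ``gamma`` threshold is used).  Conditioning covariates are part of
    the final model but are never ranked.
    """

    model: ConditionalScreening = field(repr=False)
    method: str
    cond_set: tuple[int, ...]
    candidates: np.ndarray
    params: np.ndarray
    bse: np.ndarray
    beta_cond: np.ndarray = field(repr=False)
    utilities: np.ndarray
    ranking: np.ndarray
    selected: np.ndarray
    d0: int | None
    gamma: float | None
    n_cc: int
    n_events: int
    converged: np.ndarray
    n_degenerate: int

    def __post_init__(self) -> None:
        assert np.array_equal(np.sort(self.ranking), np.sort(self.candidates))
        assert np.all(self.utilities >= 0)

    def rank_of(self, j: int) -> int:
        """1-based rank of candidate ``j`` in the utility ordering."""
        pos = np.flatnonzero(self.ranking == j)
        if pos.size == 0:
            raise KeyError(f"covariate {j} is not a ranked candidate")
        return int(pos[0]) + 1

    @property
    def final_model(self) -> np.ndarray:
        """Selected candidates plus the conditioning covariates."""
        return np.union1d(self.selected, np.asarray(self.cond_set, dtype=int))

    def to_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        """Per-candidate table sorted by rank."""
        names = names or getattr(self.model, "covariate_names", None)
        order = np.argsort([self.rank_of(j) for j in self.candidates])
        idx = self.candidates[order]
        pos = {j: k for k, j in enumerate(self.candidates)}
        rows = [pos[j] for j in idx]
        sel = np.isin(idx, self.selected)
        return pd.DataFrame(
            {
                "index": idx + 1,
                "name": [names[j] if names else f"Z{j + 1}" for j in idx],
                "beta_j": self.params[rows],
                "sigma_j": self.bse[rows],
                "M": self.utilities[rows],
                "rank": np.arange(1, idx.size + 1),
                "selected": sel.astype(int),
            }
        )

    def summary(self, top: int = 10) -> str:
        """Plain-text summary in the spirit of fitted-model summaries."""
        cond = ", ".join(f"Z{c + 1}" for c in self.cond_set) or "(none)"
        cut = f"d0 = {self.d0}" if self.d0 is not None else f"gamma = {self.gamma}"
        head = [
            f"{self.method} screening results",
            "=" * 46,
            f"case-cohort size:   {self.n_cc}",
            f"events:             {self.n_events}",
            f"candidates:         {self.candidates.size}",
            f"conditioning set:   {cond}",
            f"selection rule:     {cut}",
            f"degenerate fits:    {self.n_degenerate}",
            "-" * 46,
            f"{'rank':>4} {'cov':>8} {'beta_j':>10} {'sigma_j':>10} {'M':>10}",
        ]
        frame = self.to_frame().head(top)
        for _, r in frame.iterrows():
            head.append(
                f"{int(r['rank']):>4} {r['name']:>8} {r['beta_j']:>10.4f} "
                f"{r['sigma_j']:>10.4f} {r['M']:>10.4f}"
            )
        head.append("=" * 46)
        return "\n".join(head)


def cwsis(
    data: CaseCohortData | CohortData,
    cond_set: tuple[int, ...],
    d0: int | None = None,
    gamma: float | None = None,
) -> ScreeningResults:
    """Conditional weighted screening (the main procedure)."""
    return ConditionalScreening(data, cond_set=cond_set, weighted=True).fit(d0=d0, gamma=gamma)


def mwsis(
    data: CaseCohortData | CohortData,
    d0: int | None = None,
    gamma: float | None = None,
) -> ScreeningResults:
    """Marginal weighted screening: univariate fits, empty conditioning set."""
    return ConditionalScreening(data, cond_set=(), weighted=True).fit(d0=d0, gamma=gamma)


def ncwsis(
    data: CaseCohortData | CohortData,
    cond_set: tuple[int, ...] = (),
    d0: int | None = None,
    gamma: float | None = None,
) -> ScreeningResults:
    """Unweighted conditional screening treating the observed subset as SRS."""
    return ConditionalScreening(data, cond_set=cond_set, weighted=False).fit(d0=d0, gamma=gamma)


def csmple_srs(
    cohort: CohortData,
    n_srs: int,
    cond_set: tuple[int, ...] = (),
    d0: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> ScreeningResults:
    """Conditional screening on a simple random sample of the full cohort.

    Draws ``n_srs`` subjects without replacement and runs unweighted
    conditional screening on them — the SRS benchmark with the same
    sample size as a case-cohort sample.
    """
    if n_srs > cohort.n:
        raise ValueError("n_srs exceeds the cohort size")
    rng = np.random.default_rng(rng)
    keep = rng.choice(cohort.n, size=n_srs, replace=False)
    sub = CaseCohortData(
        X=cohort.X[keep],
        Delta=cohort.Delta[keep],
        xi=np.ones(n_srs, dtype=int),
        Z_obs=cohort.Z[keep],
        pi=None,
        true_active=cohort.true_active,
    )
    res = ConditionalScreening(sub, cond_set=cond_set, weighted=False).fit(d0=d0)
    res.method = "CSMPLE"
    return res
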