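"""Weighted pseudo-partial-likelihood estimation of marginal Cox models.

For a candidate covariate ``Z_j`` and a conditioning set ``C`` of
covariates assumed active a priori, the marginal conditional model is a
Cox proportional-hazards model on ``(Z_C, Z_j)``.  Under case-cohort
sampling the usual partial-likelihood score is not computable (covariates
of unsampled noncases are missing), so risk-set sums are replaced by
inverse-probability-weighted sums: for component ``k`` in ``C + {j}``,

    U_k(beta) = sum_i int [ Z_ik - S1_k(beta, t) / S0(beta, t) ] dN_i(t),

with ``S_l`` the weighted risk-set moments
``n^-1 sum_i Z_ik^l w_i(t) Y_i(t) exp(beta' Z_i)`` and weights
``w_i(t) = Delta_i + (1 - Delta_i) xi_i / pi_hat(t)``.  The root of
``U`` is found by damped Newton-Raphson with the observed information
``I = -dU/dbeta``; the variance of the candidate coefficient is the
last diagonal element of ``I^-1`` (the candidate is always ordered
last).

The module exposes a single-model interface (:func:`solve_wee`) and a
batched engine (:func:`batched_marginal_fits`) that solves the marginal
model for thousands of candidates simultaneously; the two share one
code path.  Ties in event times are handled Breslow-style (tied events
share the same risk-set denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CaseCohortData
from .weights import WeightProcess

__all__ = [
    "MarginalModelSpec",
    "MarginalFit",
    "weighted_score",
    "solve_wee",
    "variance_of_beta_j",
    "batched_marginal_fits",
]

_DEFAULT_TOL = 1e-8
_DEFAULT_MAX_ITER = 50
_STEP_CAP = 2.0  # inf-norm cap on one Newton step; keeps early iterations stable
_ETA_CLIP = 700.0  # exp() overflow guard on the linear predictor
_COND_LIMIT = 1e12  # information matrices beyond this are treated as singular


@dataclass
class MarginalModelSpec:
    """One marginal conditional model: conditioning set ``C`` plus candidate ``j``.

    Indices are 0-based column positions in the covariate matrix.
    """

    cond_set: tuple[int, ...]
    j: int

    def __post_init__(self) -> None:
        self.cond_set = tuple(int(c) for c in self.cond_set)
        self.j = int(self.j)
        if self.j in self.cond_set:
            raise ValueError("candidate index must not belong to the conditioning set")
        if len(set(self.cond_set)) != len(self.cond_set):
            raise ValueError("conditioning set contains duplicates")

    @property
    def q(self) -> int:
        return len(self.cond_set)


@dataclass
class MarginalFit:
    """Solution of one weighted estimating equation.

    ``sigma2_j`` is the variance estimate of the candidate coefficient,
    i.e. the last diagonal element of the inverse information matrix.
    Degenerate fits (non-convergence or a singular information matrix)
    carry ``sigma2_j = inf`` so the screening utility collapses to 0.
    """

    beta_cond: np.ndarray
    beta_j: float
    info: np.ndarray
    sigma2_j: float
    score_norm: float
    converged: bool
    n_iter: int

    @property
    def params(self) -> np.ndarray:
        return np.append(self.beta_cond, self.beta_j)


class _RiskSetLayout:
    """Sorted risk-set geometry shared by every candidate fit on one dataset.

    Subjects with observable covariates are sorted by descending
    observed time so each event's risk set is a prefix; the weight at an
    event splits into a case part (always 1) and a sampled-noncase part
    scaled by 1/pi_hat at that event time, which lets risk-set sums be
    computed as two cumulative sums regardless of the time-varying
    weight.
    """

    def __init__(
        self,
        data: CaseCohortData,
        cond_set: tuple[int, ...],
        weighted: bool = True,
        wp: WeightProcess | None = None,
    ):
        obs_idx = np.flatnonzero(data.observed)
        if obs_idx.size == 0:
            raise ValueError("no subjects with observed covariates")
        X = data.X[obs_idx]
        Delta = data.Delta[obs_idx]
        xi = data.xi[obs_idx]
        order = np.argsort(-X, kind="stable")
        self.sub_idx = obs_idx[order]
        self.X = X[order]
        D = Delta[order]
        xi = xi[order]

        self.event_pos = np.flatnonzero(D == 1)
        if self.event_pos.size == 0:
            raise ValueError("no events among observed subjects")
        t_ev = self.X[self.event_pos]
        # Breslow risk sets: everyone with X >= t, ties included
        self.risk_last = np.searchsorted(-self.X, -t_ev, side="right") - 1

        if weighted:
            wp = wp if wp is not None else WeightProcess.from_data(data)
            k = np.searchsorted(wp.event_times, t_ev, side="right") - 1
            pi_hat = wp.pi_hat_at[k]
            # pi_hat == 0 means no sampled noncase is at risk, so the
            # noncase part of the sum is exactly zero; use multiplier 0.
            self.inv_pi = np.where(pi_hat > 0, 1.0 / np.where(pi_hat > 0, pi_hat, 1.0), 0.0)
            self.case_part = D.astype(float)
            self.non_part = ((1 - D) * xi).astype(float)
        else:
            self.inv_pi = np.ones(t_ev.size)
            self.case_part = np.ones(self.X.size)
            self.non_part = np.zeros(self.X.size)

        cond = np.asarray(cond_set, dtype=int)
        if cond.size:
            Zc = data.Z_obs[self.sub_idx][:, cond]
            if np.isnan(Zc).any():
                raise ValueError("conditioning covariates missing on a weighted subject")
            # centering is a pure shift: score, information and the
            # coefficients are unchanged, but exp() stays in range
            self.Zc = Zc - Zc.mean(axis=0)
        else:
            self.Zc = np.empty((self.X.size, 0))
        self.q = cond.size
        self.m = self.X.size
        self.n_events = self.event_pos.size

    def candidate_matrix(self, data: CaseCohortData, candidates: np.ndarray) -> np.ndarray:
        Zj = data.Z_obs[self.sub_idx][:, candidates]
        if np.isnan(Zj).any():
            raise ValueError("candidate covariates missing on a weighted subject")
        return Zj - Zj.mean(axis=0)


def _score_info(
    layout: _RiskSetLayout,
    Zj: np.ndarray,
    B: np.ndarray,
    need_info: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Batched score (J, q+1) and information (J, q+1, q+1) at B (J, q+1)."""
    q = layout.q
    eta = Zj * B[:, q][None, :]
    if q:
        eta = eta + layout.Zc @ B[:, :q].T
    np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
    E = np.exp(eta)
    Ec = layout.case_part[:, None] * E
    En = layout.non_part[:, None] * E
    rl = layout.risk_last
    a = layout.inv_pi[:, None]

    def risk_sums(f: np.ndarray | None) -> np.ndarray:
        if f is None:
            return np.cumsum(Ec, 0)[rl] + a * np.cumsum(En, 0)[rl]
        return np.cumsum(f * Ec, 0)[rl] + a * np.cumsum(f * En, 0)[rl]

    comps = [layout.Zc[:, [k]] for k in range(q)] + [Zj]
    S0 = risk_sums(None)
    S1 = [risk_sums(c) for c in comps]
    U_cols = []
    for c, S1k in zip(comps, S1):
        U_cols.append((c[layout.event_pos] - S1k / S0).sum(axis=0))
    U = np.stack(U_cols, axis=1)

    if not need_info:
        return U, None
    R = [S1k / S0 for S1k in S1]
    J_ = Zj.shape[1]
    info = np.empty((J_, q + 1, q + 1))
    for k in range(q + 1):
        for l in range(k, q + 1):
            S2 = risk_sums(comps[k] * comps[l])
            val = (S2 / S0 - R[k] * R[l]).sum(axis=0)
            info[:, k, l] = val
            info[:, l, k] = val
    return U, info


def _batched_newton(
    layout: _RiskSetLayout,
    Zj: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> dict[str, np.ndarray]:
    q = layout.q
    J = Zj.shape[1]
    if init is None:
        B = np.zeros((J, q + 1))
    else:
        init = np.asarray(init, dtype=float)
        B = np.tile(init, (J, 1)) if init.ndim == 1 else init.copy()

    degenerate = np.zeros(J, dtype=bool)
    n_iter = np.zeros(J, dtype=int)
    info = np.tile(np.eye(q + 1), (J, 1, 1))
    norm = np.full(J, np.inf)

    # shrinking working set: converged / degenerate candidates drop out
    work = np.arange(J)
    for it in range(max_iter + 1):
        Zw = Zj[:, work]
        Uw, Iw = _score_info(layout, Zw, B[work], True)
        nw = np.abs(Uw).max(axis=1)
        bad = ~np.isfinite(nw)
        nw[bad] = np.inf
        norm[work] = nw
        info[work] = Iw
        degenerate[work[bad]] = True
        keep = ~bad & (nw > tol)
        work = work[keep]
        if work.size == 0 or it == max_iter:
            break
        Uw, Iw = Uw[keep], Iw[keep]

        with np.errstate(all="ignore"):
            cond_num = np.linalg.cond(Iw)
        sing = ~np.isfinite(cond_num) | (cond_num > _COND_LIMIT)
        degenerate[work[sing]] = True
        work, Uw, Iw = work[~sing], Uw[~sing], Iw[~sing]
        if work.size == 0:
            break
        step = np.linalg.solve(Iw, Uw[..., None])[..., 0]
        s_norm = np.abs(step).max(axis=1)
        step *= np.minimum(1.0, _STEP_CAP / np.maximum(s_norm, 1e-300))[:, None]

        # step-halving line search on the score norm
        B_next = B[work].copy()
        t = np.ones(work.size)
        na = np.arange(work.size)  # not-yet-accepted positions within work
        for _h in range(8):
            trial = B[work[na]] + t[na, None] * step[na]
            U_t, _ = _score_info(layout, Zj[:, work[na]], trial, False)
            nt = np.abs(U_t).max(axis=1)
            good = np.isfinite(nt) & (nt < norm[work[na]])
            B_next[na[good]] = trial[good]
            na = na[~good]
            if na.size == 0:
                break
            t[na] *= 0.5
        # candidates that never accepted a step stay put; they either
        # converge later or run out of iterations and are flagged
        B[work] = B_next
        n_iter[work] += 1

    converged = ~degenerate & (norm <= tol)

    sigma2 = np.full(J, np.inf)
    with np.errstate(all="ignore"):
        cond_num = np.linalg.cond(info)
    ok = np.isfinite(cond_num) & (cond_num <= _COND_LIMIT) & ~degenerate
    if ok.any():
        e_last = np.zeros(q + 1)
        e_last[q] = 1.0
        sol = np.linalg.solve(
            info[ok], np.broadcast_to(e_last[:, None], (int(ok.sum()), q + 1, 1)).copy()
        )
        var = sol[:, q, 0]
        var = np.where(var > 0, var, np.inf)
        sigma2[ok] = var

    return {
        "beta": B,
        "info": info,
        "sigma2": sigma2,
        "score_norm": norm,
        "converged": converged,
        "n_iter": n_iter,
        "degenerate": degenerate | ~converged,
    }


def batched_marginal_fits(
    data: CaseCohortData,
    cond_set: tuple[int, ...],
    candidates: np.ndarray,
    weighted: bool = True,
    wp: WeightProcess | None = None,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> dict[str, np.ndarray]:
    """Fit the marginal conditional model for every candidate at once.

    Returns arrays aligned with ``candidates``: ``beta`` (J, q+1) with
    the candidate coefficient last, ``sigma2``, ``score_norm``,
    ``converged``, ``n_iter`` and ``degenerate``.  pi_hat is estimated
    once and shared by every fit (it does not depend on the candidate).
    """
    candidates = np.asarray(candidates, dtype=int)
    cond_set = tuple(cond_set)
    layout = _RiskSetLayout(data, cond_set, weighted=weighted, wp=wp)
    Zj = layout.candidate_matrix(data, candidates)

    # warm start: solve the conditioning-set-only model once and start
    # every candidate fit from it (candidate coefficient 0).  This only
    # changes the Newton starting point, not the root.
    init = None
    q = len(cond_set)
    if q:
        base_layout = _RiskSetLayout(data, cond_set[:-1], weighted=weighted, wp=wp)
        base_Zj = base_layout.candidate_matrix(data, np.array([cond_set[-1]]))
        base = _batched_newton(base_layout, base_Zj, tol=1e-4, max_iter=max_iter)
        if base["converged"][0]:
            init = np.append(base["beta"][0], 0.0)

    out = _batched_newton(layout, Zj, init=init, tol=tol, max_iter=max_iter)
    out["candidates"] = candidates
    out["n_events"] = layout.n_events
    return out


def _single(spec: MarginalModelSpec, data: CaseCohortData, weighted: bool, wp, B=None,
            tol=_DEFAULT_TOL, max_iter=_DEFAULT_MAX_ITER):
    layout = _RiskSetLayout(data, spec.cond_set, weighted=weighted, wp=wp)
    Zj = layout.candidate_matrix(data, np.array([spec.j]))
    return layout, Zj


def weighted_score(
    spec: MarginalModelSpec,
    beta: np.ndarray,
    data: CaseCohortData,
    wp: WeightProcess | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Score vector U(beta) of the weighted estimating equation.

    ``beta`` orders the conditioning coefficients first and the
    candidate coefficient last.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (spec.q + 1,):
        raise ValueError(f"beta must have length q+1 = {spec.q + 1}")
    layout, Zj = _single(spec, data, weighted, wp)
    U, _ = _score_info(layout, Zj, beta[None, :], False)
    return U[0]


def solve_wee(
    spec: MarginalModelSpec,
    data: CaseCohortData,
    wp: WeightProcess | None = None,
    init: np.ndarray | None = None,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
    weighted: bool = True,
) -> MarginalFit:
    """Newton-Raphson root of the weighted estimating equation.

    Non-convergence or a singular information matrix does not raise:
    the fit is returned flagged, with ``sigma2_j = inf`` so that the
    screening utility of this candidate is 0.
    """
    layout, Zj = _single(spec, data, weighted, wp)
    out = _batched_newton(layout, Zj, init=init, tol=tol, max_iter=max_iter)
    q = spec.q
    return MarginalFit(
        beta_cond=out["beta"][0, :q].copy(),
        beta_j=float(out["beta"][0, q]),
        info=out["info"][0],
        sigma2_j=float(out["sigma2"][0]),
        score_norm=float(out["score_norm"][0]),
        converged=bool(out["converged"][0]),
        n_iter=int(out["n_iter"][0]),
    )


def variance_of_beta_j(fit: MarginalFit) -> float:
    """Last diagonal element of the inverse information matrix."""
    info = np.atleast_2d(fit.info)
    try:
        inv = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("information matrix is singular") from err
    return float(inv[-1, -1])
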