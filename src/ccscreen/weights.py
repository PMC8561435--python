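"""Time-varying inverse-probability weights for case-cohort risk sets.

At an event time ``t`` the sampling probability of a censored subject is
estimated by the ratio of at-risk sampled noncases to all at-risk
noncases,

    pi_hat(t) = sum_i (1 - Delta_i) xi_i Y_i(t) / sum_i (1 - Delta_i) Y_i(t),

with the at-risk indicator ``Y_i(t) = 1{X_i >= t}``.  The subject-level
weight is ``w_i(t) = Delta_i + (1 - Delta_i) xi_i / pi_hat(t)``: cases
always count 1, sampled noncases are inflated by 1/pi_hat(t), unsampled
noncases drop out.  The estimating equation integrates counting-process
jumps, so the weights are only ever needed at observed event times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CaseCohortData

__all__ = ["WeightProcess", "estimate_pi_hat", "weight_at"]


def estimate_pi_hat(data: CaseCohortData, times: np.ndarray) -> np.ndarray:
    """pi_hat(t) at each requested time; errors on an empty denominator.

    Both the numerator and the denominator only need ``X``, ``Delta``
    and ``xi``, which are known for every cohort member, so the full
    cohort enters even though most covariates are masked.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    noncase = data.Delta == 0
    x_non = data.X[noncase]
    xi_non = data.xi[noncase]
    # at-risk counts via sorted search: #{X >= t}
    order = np.argsort(x_non)
    x_sorted = x_non[order]
    sampled_suffix = np.concatenate([np.cumsum(xi_non[order][::-1])[::-1], [0]])
    idx = np.searchsorted(x_sorted, times, side="left")
    denom = x_non.size - idx
    if np.any(denom == 0):
        t_bad = times[np.flatnonzero(denom == 0)[0]]
        raise ValueError(f"no noncases at risk at time {t_bad:g}; pi_hat undefined")
    num = sampled_suffix[idx]
    return num / denom


def weight_at(data: CaseCohortData, pi_hat: np.ndarray, i: int, t_index: int) -> float:
    """Weight of subject ``i`` at the event time indexed by ``t_index``."""
    if data.Delta[i] == 1:
        return 1.0
    if data.xi[i] == 0:
        return 0.0
    return 1.0 / float(np.atleast_1d(pi_hat)[t_index])


@dataclass
class WeightProcess:
    """pi_hat and subject weights evaluated at the distinct event times.

    ``event_times`` are the sorted distinct times with ``Delta == 1``;
    ``pi_hat_at`` is the step function pi_hat evaluated there.  When no
    noncases remain at risk at a late event time, pi_hat falls back to
    the design probability if known, else to the last defined value
    (with a warning): the estimating equation still needs a finite
    weight for sampled noncases tied at that time.
    """

    event_times: np.ndarray
    pi_hat_at: np.ndarray

    @classmethod
    def from_data(cls, data: CaseCohortData) -> "WeightProcess":
        event_times = np.unique(data.X[data.Delta == 1])
        if event_times.size == 0:
            raise ValueError("no events in the data; nothing to weight")
        try:
            pi_hat = estimate_pi_hat(data, event_times)
        except ValueError:
            pi_hat = np.empty(event_times.size)
            last = data.pi if data.pi is not None else None
            for k, t in enumerate(event_times):
                try:
                    pi_hat[k] = estimate_pi_hat(data, np.array([t]))[0]
                    if last is None:
                        last = pi_hat[k]
                except ValueError:
                    fallback = data.pi if data.pi is not None else last
                    if fallback is None:
                        # no design pi and pi_hat never defined: if the
                        # data hold no sampled noncases at all, every
                        # weight is 0 or 1 and the value is immaterial
                        if (((1 - data.Delta) * data.xi) == 0).all():
                            fallback = 1.0
                        else:
                            raise
                    warnings.warn(
                        f"no noncases at risk at event time {t:g}; "
                        f"using fallback sampling probability {fallback:g}",
                        stacklevel=2,
                    )
                    pi_hat[k] = fallback
        return cls(event_times=event_times, pi_hat_at=pi_hat)

    def weight(self, data: CaseCohortData, i: int, t: float) -> float:
        """w_i(t) with t matched to the enclosing event time."""
        k = int(np.searchsorted(self.event_times, t, side="right")) - 1
        if k < 0:
            k = 0
        return weight_at(data, self.pi_hat_at, i, k)

    def weight_matrix(self, data: CaseCohortData) -> np.ndarray:
        """Dense (n, K) table of w_i(t_k); mostly for inspection and tests."""
        inv = 1.0 / self.pi_hat_at
        w = np.outer((1 - data.Delta) * data.xi, inv)
        w[data.Delta == 1] = 1.0
        return w
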