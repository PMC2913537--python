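"""Changepoint-process allocation machinery.

K mixture components are identified with K-1 real-valued changepoints
b_1 < ... < b_{K-1} on the interval (2, m), with pseudo-changepoints b_0 = 2
and b_K = m.  Time point t belongs to component k iff b_{k-1} <= t < b_k,
with the final segment closed at m so every observation is allocated.

The changepoints are a priori the even-numbered order statistics of
L = 2(K-1) + 1 points drawn uniformly on [2, m], which discourages very
short segments; K carries a Poisson(lambda = 1) prior truncated to 1..K*.
Birth, death and reallocation moves with Green-style acceptance factors
leave the induced joint prior invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "KPrior", "MoveProbabilities", "allocation_from_changepoints",
    "log_changepoint_prior_density", "log_changepoint_prior_ratio_realloc",
    "log_birth_factor", "log_death_factor", "move_probabilities",
    "sample_changepoints_from_prior",
]


@dataclass(frozen=True)
class KPrior:
    """Truncated Poisson prior over the number of components, P(K) for
    K = 1..k_max, P(K) proportional to lambda^K / K!."""

    lam: float = 1.0
    k_max: int = 10

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k_max < 1:
            raise ValueError("need lam > 0 and k_max >= 1")

    def log_probs(self) -> np.ndarray:
        k = np.arange(1, self.k_max + 1)
        logw = k * np.log(self.lam) - gammaln(k + 1)
        logw -= np.logaddexp.reduce(logw)
        return logw

    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs())

    def log_prob(self, k: int) -> float:
        if not 1 <= k <= self.k_max:
            return -np.inf
        return float(self.log_probs()[k - 1])


@dataclass(frozen=True)
class MoveProbabilities:
    """Per-K birth/death selection probabilities b_K and d_K with
    b_K P(K) = d_{K+1} P(K+1) and b_K + d_K <= 0.9 for all K; the remaining
    probability (at least 0.1) goes to the reallocation move."""

    birth: np.ndarray   # b_K, index K-1
    death: np.ndarray   # d_K, index K-1
    constant: float

    def realloc(self, k: int) -> float:
        return 1.0 - self.birth[k - 1] - self.death[k - 1]


def move_probabilities(kprior: KPrior, cap: float = 0.9) -> MoveProbabilities:
    """Maximise the common scale c subject to b_K + d_K <= ``cap``.

    b_K = c min{1, P(K+1)/P(K)} for K < K* (b_{K*} = 0) and
    d_{K+1} = c min{1, P(K)/P(K+1)} (d_1 = 0).
    """
    p = kprior.probs()
    kmax = kprior.k_max
    b_unit = np.zeros(kmax)
    d_unit = np.zeros(kmax)
    for k in range(1, kmax):
        b_unit[k - 1] = min(1.0, p[k] / p[k - 1])
        d_unit[k] = min(1.0, p[k - 1] / p[k])
    totals = b_unit + d_unit
    c = cap / totals.max() if totals.max() > 0 else cap
    c = min(c, cap)
    return MoveProbabilities(birth=c * b_unit, death=c * d_unit, constant=c)


def allocation_from_changepoints(changepoints, m: int) -> np.ndarray:
    """Allocation vector V of length m-1 over t = 2..m induced by a sorted
    changepoint tuple: V(t) = k iff b_{k-1} <= t < b_k, last segment closed."""
    b = np.asarray(changepoints, dtype=float)
    if b.size and (np.any(np.diff(b) <= 0) or b.min() <= 2 or b.max() >= m):
        raise ValueError("changepoints must be strictly increasing in (2, m)")
    t = np.arange(2, m + 1)
    alloc = np.searchsorted(b, t, side="right") + 1
    return alloc.astype(int)


def log_changepoint_prior_density(changepoints, m: int) -> float:
    """Log joint prior density of the changepoint locations given K: the
    even-numbered order statistics of L = 2(K-1)+1 uniforms on [2, m] have
    density L! / (m-2)^L * prod_j (b_{j+1} - b_j) over the K gaps formed with
    the pseudo endpoints."""
    b = np.asarray(changepoints, dtype=float)
    k = b.size + 1
    if k == 1:
        return 0.0
    L = 2 * (k - 1) + 1
    pts = np.concatenate([[2.0], np.sort(b), [float(m)]])
    gaps = np.diff(pts)
    if np.any(gaps <= 0):
        return -np.inf
    return float(gammaln(L + 1) - L * np.log(m - 2) + np.log(gaps).sum())


def log_changepoint_prior_ratio_realloc(b_left: float, b_old: float,
                                        b_new: float, b_right: float) -> float:
    """Log prior ratio R_r for replacing changepoint b_old by b_new inside
    the flanking interval (b_left, b_right); the proposal ratio is 1."""
    if not (b_left < b_old < b_right and b_left < b_new < b_right):
        raise ValueError("replacement outside the flanking interval")
    return float(np.log(b_right - b_new) + np.log(b_new - b_left)
                 - np.log(b_right - b_old) - np.log(b_old - b_left))


def log_birth_factor(k: int, m: int, b_new: float,
                     b_left: float, b_right: float) -> float:
    """Log of the combined prior x proposal factor R_b * B_b for the birth of
    changepoint ``b_new`` inside the segment (b_left, b_right) when the chain
    currently has ``k`` components:
    2 (2k+1) / (m-2) * (b_right - b_new)(b_new - b_left) / (b_right - b_left).
    The birth/death selection probabilities and the Poisson ratio have
    already cancelled through the flow-balance choice of b_K and d_{K+1}.
    """
    if not b_left < b_new < b_right:
        raise ValueError("new changepoint outside its segment")
    return float(np.log(2.0 * (2 * k + 1)) - np.log(m - 2)
                 + np.log(b_right - b_new) + np.log(b_new - b_left)
                 - np.log(b_right - b_left))


def log_death_factor(k: int, m: int, b_removed: float,
                     b_left: float, b_right: float) -> float:
    """Log of R_d * B_d for removing ``b_removed`` (flanked by b_left and
    b_right after removal) when the chain currently has ``k`` components:
    (m-2) / (2 (2k-1)) * (b_right - b_left) /
    ((b_right - b_removed)(b_removed - b_left))."""
    if not b_left < b_removed < b_right:
        raise ValueError("removed changepoint outside its flanks")
    return float(np.log(m - 2) - np.log(2.0 * (2 * k - 1))
                 + np.log(b_right - b_left)
                 - np.log(b_right - b_removed) - np.log(b_removed - b_left))


def sample_changepoints_from_prior(k: int, m: int,
                                   rng: np.random.Generator) -> np.ndarray:
    """Draw K-1 changepoints as the even-numbered order statistics of
    2(K-1)+1 uniform points on [2, m]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.empty(0)
    L = 2 * (k - 1) + 1
    u = np.sort(rng.uniform(2.0, float(m), size=L))
    return u[1::2].copy()
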