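"""Free (unconstrained) allocation of time points to mixture components.

This is the comparator model: instead of contiguous temporal segments, each
time point t = 2..m may be assigned to any of K components.  The allocation
vector carries a symmetric Dirichlet-multinomial prior with unit
concentrations (alpha_k = 1, alpha_0 = K), so P(V | K) depends only on the
component occupancy counts, and P(V | K = 1) = 1.

The sampler over (V, K) combines a single-point Gibbs reassignment with
birth/death of *empty* components; together with the Gibbs step this is an
ergodic sampler of the joint posterior, exchangeable in the component labels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .changepoints import KPrior

__all__ = ["log_free_allocation_prior", "gibbs_reassign",
           "empty_component_birth", "empty_component_death"]


def log_free_allocation_prior(allocation: np.ndarray, k: int) -> float:
    """log P(V | K) under the symmetric unit-concentration Dirichlet-
    multinomial: Gamma(K) / Gamma(K + m - 1) * prod_k Gamma(1 + m_k)."""
    v = np.asarray(allocation, dtype=int)
    if v.size and (v.min() < 1 or v.max() > k):
        raise ValueError("allocation label outside 1..K")
    if k == 1:
        return 0.0
    counts = np.bincount(v, minlength=k + 1)[1:k + 1]
    return float(gammaln(k) - gammaln(k + v.size)
                 + np.sum(gammaln(1.0 + counts)))


def _component_times(allocation: np.ndarray, k: int) -> tuple[int, ...]:
    return tuple(int(t) for t in np.nonzero(allocation == k)[0] + 2)


def _node_sum(scorer, graph, times) -> float:
    return sum(scorer.family_log_score(n, graph.parents(n), times)
               for n in range(graph.n_nodes))


def gibbs_reassign(allocation: np.ndarray, k: int, scorer, graph,
                   rng: np.random.Generator) -> np.ndarray:
    """Resample the component of one uniformly chosen time point from its
    full conditional P(V(t) = j | rest) which is proportional to
    (1 + m_j^{-t}) * prod_n Psi(component j with t) / Psi(component j).

    Always accepted (a Gibbs step).  Returns the updated allocation.
    """
    v = np.asarray(allocation, dtype=int).copy()
    pos = int(rng.integers(v.size))
    old = v[pos]
    counts = np.bincount(v, minlength=k + 1)[1:k + 1].astype(float)
    counts[old - 1] -= 1.0
    log_weights = np.empty(k)
    for j in range(1, k + 1):
        v[pos] = j
        times_j = _component_times(v, j)
        v[pos] = 0
        times_wo = _component_times(v, j)
        delta = _node_sum(scorer, graph, times_j) - _node_sum(
            scorer, graph, times_wo)
        log_weights[j - 1] = np.log(1.0 + counts[j - 1]) + delta
    log_weights -= logsumexp(log_weights)
    v[pos] = 1 + rng.choice(k, p=np.exp(log_weights))
    return v


def empty_component_birth(allocation: np.ndarray, k: int, kprior: KPrior,
                          rng: np.random.Generator,
                          p_birth: float, p_death: float
                          ) -> tuple[np.ndarray, int, bool]:
    """Insert an empty component at a uniform label position (K -> K+1).

    The data likelihood is unchanged (an empty compartment scores Psi = 1),
    so the acceptance ratio involves only P(K) P(V | K) and the proposal
    probabilities.  Returns (allocation, K, accepted).
    """
    v = np.asarray(allocation, dtype=int)
    if k >= kprior.k_max:
        return v, k, False
    pos = int(rng.integers(k + 1)) + 1       # new label in 1..K+1
    v_new = np.where(v >= pos, v + 1, v)
    n_empty_new = int(np.sum(np.bincount(v_new, minlength=k + 2)[1:k + 2] == 0))
    log_acc = (kprior.log_prob(k + 1) - kprior.log_prob(k)
               + log_free_allocation_prior(v_new, k + 1)
               - log_free_allocation_prior(v, k)
               + np.log(p_death) - np.log(n_empty_new)
               - np.log(p_birth) + np.log(k + 1))
    if np.log(rng.uniform()) < min(0.0, log_acc):
        return v_new, k + 1, True
    return v, k, False


def empty_component_death(allocation: np.ndarray, k: int, kprior: KPrior,
                          rng: np.random.Generator,
                          p_birth: float, p_death: float
                          ) -> tuple[np.ndarray, int, bool]:
    """Remove a uniformly chosen empty component (K -> K-1); the reverse of
    the empty-component birth.  Invalid (chain unchanged) when K = 1 or no
    component is empty."""
    v = np.asarray(allocation, dtype=int)
    if k <= 1:
        return v, k, False
    counts = np.bincount(v, minlength=k + 1)[1:k + 1]
    empties = np.nonzero(counts == 0)[0] + 1
    if empties.size == 0:
        return v, k, False
    label = int(rng.choice(empties))
    v_new = np.where(v > label, v - 1, v)
    log_acc = (kprior.log_prob(k - 1) - kprior.log_prob(k)
               + log_free_allocation_prior(v_new, k - 1)
               - log_free_allocation_prior(v, k)
               + np.log(p_birth) - np.log(k)
               - np.log(p_death) + np.log(empties.size))
    if np.log(rng.uniform()) < min(0.0, log_acc):
        return v_new, k - 1, True
    return v, k, False
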