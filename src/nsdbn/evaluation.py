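"""Posterior summaries and convergence diagnostics.

All summaries are functions of the thinned trace only and are invariant
under permutations of the mixture-component labels: edge posteriors count
edge indicators, the connectivity matrix counts co-allocation of time-point
pairs, and the changepoint-location posterior counts per-gap changepoint
presence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .mcmc import TraceSet
from .scoring import make_scorer
from .graph import Graph

__all__ = ["edge_posteriors", "connectivity_matrix",
           "changepoint_location_posterior", "auc", "psrf",
           "predictive_probability", "write_matrix"]


def _all_samples(traces) -> list:
    if isinstance(traces, TraceSet):
        traces = [traces]
    samples = [s for tr in traces for s in tr.samples]
    if not samples:
        raise ValueError("empty trace")
    return samples


def edge_posteriors(traces, n_nodes: int | None = None) -> np.ndarray:
    """N x N matrix of marginal edge posterior probabilities: the fraction of
    kept graphs containing each edge, pooled across chains."""
    if isinstance(traces, TraceSet):
        traces = [traces]
    n = n_nodes or traces[0].n_nodes
    samples = _all_samples(traces)
    mat = np.zeros((n, n))
    for s in samples:
        for (i, j) in s.edges:
            mat[i, j] += 1.0
    return mat / len(samples)


def connectivity_matrix(traces) -> np.ndarray:
    """(m-1) x (m-1) matrix C with C[i, j] the fraction of kept states that
    allocate time points t_{i+2} and t_{j+2} to the same component.
    Symmetric with unit diagonal."""
    samples = _all_samples(traces)
    v0 = np.asarray(samples[0].allocation)
    acc = np.zeros((v0.size, v0.size))
    for s in samples:
        v = np.asarray(s.allocation)
        acc += (v[:, None] == v[None, :])
    return acc / len(samples)


def changepoint_location_posterior(traces, m: int,
                                   multiplicity: bool = False) -> np.ndarray:
    """Per-gap changepoint posterior: entry g (for g = 0..m-3, the gap
    between t = g+2 and t = g+3) is the fraction of kept states with at
    least one changepoint in [g+2, g+3); with ``multiplicity=True`` the mean
    changepoint count per gap instead."""
    samples = _all_samples(traces)
    gaps = np.zeros(m - 2)
    for s in samples:
        if s.changepoints is None:
            raise ValueError(
                "changepoint locations are undefined for free-allocation "
                "traces")
        idx = np.floor(np.asarray(s.changepoints)).astype(int) - 2
        idx = np.clip(idx, 0, m - 3)
        if multiplicity:
            np.add.at(gaps, idx, 1.0)
        else:
            gaps[np.unique(idx)] += 1.0
    return gaps / len(samples)


def auc(edge_post: np.ndarray, true_graph: Graph) -> float:
    """Area under the ROC curve of posterior edge scores against the true
    edge labels.  Self-loop cells are included only when the true graph
    allows self-loops; returns NaN when only one class is present."""
    n = true_graph.n_nodes
    scores, labels = [], []
    for i in range(n):
        for j in range(n):
            if i == j and not true_graph.allow_self_loops:
                continue
            scores.append(edge_post[i, j])
            labels.append(1 if (i, j) in true_graph.edges else 0)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores)))


def _gelman_rubin(chain_draws: np.ndarray) -> float:
    """Classical potential scale reduction factor for a chains x draws
    matrix of scalar estimates."""
    c, n = chain_draws.shape
    if c < 2 or n < 2:
        raise ValueError("need >= 2 chains and >= 2 draws per chain")
    within = chain_draws.var(axis=1, ddof=1).mean()
    between = n * chain_draws.mean(axis=1).var(ddof=1)
    if within < 1e-12:
        return 1.0 if between < 1e-12 else float("inf")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def psrf(traces: list, n_batches: int = 20) -> tuple[np.ndarray, float]:
    """Per-edge potential scale reduction factors across chains.

    Each chain's kept edge-indicator sequence is summarised by ``n_batches``
    batch means (indicator draws need batching before a variance-based
    diagnostic); the Gelman-Rubin statistic is then computed per edge over
    the chains.  Returns (N x N matrix, max over edges); edges constant in
    every chain score 1.  Convergence is conventionally declared at
    max PSRF < 1.2.
    """
    if len(traces) < 2:
        raise ValueError("PSRF needs at least 2 chains")
    n = traces[0].n_nodes
    n_kept = min(len(tr) for tr in traces)
    if n_kept < n_batches:
        n_batches = max(2, n_kept)
    per_chain = np.zeros((len(traces), n_batches, n, n))
    for c, tr in enumerate(traces):
        ind = np.zeros((n_kept, n, n))
        for s_idx, s in enumerate(tr.samples[:n_kept]):
            for (i, j) in s.edges:
                ind[s_idx, i, j] = 1.0
        bounds = np.linspace(0, n_kept, n_batches + 1).astype(int)
        for b in range(n_batches):
            per_chain[c, b] = ind[bounds[b]:bounds[b + 1]].mean(axis=0)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = _gelman_rubin(per_chain[:, :, i, j])
    return out, float(out.max())


def predictive_probability(train, test, traces) -> float:
    """Monte-Carlo log predictive probability of a held-out series: the
    log-mean-exp over kept states of the product over compartments of
    posterior-predictive compartment scores (test data scored under the
    training-posterior-updated prior, with the training allocation applied
    to the test series)."""
    if train.n_nodes != test.n_nodes or train.m != test.m:
        raise ValueError("train and test must share node set and length")
    if isinstance(traces, TraceSet):
        traces = [traces]
    cfg = traces[0].config
    score = cfg.score if cfg is not None else "bge"
    train_scorer = make_scorer(train, score)
    test_scorer = make_scorer(test, score)
    samples = _all_samples(traces)
    per_sample = np.empty(len(samples))
    cache: dict = {}
    for idx, s in enumerate(samples):
        v = np.asarray(s.allocation)
        graph_edges = s.edges
        total = 0.0
        for k in range(1, s.k + 1):
            times = tuple(int(t) for t in np.nonzero(v == k)[0] + 2)
            if not times:
                continue
            for node in range(train.n_nodes):
                parents = tuple(sorted(i for (i, j) in graph_edges
                                       if j == node))
                key = (node, parents, times)
                val = cache.get(key)
                if val is None:
                    val = train_scorer.predictive_family_score(
                        test_scorer, node, parents, times)
                    cache[key] = val
                total += val
        per_sample[idx] = total
    mx = per_sample.max()
    return float(mx + np.log(np.mean(np.exp(per_sample - mx))))


def write_matrix(matrix: np.ndarray, path, labels=None) -> None:
    """Write a matrix as a TSV table with a shared header row/column."""
    if labels is None:
        labels = [str(i) for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=labels,
                 columns=labels[:matrix.shape[1]]).to_csv(
        path, sep="\t", index_label="")
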