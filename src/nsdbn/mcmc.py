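"""Combined structure + allocation sampler.

Each iteration performs, with probability 0.5, a single-edge structure move
(leaving the allocation untouched) and otherwise an allocation move (leaving
the graph untouched).  For the changepoint models the allocation move is a
changepoint birth, death or reallocation chosen with the flow-balanced
probabilities (b_K, d_K, remainder); for the free-allocation models it is a
Gibbs single-point reassignment or an empty-component birth/death.  The
homogeneous baselines (plain BGe/BDe) keep K = 1 and perform structure moves
only.

Invalid move draws (death at K = 1, birth at K = K*, death with no empty
component) leave the chain unchanged but still count as iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import changepoints as cp
from . import free_allocation as fa
from .datasets import TimeSeriesDataset
from .graph import (Graph, log_structure_acceptance, propose_structure_move)
from .scoring import BDeHyper, BGeHyper, make_scorer

__all__ = ["SamplerConfig", "SamplerState", "TraceSample", "TraceSet",
           "run_chain", "run_multi_chain", "export_trace"]

_MODEL_INFO = {
    "bgmd": ("bge", "changepoint"),
    "bgm": ("bge", "free"),
    "bdmd": ("bde", "changepoint"),
    "bdm": ("bde", "free"),
    "bge": ("bge", "none"),
    "bde": ("bde", "none"),
}


@dataclass
class SamplerConfig:
    """Run configuration.

    Defaults mirror a production schedule (5 x 10^5 burn-in and sampling
    iterations, thinning 1000, 5 chains, K* = 10, fan-in 3); tests and the
    bundled examples use much shorter schedules.
    """

    model: str = "bgmd"
    burn_in: int = 500_000
    sampling: int = 500_000
    thinning: int = 1_000
    chains: int = 5
    structure_move_prob: float = 0.5
    k_max: int = 10
    fan_in: int = 3
    allow_self_loops: bool = True
    lam: float = 1.0
    init: str = "empty"          # or "random"
    seed: int = 0
    bge_hyper: BGeHyper | None = None
    bde_hyper: BDeHyper | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODEL_INFO:
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.burn_in, self.sampling, self.thinning) < 0 or \
                self.thinning < 1:
            raise ValueError("schedule lengths must be positive")

    @property
    def score(self) -> str:
        return _MODEL_INFO[self.model][0]

    @property
    def allocation_kind(self) -> str:
        return _MODEL_INFO[self.model][1]


@dataclass
class SamplerState:
    """Current sampler position: graph, allocation (with its changepoints in
    the changepoint models), K, and the cached total log marginal."""

    graph: Graph
    k: int
    allocation: np.ndarray
    changepoints: np.ndarray | None
    log_lik: float


@dataclass(frozen=True)
class TraceSample:
    iteration: int
    k: int
    log_post: float
    edges: frozenset
    allocation: tuple
    changepoints: tuple | None


@dataclass
class TraceSet:
    """Thinned post-burn-in sample of states from one chain."""

    samples: list = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)
    attempts: dict = field(default_factory=dict)
    config: SamplerConfig | None = None
    m: int = 0
    n_nodes: int = 0

    def __len__(self) -> int:
        return len(self.samples)


def _node_block_score(scorer, graph: Graph, node: int,
                      segments: list[tuple[int, ...]]) -> float:
    parents = graph.parents(node)
    return sum(scorer.family_log_score(node, parents, seg)
               for seg in segments)


def _total_log_lik(scorer, graph: Graph,
                   segments: list[tuple[int, ...]]) -> float:
    return sum(_node_block_score(scorer, graph, n, segments)
               for n in range(graph.n_nodes))


def _segments_from_allocation(allocation: np.ndarray,
                              k: int) -> list[tuple[int, ...]]:
    return [tuple(int(t) for t in np.nonzero(allocation == j)[0] + 2)
            for j in range(1, k + 1)]


def _log_alloc_prior(state: SamplerState, kind: str, kprior: cp.KPrior,
                     m: int) -> float:
    lp = kprior.log_prob(state.k)
    if kind == "changepoint":
        lp += cp.log_changepoint_prior_density(state.changepoints, m)
    elif kind == "free":
        lp += fa.log_free_allocation_prior(state.allocation, state.k)
    return lp


def _initial_state(config: SamplerConfig, n_nodes: int, m: int,
                   kprior: cp.KPrior, scorer,
                   rng: np.random.Generator) -> SamplerState:
    if config.init == "empty":
        graph = Graph.empty(n_nodes, config.fan_in, config.allow_self_loops)
        k = 1
        b = np.empty(0)
    elif config.init == "random":
        graph = Graph.empty(n_nodes, config.fan_in, config.allow_self_loops)
        for _ in range(rng.integers(0, n_nodes * 2 + 1)):
            graph = propose_structure_move(graph, rng)
        if config.allocation_kind == "none":
            k, b = 1, np.empty(0)
        else:
            k = 1 + int(rng.choice(kprior.k_max, p=kprior.probs()))
            b = cp.sample_changepoints_from_prior(k, m, rng)
    else:
        raise ValueError(f"unknown init mode {config.init!r}")
    if config.allocation_kind in ("changepoint", "none"):
        alloc = cp.allocation_from_changepoints(b, m)
        changepts = b
    else:
        alloc = cp.allocation_from_changepoints(b, m)
        changepts = None
    segments = _segments_from_allocation(alloc, k)
    log_lik = _total_log_lik(scorer, graph, segments)
    return SamplerState(graph, k, alloc, changepts, log_lik)


def _structure_move(state: SamplerState, scorer, rng, counters) -> None:
    counters["attempts"]["structure"] += 1
    graph = state.graph
    candidate = propose_structure_move(graph, rng)
    changed = next(iter(candidate.edges ^ graph.edges))[1]
    segments = _segments_from_allocation(state.allocation, state.k)
    delta = (_node_block_score(scorer, candidate, changed, segments)
             - _node_block_score(scorer, graph, changed, segments))
    log_acc = log_structure_acceptance(0.0, delta, graph, candidate)
    if np.log(rng.uniform()) < log_acc:
        state.graph = candidate
        state.log_lik += delta
        counters["accepted"]["structure"] += 1


def _changepoint_segments_delta(state: SamplerState, scorer,
                                b_new: np.ndarray, m: int) -> float:
    """Likelihood delta from replacing the whole changepoint set; relies on
    the score cache so only genuinely new segments cost work."""
    k_new = b_new.size + 1
    alloc_new = cp.allocation_from_changepoints(b_new, m)
    seg_new = _segments_from_allocation(alloc_new, k_new)
    seg_old = _segments_from_allocation(state.allocation, state.k)
    new_lik = _total_log_lik(scorer, state.graph, seg_new)
    old_lik = _total_log_lik(scorer, state.graph, seg_old)
    return new_lik - old_lik


def _changepoint_move(state: SamplerState, scorer, rng, kprior, moveprobs,
                      m: int, counters) -> None:
    k = state.k
    b = state.changepoints
    u = rng.uniform()
    pb = moveprobs.birth[k - 1]
    pd = moveprobs.death[k - 1]
    if u < pb:
        kind = "cp_birth"
    elif u < pb + pd:
        kind = "cp_death"
    else:
        kind = "cp_realloc"
    counters["attempts"][kind] += 1

    if kind == "cp_birth":
        if k >= kprior.k_max:
            return
        b_new_pt = rng.uniform(2.0, float(m))
        if np.any(b == b_new_pt):            # measure-zero degenerate draw
            return
        full = np.concatenate([[2.0], b, [float(m)]])
        j = int(np.searchsorted(full, b_new_pt)) - 1
        log_rb = cp.log_birth_factor(k, m, b_new_pt, full[j], full[j + 1])
        b_new = np.sort(np.append(b, b_new_pt))
    elif kind == "cp_death":
        if k <= 1:
            return
        idx = int(rng.integers(b.size))
        full = np.concatenate([[2.0], b, [float(m)]])
        log_rb = cp.log_death_factor(k, m, b[idx], full[idx], full[idx + 2])
        b_new = np.delete(b, idx)
    else:
        if k <= 1:
            return
        idx = int(rng.integers(b.size))
        full = np.concatenate([[2.0], b, [float(m)]])
        left, right = full[idx], full[idx + 2]
        b_dagger = rng.uniform(left, right)
        if b_dagger == b[idx] or b_dagger == left or b_dagger == right:
            return
        log_rb = cp.log_changepoint_prior_ratio_realloc(
            left, b[idx], b_dagger, right)
        b_new = b.copy()
        b_new[idx] = b_dagger

    delta = _changepoint_segments_delta(state, scorer, b_new, m)
    if np.log(rng.uniform()) < min(0.0, delta + log_rb):
        state.changepoints = b_new
        state.k = b_new.size + 1
        state.allocation = cp.allocation_from_changepoints(b_new, m)
        state.log_lik += delta
        counters["accepted"][kind] += 1


def _free_allocation_move(state: SamplerState, scorer, rng, kprior,
                          counters) -> None:
    u = rng.uniform()
    if u < 0.5:
        counters["attempts"]["fa_gibbs"] += 1
        state.allocation = fa.gibbs_reassign(
            state.allocation, state.k, scorer, state.graph, rng)
        segments = _segments_from_allocation(state.allocation, state.k)
        state.log_lik = _total_log_lik(scorer, state.graph, segments)
        counters["accepted"]["fa_gibbs"] += 1
    elif u < 0.75:
        counters["attempts"]["fa_birth"] += 1
        state.allocation, state.k, acc = fa.empty_component_birth(
            state.allocation, state.k, kprior, rng, 0.25, 0.25)
        counters["accepted"]["fa_birth"] += int(acc)
    else:
        counters["attempts"]["fa_death"] += 1
        state.allocation, state.k, acc = fa.empty_component_death(
            state.allocation, state.k, kprior, rng, 0.25, 0.25)
        counters["accepted"]["fa_death"] += int(acc)


def run_chain(data: TimeSeriesDataset | None, config: SamplerConfig,
              rng: np.random.Generator | None = None,
              m: int | None = None, n_nodes: int | None = None,
              prior_only: bool = False) -> TraceSet:
    """Run one MCMC chain and return the thinned post-burn-in trace.

    With ``data=None`` (or ``prior_only=True``) the run is purely
    prior-driven: every compartment factor is Psi = 1 and, since structure
    moves then have no effect, only allocation moves are performed; ``m``
    and ``n_nodes`` must be supplied in that case.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    prior_only = prior_only or data is None
    if prior_only:
        if m is None:
            raise ValueError("prior-only runs need an explicit m")
        n_nodes = n_nodes or 1
        scorer = make_scorer(None, config.score)
    else:
        m = data.m
        n_nodes = data.n_nodes
        scorer = make_scorer(data, config.score, config.bge_hyper,
                             config.bde_hyper)

    kprior = cp.KPrior(lam=config.lam, k_max=config.k_max)
    moveprobs = cp.move_probabilities(kprior)
    state = _initial_state(config, n_nodes, m, kprior, scorer, rng)

    move_names = ["structure", "cp_birth", "cp_death", "cp_realloc",
                  "fa_gibbs", "fa_birth", "fa_death"]
    counters = {"attempts": dict.fromkeys(move_names, 0),
                "accepted": dict.fromkeys(move_names, 0)}

    kind = config.allocation_kind
    trace = TraceSet(config=config, m=m, n_nodes=n_nodes)
    total = config.burn_in + config.sampling
    for it in range(1, total + 1):
        if kind == "none":
            do_structure = True
        elif prior_only:
            do_structure = False
        else:
            do_structure = rng.uniform() < config.structure_move_prob
        if do_structure:
            _structure_move(state, scorer, rng, counters)
        elif kind == "changepoint":
            _changepoint_move(state, scorer, rng, kprior, moveprobs, m,
                              counters)
        elif kind == "free":
            _free_allocation_move(state, scorer, rng, kprior, counters)

        if it > config.burn_in and (it - config.burn_in) % config.thinning == 0:
            log_post = state.log_lik + _log_alloc_prior(state, kind, kprior, m)
            trace.samples.append(TraceSample(
                iteration=it,
                k=state.k,
                log_post=float(log_post),
                edges=state.graph.edges,
                allocation=tuple(int(x) for x in state.allocation),
                changepoints=(tuple(float(x) for x in state.changepoints)
                              if state.changepoints is not None else None),
            ))
    trace.acceptance = counters["accepted"]
    trace.attempts = counters["attempts"]
    return trace


def run_multi_chain(data: TimeSeriesDataset | None, config: SamplerConfig,
                    **kwargs) -> list[TraceSet]:
    """Run ``config.chains`` independently seeded chains (seeds spawned from
    ``config.seed``); chain 0 reproduces ``run_chain`` with the same config."""
    traces = []
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.chains):
        traces.append(run_chain(data, config,
                                rng=np.random.default_rng(child), **kwargs))
    return traces


def export_trace(trace: TraceSet, path) -> None:
    """Write one row per kept sample: iteration, K, log posterior, edge
    bit-vector (row-major over source x target) and changepoint locations."""
    n = trace.n_nodes
    rows = []
    for s in trace.samples:
        bits = "".join("1" if (i, j) in s.edges else "0"
                       for i in range(n) for j in range(n))
        cps = ";".join(f"{b:.6f}" for b in s.changepoints) \
            if s.changepoints is not None else ""
        rows.append((s.iteration, s.k, s.log_post, bits, cps))
    df = pd.DataFrame(rows, columns=["iteration", "K", "log_posterior",
                                     "edge_bits", "changepoints"])
    df.to_csv(path, sep="\t", index=False)
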