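"""Synthetic time-series generators with known ground truth.

Three designs:

* a sinusoid state-space network — a random-walk-with-drift regulator X
  driving one or three targets through a sine nonlinearity, the benchmark on
  which changepoint and free-allocation models are compared;
* piecewise-stationary linear-Gaussian series with known changepoints, for
  changepoint-recovery checks;
* a per-gene median split that binarises continuous data for the discrete
  (BDe-scored) models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import TimeSeriesDataset
from .graph import Graph

__all__ = ["SineNetworkConfig", "generate_sine_network",
           "generate_piecewise_series", "quantile_binarise"]

DEFAULT_DRIFT = 2.0 * np.pi / 40.0


@dataclass
class SineNetworkConfig:
    """Sinusoid network design.

    The regulator follows X(t) = X(t-1) + c + c_X eps_X(t) and each target
    Y_i(t) = sin(X(t-1) + tau_i pi) + c_Y eps_Y,i(t) with iid standard normal
    noise.  The default drift c = 2 pi / 40 with m = 41 observations sweeps
    one full period of the sine on average.  With one target tau = (0,);
    with three, the periods are shifted by tau = (0, 2/3, 4/3).
    """

    n_targets: int = 1
    drift: float = DEFAULT_DRIFT
    c_x: float = 0.5
    c_y: float = 0.5
    m: int = 41
    phase_shifts: tuple | None = None
    x_init: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets not in (1, 3):
            raise ValueError("n_targets must be 1 or 3")
        if self.m < 3:
            raise ValueError("m must be at least 3")
        if self.c_x < 0 or self.c_y < 0:
            raise ValueError("noise scales must be non-negative")
        if self.phase_shifts is None:
            self.phase_shifts = (0.0,) if self.n_targets == 1 \
                else (0.0, 2.0 / 3.0, 4.0 / 3.0)
        if len(self.phase_shifts) != self.n_targets:
            raise ValueError("one phase shift per target required")


def generate_sine_network(config: SineNetworkConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[TimeSeriesDataset, Graph]:
    """Generate one sinusoid-network dataset and its true structure
    {X -> X, X -> Y_i}."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    m = config.m
    x = np.empty(m)
    x[0] = config.x_init
    for t in range(1, m):
        x[t] = x[t - 1] + config.drift + config.c_x * rng.standard_normal()
    ys = np.empty((config.n_targets, m))
    for i, tau in enumerate(config.phase_shifts):
        noise = config.c_y * rng.standard_normal(m)
        ys[i, 0] = np.sin(config.x_init + tau * np.pi) + noise[0]
        ys[i, 1:] = np.sin(x[:-1] + tau * np.pi) + noise[1:]
    values = np.vstack([x, ys])
    names = ["X"] + (["Y"] if config.n_targets == 1
                     else [f"Y{i+1}" for i in range(config.n_targets)])
    data = TimeSeriesDataset(values, names, mode="continuous")
    edges = frozenset({(0, 0)} | {(0, i + 1) for i in range(config.n_targets)})
    truth = Graph(n_nodes=1 + config.n_targets, edges=edges,
                  fan_in_bound=3, allow_self_loops=True)
    return data, truth


def generate_piecewise_series(segment_params: list[dict], m: int,
                              seed: int = 0, n_nodes: int = 2,
                              rng: np.random.Generator | None = None
                              ) -> tuple[TimeSeriesDataset, list[int]]:
    """Piecewise-stationary linear-Gaussian series with known changepoints.

    One regulator X (iid standard normal) drives ``n_nodes - 1`` targets
    Y_i(t) = a X(t-1) + s eps_i(t); each entry of ``segment_params``
    describes one segment, ``{"length": L, "coef": a, "noise": s}``.  The
    network structure (X -> Y_i) is shared across segments; only the
    coefficients change.  Returns the dataset and the 1-based time indices
    of the first time point of each new segment (the true changepoint gaps
    are (t-1, t)).
    """
    if not segment_params:
        raise ValueError("need at least one segment")
    if n_nodes < 2:
        raise ValueError("need the regulator plus at least one target")
    lengths = [int(p["length"]) for p in segment_params]
    if min(lengths) < 2:
        raise ValueError("segments must contain at least 2 time points")
    if sum(lengths) != m:
        raise ValueError("segment lengths must sum to m")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_targets = n_nodes - 1
    x = rng.standard_normal(m)
    ys = np.empty((n_targets, m))
    ys[:, 0] = segment_params[0].get("noise", 1.0) * \
        rng.standard_normal(n_targets)
    bounds = np.cumsum([0] + lengths)
    true_changepoints = [int(b) + 1 for b in bounds[1:-1]]
    for seg, p in enumerate(segment_params):
        a = float(p["coef"])
        s = float(p.get("noise", 1.0))
        lo = max(bounds[seg], 1)
        hi = bounds[seg + 1]
        for t in range(lo, hi):
            ys[:, t] = a * x[t - 1] + s * rng.standard_normal(n_targets)
    names = ["X"] + (["Y"] if n_targets == 1
                     else [f"Y{i+1}" for i in range(n_targets)])
    data = TimeSeriesDataset(np.vstack([x, ys]), names, mode="continuous")
    return data, true_changepoints


def quantile_binarise(data: TimeSeriesDataset) -> TimeSeriesDataset:
    """Binarise each gene at its median: values <= median become category 1,
    values above become category 2 (ties go to the lower category).
    Constant genes are degenerate and rejected."""
    if data.mode != "continuous":
        raise ValueError("binarisation expects continuous data")
    values = np.empty_like(data.values)
    for i in range(data.n_nodes):
        row = data.values[i]
        if np.ptp(row) == 0:
            raise ValueError(
                f"gene {data.node_names[i]!r} is constant; median split "
                "is degenerate")
        med = np.median(row)
        values[i] = np.where(row <= med, 1.0, 2.0)
    return TimeSeriesDataset(values, list(data.node_names), mode="discrete",
                             n_categories=2)
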