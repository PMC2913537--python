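"""Time-series containers and plain-text I/O.

A dataset is a rectangular gene-by-time matrix sampled at equidistant time
points t = 1..m.  Continuous data feed the Gaussian (BGe) scores, discrete
data (small integer categories 1..r) feed the multinomial (BDe) scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesDataset", "read_timeseries", "write_timeseries"]


@dataclass
class TimeSeriesDataset:
    """Gene-expression time series: N node rows by m equidistant time columns.

    Parameters
    ----------
    values
        N x m matrix.  Real-valued in continuous mode; integer category
        labels 1..r in discrete mode.
    node_names
        N identifiers, unique.
    mode
        ``"continuous"`` or ``"discrete"``.
    n_categories
        Number of categories r in discrete mode (inferred from the data when
        omitted); ignored in continuous mode.
    """

    values: np.ndarray
    node_names: list[str]
    mode: str = "continuous"
    n_categories: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (nodes x time)")
        n, m = self.values.shape
        if m < 3:
            raise ValueError(f"need at least 3 time points, got m={m}")
        if len(self.node_names) != n:
            raise ValueError("node_names length does not match the row count")
        if len(set(self.node_names)) != n:
            raise ValueError("duplicate node names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite cells are not supported")
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "discrete":
            ints = np.rint(self.values)
            if not np.allclose(self.values, ints):
                raise ValueError("discrete mode requires integer category labels")
            self.values = ints
            if self.values.min() < 1:
                raise ValueError("category labels must start at 1")
            r = int(self.values.max())
            if self.n_categories is None:
                self.n_categories = max(r, 2)
            elif r > self.n_categories:
                raise ValueError(
                    f"label {r} outside the declared range 1..{self.n_categories}"
                )
            if self.n_categories < 2:
                raise ValueError("discrete data need at least 2 categories")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of time points."""
        return self.values.shape[1]

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)

    def standardise(self) -> "TimeSeriesDataset":
        """Gene-wise z-scoring (continuous mode only).

        The Gaussian score with the default identity precision scale is not
        invariant to the measurement scale, so expression matrices are
        conventionally standardised before inference.
        """
        if self.mode != "continuous":
            raise ValueError("standardise applies to continuous data")
        sd = self.values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot standardise a constant gene")
        vals = (self.values - self.values.mean(axis=1, keepdims=True)) / sd
        return TimeSeriesDataset(vals, list(self.node_names),
                                 mode="continuous")


def read_timeseries(path, mode: str = "continuous",
                    n_categories: int | None = None,
                    transpose: bool = False) -> TimeSeriesDataset:
    """Read a TSV/CSV table: first column node names, remaining columns the
    time points in order.  ``transpose=True`` reads time points in rows."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = df.index[np.isnan(values).any(axis=1)][0]
        raise ValueError(f"non-numeric or missing cell in row {bad!r}")
    names = [str(x) for x in df.index]
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names in the first column")
    return TimeSeriesDataset(values, names, mode=mode, n_categories=n_categories)


def write_timeseries(data: TimeSeriesDataset, path) -> None:
    """Write a dataset as a tab-separated table with 1-based time labels."""
    df = pd.DataFrame(
        data.values,
        index=data.node_names,
        columns=[f"t{t}" for t in range(1, data.m + 1)],
    )
    if data.mode == "discrete":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="node")
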