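"""Functional-connectivity matrices and network-level connectivity summaries.

A subject's connectome is the matrix of Pearson correlations between every
pair of regional time series.  Three summaries condense it over a network
partition:

* **WNC** (within-network connectivity): mean FC over all node pairs inside
  one network — 10 values for a 10-network partition.
* **BNC** (between-network connectivity): mean FC over all node pairs
  spanning two distinct networks — one value per unordered network pair,
  C(10, 2) = 45 values.
* **OVO** (one-versus-all-others): mean FC over all node pairs linking one
  network to the nodes of every other network — 10 values.

All means are plain arithmetic means over node pairs.  OVO therefore equals
the pair-count-weighted mean of the corresponding BNC values, an identity the
test suite asserts.  Negative correlations enter the means as-is: no absolute
value, no thresholding.  Averaging is done on raw r by default; the Fisher
z transform is available and propagates through every summary unchanged.

The matrix diagonal carries NaN as an explicit sentinel so self-correlations
can never leak into a mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import AtlasPartition
from .errors import DataError, NumericalError

__all__ = [
    "Connectome",
    "NetworkSummary",
    "compute_fc",
    "fisher_z",
    "summarize_networks",
    "summarize_cohort",
    "fci",
    "canonical_edges",
    "metric_names",
]


@dataclass(frozen=True)
class Connectome:
    """Symmetric node-by-node functional connectivity matrix.

    ``scale`` records whether entries are raw Pearson r (bounded in [-1, 1])
    or Fisher z values.  The diagonal is NaN and is ignored by every summary.
    """

    values: np.ndarray
    scale: str = "pearson_r"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError(f"connectome must be square, got shape {v.shape}")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=1e-10, equal_nan=True):
            raise DataError("connectome matrix is not symmetric")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "pearson_r" and np.any(np.abs(v[off]) > 1 + 1e-12):
            raise DataError("pearson_r connectome has off-diagonal |r| > 1")
        v = v.copy()
        np.fill_diagonal(v, np.nan)
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_fc(time_series: np.ndarray) -> Connectome:
    """Pearson-correlation connectome from a T x N time-series matrix.

    Raises :class:`NumericalError` naming the offending node if any column is
    constant (its correlation is undefined; failing loudly beats silent NaN).
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2:
        raise DataError(f"time series must be 2-D, got shape {ts.shape}")
    if ts.shape[0] < 3:
        raise DataError(f"need at least 3 timepoints, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        node = int(np.flatnonzero(sd == 0)[0])
        raise NumericalError(
            f"constant time series for node {node + 1}: correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    # guard against tiny excursions beyond [-1, 1] from floating point
    np.clip(r, -1.0, 1.0, out=r)
    return Connectome(values=r, scale="pearson_r")


def fisher_z(conn: Connectome) -> Connectome:
    """Entrywise Fisher z transform, z = atanh(r)."""
    if conn.scale != "pearson_r":
        raise DataError("fisher_z expects a pearson_r connectome")
    off = ~np.eye(conn.n_nodes, dtype=bool)
    if np.any(np.abs(conn.values[off]) >= 1):
        raise NumericalError("|r| = 1 entry: Fisher z is infinite")
    return Connectome(values=np.arctanh(np.where(off, conn.values, 0.0)),
                      scale="fisher_z")


@dataclass(frozen=True)
class NetworkSummary:
    """Per-subject network-level connectivity summaries.

    ``wnc`` and ``ovo`` are indexed by network name; ``bnc`` by unordered
    network pair (name_a, name_b) with a < b lexicographic ordering of the
    partition's network order.  ``pair_counts`` gives the number of node
    pairs entering each mean under the same keys.
    """

    networks: tuple[str, ...]
    wnc: Mapping[str, float]
    ovo: Mapping[str, float]
    bnc: Mapping[tuple[str, str], float]
    pair_counts: Mapping[object, int]
    scale: str = "pearson_r"

    def to_series(self) -> pd.Series:
        """Flatten to a Series keyed by canonical metric names."""
        data = {f"WNC:{n}": self.wnc[n] for n in self.networks}
        data.update({f"OVO:{n}": self.ovo[n] for n in self.networks})
        for a, b in itertools.combinations(self.networks, 2):
            data[f"BNC:{a}-{b}"] = self.bnc[(a, b)]
        return pd.Series(data)


def metric_names(partition: AtlasPartition) -> list[str]:
    """Canonical ordering of the network-metric family: WNC, OVO, then BNC."""
    nets = partition.network_names
    names = [f"WNC:{n}" for n in nets] + [f"OVO:{n}" for n in nets]
    names += [f"BNC:{a}-{b}" for a, b in itertools.combinations(nets, 2)]
    return names


def summarize_networks(conn: Connectome, partition: AtlasPartition) -> NetworkSummary:
    """Compute WNC, pairwise BNC, and OVO over a partition.

    Every network needs at least two nodes for WNC to be defined; a singleton
    network is an error rather than a silent NaN.
    """
    if partition.n_nodes != conn.n_nodes:
        raise DataError(
            f"partition has {partition.n_nodes} nodes, connectome {conn.n_nodes}"
        )
    v = conn.values
    nets = partition.network_names
    idx = {n: partition.indices(n) for n in nets}
    for n in nets:
        if len(idx[n]) < 2:
            raise DataError(f"network {n!r} has fewer than 2 nodes: WNC undefined")

    wnc: dict[str, float] = {}
    bnc: dict[tuple[str, str], float] = {}
    counts: dict[object, int] = {}
    for n in nets:
        block = v[np.ix_(idx[n], idx[n])]
        iu = np.triu_indices(len(idx[n]), k=1)
        wnc[n] = float(block[iu].mean())
        counts[n] = len(iu[0])
    for a, b in itertools.combinations(nets, 2):
        block = v[np.ix_(idx[a], idx[b])]
        bnc[(a, b)] = float(block.mean())
        counts[(a, b)] = block.size
    # OVO pools all inter-network node pairs touching the network, i.e. the
    # pair-count-weighted mean of its 9 BNC values.
    ovo: dict[str, float] = {}
    for n in nets:
        total = 0.0
        m = 0
        for o in nets:
            if o == n:
                continue
            key = (n, o) if (n, o) in bnc else (o, n)
            total += bnc[key] * counts[key]
            m += counts[key]
        ovo[n] = total / m
    return NetworkSummary(
        networks=nets, wnc=wnc, ovo=ovo, bnc=bnc, pair_counts=counts,
        scale=conn.scale,
    )


def summarize_cohort(
    connectomes: Mapping[str, Connectome], partition: AtlasPartition
) -> pd.DataFrame:
    """Summaries for a whole cohort: subjects x metrics DataFrame.

    Columns follow :func:`metric_names` order (10 WNC + 10 OVO + 45 BNC = 65
    for the default partition); the index is the subject id.
    """
    rows = {sid: summarize_networks(c, partition).to_series()
            for sid, c in connectomes.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.loc[:, metric_names(partition)]


def canonical_edges(edges: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    """Normalize an iterable of node pairs to a set of (i, j) with i < j."""
    out = set()
    for i, j in edges:
        if i == j:
            raise DataError(f"self-loop on node {i + 1}")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


def fci(conn: Connectome, edges: Iterable[tuple[int, int]]) -> float:
    """FC index: mean connectivity over a designated edge set.

    The FCI condenses a set of differential connections into one subject-level
    composite used for correlation analyses and as a classification feature.
    """
    es = canonical_edges(edges)
    if not es:
        raise DataError("empty edge set: FCI undefined")
    n = conn.n_nodes
    for i, j in es:
        if not (0 <= i < n and 0 <= j < n):
            raise DataError(f"edge ({i + 1},{j + 1}) outside matrix of {n} nodes")
    ii, jj = zip(*sorted(es))
    return float(conn.values[np.array(ii), np.array(jj)].mean())
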