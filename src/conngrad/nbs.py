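"""Network-based statistic (NBS): component-level permutation inference.

Mass-univariate edge statistics on subject connectomes are thresholded and
the surviving edges grouped into connected components; family-wise error is
controlled at the component level by comparing each observed component's
extent (edge count) against the permutation distribution of the maximal
component extent under exchanged group labels.

Edge statistic
--------------
For every upper-triangle edge, the t statistic of the group indicator in an
ordinary least-squares model of edge FC on group + covariates (age, sex,
education, site).  The group indicator is 1 for the A group, so a positive
statistic means A-group mean above B-group mean.  The computation is
vectorized across all edges at once: one normal-equations solve per design,
shared across the ~25k edges of a 226-node matrix, which is what makes
thousands of permutations tractable.

Primary threshold
-----------------
The edge-forming threshold defaults to the two-sided p = 0.001 critical t at
the model's residual degrees of freedom; it is always recorded in the result.
Positive and negative directions are tested separately and the component
p-values Bonferroni-corrected by the number of directions (the correction
family size is exposed because conventions differ).

Permutation schemes
-------------------
``labels`` permutes the group indicator only (covariates stay with their
subjects); ``freedman_lane`` permutes the residuals of the covariates-only
model and adds them back to its fitted values, the standard scheme when
nuisance covariates are present.  An optional stratification restricts label
exchanges to within strata (e.g. within site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.stats as sps

from .connectome import Connectome, canonical_edges
from .errors import ConfigError, DataError
from .inference import covariate_design, _check_rank

__all__ = [
    "NBSComponent",
    "NBSResult",
    "stack_edges",
    "edge_stats",
    "extract_components",
    "nbs_test",
    "conjunction",
    "overlap_edges",
]


def stack_edges(
    connectomes: Sequence[Connectome | np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Stack upper-triangle edges into a subjects x edges matrix.

    Returns (Y, row_idx, col_idx, n_nodes) where Y[s, e] is subject s's FC on
    edge e = (row_idx[e], col_idx[e]).
    """
    mats = [c.values if isinstance(c, Connectome) else np.asarray(c, float)
            for c in connectomes]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise DataError("connectomes have inconsistent sizes")
    iu = np.triu_indices(n, k=1)
    Y = np.stack([m[iu] for m in mats])
    return Y, iu[0], iu[1], n


def _vectorized_t(Y: np.ndarray, X: np.ndarray, col: int) -> np.ndarray:
    """OLS t statistic of X[:, col], computed jointly for every column of Y.

    Degenerate edges (zero residual variance) get t = 0.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    if df <= 0:
        raise DataError(f"non-positive residual df ({df}): too few subjects")
    sigma2 = np.maximum(np.einsum("ij,ij->j", resid, resid), 0.0) / df
    # edges with (numerically) zero residual variance relative to their own
    # scale are degenerate: identical values across subjects -> statistic 0
    tol = 1e-12 * np.maximum((Y ** 2).mean(axis=0), 1e-30)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[col, col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sigma2 > tol, beta[col] / np.where(se > 0, se, 1.0), 0.0)
    return t


def _design(
    indicator: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, int]:
    C, names = covariate_design(covariates, len(indicator))
    X = np.column_stack([C, indicator.astype(float)])
    _check_rank(X, names + ["group"])
    return X, X.shape[1] - 1


def edge_stats(
    connectomes_a: Sequence[Connectome | np.ndarray],
    connectomes_b: Sequence[Connectome | np.ndarray],
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Per-edge group t-statistic matrix for an A-vs-B contrast.

    ``covariates`` rows must be ordered A-group subjects first, then B-group.
    Returns a symmetric n x n matrix with zeros on the diagonal; positive
    entries mean A mean > B mean after covariate adjustment.
    """
    na, nb = len(connectomes_a), len(connectomes_b)
    if na < 3 or nb < 3:
        raise DataError(f"each group needs n >= 3 (got {na}, {nb})")
    Y, ii, jj, n = stack_edges(list(connectomes_a) + list(connectomes_b))
    indicator = np.r_[np.ones(na), np.zeros(nb)]
    X, col = _design(indicator, covariates)
    t = _vectorized_t(Y, X, col)
    out = np.zeros((n, n))
    out[ii, jj] = t
    out[jj, ii] = t
    return out


def _component_edge_sets(
    ii: np.ndarray, jj: np.ndarray, n_nodes: int
) -> list[frozenset[tuple[int, int]]]:
    """Connected components (as edge sets) of the graph with edges (ii, jj)."""
    if len(ii) == 0:
        return []
    nodes = np.unique(np.concatenate([ii, jj]))
    remap = np.full(n_nodes, -1, dtype=int)
    remap[nodes] = np.arange(len(nodes))
    g = sp.coo_matrix(
        (np.ones(len(ii)), (remap[ii], remap[jj])), shape=(len(nodes), len(nodes))
    )
    _, labels = csgraph.connected_components(g, directed=False)
    edge_label = labels[remap[ii]]
    comps: dict[int, set[tuple[int, int]]] = {}
    for a, b, lab in zip(ii, jj, edge_label):
        comps.setdefault(int(lab), set()).add((min(a, b), max(a, b)))
    return [frozenset(c) for c in
            sorted(comps.values(), key=len, reverse=True)]


def extract_components(
    stat_matrix: np.ndarray,
    primary_threshold: float,
    direction: str = "positive",
) -> list[frozenset[tuple[int, int]]]:
    """Connected components of the suprathreshold graph, largest first.

    ``positive`` keeps edges with statistic >= threshold, ``negative`` those
    with statistic <= -threshold.  An empty graph yields an empty list.
    """
    if primary_threshold <= 0:
        raise ConfigError("primary_threshold must be positive")
    m = np.asarray(stat_matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    if direction == "positive":
        keep = vals >= primary_threshold
    elif direction == "negative":
        keep = vals <= -primary_threshold
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    return _component_edge_sets(iu[0][keep], iu[1][keep], m.shape[0])


def _max_component_size(ii: np.ndarray, jj: np.ndarray, n_nodes: int) -> int:
    """Edge count of the largest connected component (0 for no edges)."""
    if len(ii) == 0:
        return 0
    if len(ii) == 1:
        return 1
    nodes = np.unique(np.concatenate([ii, jj]))
    remap = np.full(n_nodes, -1, dtype=int)
    remap[nodes] = np.arange(len(nodes))
    g = sp.coo_matrix(
        (np.ones(len(ii)), (remap[ii], remap[jj])), shape=(len(nodes), len(nodes))
    )
    _, labels = csgraph.connected_components(g, directed=False)
    counts = np.bincount(labels[remap[ii]])
    return int(counts.max())


@dataclass(frozen=True)
class NBSComponent:
    edges: frozenset[tuple[int, int]]
    direction: str
    p: float
    p_corrected: float

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class NBSResult:
    contrast: tuple[str, str]
    primary_threshold: float
    components: tuple[NBSComponent, ...]
    null_max_sizes: Mapping[str, np.ndarray]
    n_permutations: int
    seed: int
    permute: str

    def significant_edges(self, alpha: float = 0.05) -> frozenset[tuple[int, int]]:
        """Union of edges over components with corrected p <= alpha."""
        out: set[tuple[int, int]] = set()
        for c in self.components:
            if c.p_corrected <= alpha:
                out |= c.edges
        return frozenset(out)


def _permutation_indices(
    rng: np.random.Generator, n: int, strata: Sequence | None
) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    order = np.arange(n)
    s = np.asarray(strata)
    for lev in np.unique(s):
        idx = np.flatnonzero(s == lev)
        order[idx] = idx[rng.permutation(len(idx))]
    return order


def nbs_test(
    connectomes_a: Sequence[Connectome | np.ndarray],
    connectomes_b: Sequence[Connectome | np.ndarray],
    covariates: pd.DataFrame | None = None,
    primary_threshold: float | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    permute: str = "labels",
    strata: Sequence | None = None,
    contrast: tuple[str, str] = ("A", "B"),
    bonferroni_factor: int | None = None,
) -> NBSResult:
    """Component-extent NBS for an A-vs-B contrast.

    Component p = (1 + #{null max extent >= observed extent}) /
    (1 + n_permutations), per direction; corrected p multiplies by
    ``bonferroni_factor`` (default: the two directions tested).
    """
    if n_permutations < 100:
        raise ConfigError("n_permutations must be at least 100")
    na, nb = len(connectomes_a), len(connectomes_b)
    if na < 3 or nb < 3:
        raise DataError(f"each group needs n >= 3 (got {na}, {nb})")
    Y, ii, jj, n_nodes = stack_edges(list(connectomes_a) + list(connectomes_b))
    n = na + nb
    indicator = np.r_[np.ones(na), np.zeros(nb)]
    X, col = _design(indicator, covariates)
    if primary_threshold is None:
        df = n - X.shape[1]
        primary_threshold = float(sps.t.isf(0.001 / 2, df))
    directions = ("positive", "negative")
    factor = len(directions) if bonferroni_factor is None else bonferroni_factor

    t_obs = _vectorized_t(Y, X, col)
    obs_comps = {}
    for d in directions:
        keep = t_obs >= primary_threshold if d == "positive" else t_obs <= -primary_threshold
        obs_comps[d] = _component_edge_sets(ii[keep], jj[keep], n_nodes)

    if permute == "freedman_lane":
        # residualize on the covariates-only model once; permutations shuffle
        # the residuals and add back the nuisance fit
        Z = X[:, :col]
        Zb = np.linalg.lstsq(Z, Y, rcond=None)[0]
        fitted = Z @ Zb
        resid = Y - fitted
    elif permute != "labels":
        raise ConfigError(f"unknown permutation scheme {permute!r}")

    rng = np.random.default_rng(seed)
    null = {d: np.empty(n_permutations) for d in directions}
    for b in range(n_permutations):
        order = _permutation_indices(rng, n, strata)
        if permute == "labels":
            Xp = X.copy()
            Xp[:, col] = indicator[order]
            t_null = _vectorized_t(Y, Xp, col)
        else:
            t_null = _vectorized_t(fitted + resid[order], X, col)
        for d in directions:
            keep = (t_null >= primary_threshold if d == "positive"
                    else t_null <= -primary_threshold)
            null[d][b] = _max_component_size(ii[keep], jj[keep], n_nodes)

    components = []
    for d in directions:
        for edges in obs_comps[d]:
            p = float((1 + np.sum(null[d] >= len(edges))) / (1 + n_permutations))
            components.append(NBSComponent(
                edges=edges, direction=d, p=p,
                p_corrected=min(1.0, p * factor),
            ))
    components.sort(key=lambda c: (c.p, -c.size))
    return NBSResult(
        contrast=contrast,
        primary_threshold=float(primary_threshold),
        components=tuple(components),
        null_max_sizes={d: null[d].copy() for d in directions},
        n_permutations=n_permutations,
        seed=seed,
        permute=permute,
    )


def conjunction(
    edge_sets: Sequence[Iterable[tuple[int, int]]],
) -> frozenset[tuple[int, int]]:
    """Edges present in every input set (order-independent intersection)."""
    if len(edge_sets) < 2:
        raise DataError("conjunction needs at least 2 edge sets")
    sets = [canonical_edges(es) for es in edge_sets]
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def overlap_edges(
    edge_sets: Sequence[Iterable[tuple[int, int]]], min_count: int = 2
) -> frozenset[tuple[int, int]]:
    """Edges shared by at least ``min_count`` of the input sets.

    The pairwise reading of conjunction ("common connections between
    arbitrary two groups"): with ``min_count=2`` an edge qualifies as
    overlapping if any two contrasts both flagged it; with
    ``min_count=len(edge_sets)`` this reduces to :func:`conjunction`.
    """
    if len(edge_sets) < 2:
        raise DataError("overlap needs at least 2 edge sets")
    if min_count < 2:
        raise ConfigError("min_count must be at least 2")
    counts: dict[tuple[int, int], int] = {}
    for es in edge_sets:
        for e in canonical_edges(es):
            counts[e] = counts.get(e, 0) + 1
    return frozenset(e for e, c in counts.items() if c >= min_count)
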