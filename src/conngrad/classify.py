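"""Linear SVM classification of group contrasts from connectivity features.

Protocol: the data are split into stratified train/test sets ``n_splits``
times; within each training set, the soft-margin C of a linear SVM is chosen
by stratified cross-validation and features are standardized using
training-set statistics only; accuracy, sensitivity, specificity and AUC are
then measured on the held-out test set.  Metrics are aggregated as
mean +/- SD across splits.  The permutation test shuffles labels *before the
entire split/CV procedure* and compares the permuted mean accuracies with the
observed one: p = (1 + #{permuted >= observed}) / (1 + n_permutations).

Features are either one column per edge, or FC-index (FCI) composites: the
selected edges are grouped by the network block (within-network or
network-pair) they belong to and each block contributes the mean FC over its
edges — the representation used when a differential edge set is condensed
into a handful of interpretable features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .atlas import AtlasPartition, GROUPS
from .connectome import Connectome, canonical_edges
from .errors import ConfigError, DataError

__all__ = [
    "ClassificationReport",
    "build_features",
    "evaluate_classifier",
    "contrast_families",
    "run_all_contrasts",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def build_features(
    connectomes: Mapping[str, Connectome],
    edges: Iterable[tuple[int, int]],
    mode: str = "per-edge",
    partition: AtlasPartition | None = None,
) -> pd.DataFrame:
    """Feature table (subjects x features) from an edge set.

    ``per-edge``: one column per edge, named ``e<i>-<j>`` (1-based).
    ``fci``: edges are grouped by the network block each edge spans (needs
    ``partition``); each block yields one mean-FC column.
    Column order is deterministic; row order follows the mapping order.
    """
    es = sorted(canonical_edges(edges))
    if not es:
        raise DataError("empty edge set")
    sids = list(connectomes.keys())
    n = connectomes[sids[0]].n_nodes
    for i, j in es:
        if not (0 <= i < n and 0 <= j < n):
            raise DataError(f"edge ({i + 1},{j + 1}) outside matrix of {n} nodes")
    ii = np.array([e[0] for e in es])
    jj = np.array([e[1] for e in es])
    vals = np.stack([connectomes[s].values[ii, jj] for s in sids])
    if mode == "per-edge":
        cols = [f"e{i + 1}-{j + 1}" for i, j in es]
        return pd.DataFrame(vals, index=sids, columns=cols)
    if mode != "fci":
        raise ConfigError(f"unknown feature mode {mode!r}")
    if partition is None:
        raise ConfigError("fci mode requires a partition")
    net = partition.network_of_node
    blocks: dict[str, list[int]] = {}
    for k, (i, j) in enumerate(es):
        a, b = sorted((net[i], net[j]))
        blocks.setdefault(f"FCI:{a}-{b}" if a != b else f"FCI:{a}", []).append(k)
    cols = sorted(blocks)
    out = np.column_stack([vals[:, blocks[c]].mean(axis=1) for c in cols])
    return pd.DataFrame(out, index=sids, columns=cols)


@dataclass(frozen=True)
class ClassificationReport:
    contrast: tuple[str, str]
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    auc: float
    auc_sd: float
    permutation_p: float | None
    per_split: pd.DataFrame
    n_splits: int
    cv_folds: int
    n_permutations: int
    test_size: float
    seed: int


def _split_metrics(
    X: np.ndarray, y: np.ndarray, rng_seed: int, cv_folds: int,
    test_size: float, c_grid: Sequence[float],
) -> dict[str, float]:
    """One stratified train/test split: inner-CV C selection, test metrics."""
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=rng_seed,
    )
    folds = min(cv_folds, int(np.bincount(ytr).min()))
    if folds < 2:
        raise DataError("too few subjects per class for cross-validation")
    scaler = StandardScaler().fit(Xtr)
    Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)
    best_c, best_score = c_grid[0], -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    for c in c_grid:
        scores = []
        for tr, va in skf.split(Xtr_s, ytr):
            clf = SVC(kernel="linear", C=c).fit(Xtr_s[tr], ytr[tr])
            scores.append(clf.score(Xtr_s[va], ytr[va]))
        score = float(np.mean(scores))
        if score > best_score:
            best_c, best_score = c, score
    clf = SVC(kernel="linear", C=best_c).fit(Xtr_s, ytr)
    pred = clf.predict(Xte_s)
    dec = clf.decision_function(Xte_s)
    tp = int(np.sum((pred == 1) & (yte == 1)))
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    return {
        "accuracy": (tp + tn) / len(yte),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "auc": roc_auc_score(yte, dec),
        "C": best_c,
    }


def _mean_accuracy(
    X: np.ndarray, y: np.ndarray, seed: int, n_splits: int, cv_folds: int,
    test_size: float, c_grid: Sequence[float],
) -> tuple[float, list[dict[str, float]]]:
    rows = []
    for s in range(n_splits):
        split_seed = int(np.random.SeedSequence(seed, spawn_key=(s,))
                         .generate_state(1)[0] % (2 ** 31))
        rows.append(_split_metrics(X, y, split_seed, cv_folds,
                                   test_size, c_grid))
    return float(np.mean([r["accuracy"] for r in rows])), rows


def evaluate_classifier(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    n_splits: int = 10,
    cv_folds: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
    test_size: float = 0.2,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    contrast: tuple[str, str] | None = None,
) -> ClassificationReport:
    """Repeated-split linear-SVM evaluation with a label-permutation test.

    The positive class (sensitivity target) is ``contrast[0]`` when given,
    else the lexicographically larger label.  Set ``n_permutations=0`` to
    skip the permutation test.
    """
    X = np.asarray(features, dtype=float)
    lab = pd.Series(list(labels), dtype=str)
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes, got {classes}")
    if contrast is None:
        contrast = (classes[1], classes[0])
    pos = contrast[0]
    y = (lab == pos).to_numpy(dtype=int)
    if min(np.bincount(y)) < 4:
        raise DataError("need at least 4 subjects per class")

    obs_acc, rows = _mean_accuracy(X, y, seed, n_splits, cv_folds,
                                   test_size, c_grid)
    per_split = pd.DataFrame(rows)

    perm_p = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        hits = 0
        for b in range(n_permutations):
            yp = rng.permutation(y)
            acc, _ = _mean_accuracy(X, yp, seed + b + 1, n_splits, cv_folds,
                                    test_size, c_grid)
            hits += acc >= obs_acc
        perm_p = (1 + hits) / (1 + n_permutations)

    def agg(c: str) -> tuple[float, float]:
        v = per_split[c].to_numpy(dtype=float)
        return float(np.nanmean(v)), float(np.nanstd(v))

    acc, acc_sd = agg("accuracy")
    sens, sens_sd = agg("sensitivity")
    spec, spec_sd = agg("specificity")
    auc, auc_sd = agg("auc")
    return ClassificationReport(
        contrast=contrast, accuracy=acc, accuracy_sd=acc_sd,
        sensitivity=sens, sensitivity_sd=sens_sd,
        specificity=spec, specificity_sd=spec_sd, auc=auc, auc_sd=auc_sd,
        permutation_p=perm_p, per_split=per_split, n_splits=n_splits,
        cv_folds=cv_folds, n_permutations=n_permutations,
        test_size=test_size, seed=seed,
    )


def contrast_families() -> list[tuple[str, str]]:
    """The three binary contrast families along the severity gradient.

    (1) each MDD subgroup vs HC (5); (2) each suicidal-ideation subgroup or
    MDDSB vs MDDNSI (4); (3) all pairs among the four suicidal subgroups (6).
    15 contrasts total; the first element of each pair is the positive class.
    """
    mdd = list(GROUPS[1:])          # MDDNSI .. MDDSB
    suicidal = mdd[1:]              # MDDmSI .. MDDSB
    fams = [(g, "HC") for g in mdd]
    fams += [(g, "MDDNSI") for g in suicidal]
    fams += [(b, a) for a, b in itertools.combinations(suicidal, 2)]
    return fams


def run_all_contrasts(
    connectomes: Mapping[str, Connectome],
    groups: Mapping[str, str],
    edges: Iterable[tuple[int, int]],
    mode: str = "fci",
    partition: AtlasPartition | None = None,
    **eval_kwargs,
) -> tuple[dict[tuple[str, str], ClassificationReport], list[dict]]:
    """Evaluate every contrast family; skip (with a logged reason) contrasts
    whose groups are absent or too small."""
    features = build_features(connectomes, edges, mode=mode, partition=partition)
    glab = pd.Series({s: groups[s] for s in features.index})
    reports: dict[tuple[str, str], ClassificationReport] = {}
    skipped: list[dict] = []
    for a, b in contrast_families():
        sel = glab.isin([a, b])
        counts = glab[sel].value_counts()
        if counts.get(a, 0) < 4 or counts.get(b, 0) < 4:
            skipped.append({"contrast": (a, b),
                            "reason": f"insufficient subjects ({dict(counts)})"})
            continue
        reports[(a, b)] = evaluate_classifier(
            features[sel.to_numpy()], glab[sel], contrast=(a, b), **eval_kwargs,
        )
    return reports, skipped
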