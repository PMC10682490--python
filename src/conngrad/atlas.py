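"""Atlas partitions, subject tables, matrix and edge-list I/O, and cohort QC.

File conventions
----------------
* Node indexing is **1-based in every on-disk format** (the ROI convention in
  neuroimaging edge lists) and **0-based in memory**.
* Partition files are two-column delimited text ``node_id<TAB>network``; a
  header line is detected and skipped.
* Time series and connectomes are whitespace- or tab-delimited numeric
  matrices, one file per subject.
* Edge lists are three-column TSV ``node_i  node_j  value`` with ``i < j``.

The shipped default partition (``power226_synthetic.tsv``) is a synthetic
stand-in with the documented structure of the 226-node / 10-network
resting-state parcellation used throughout the package: 226 nodes assigned to
the ten canonical networks (AUD, CON, DAN, DMN, FPN, SAN, SMN, SUB, VAN, VIS)
with realistic block sizes.  It is structurally faithful, not a claim about
the true atlas coordinates or labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AtlasPartition",
    "GROUPS",
    "MDD_GROUPS",
    "GROUP_OF_SCORE",
    "read_partition",
    "write_partition",
    "default_partition",
    "assign_suicidality_group",
    "read_subject_table",
    "write_subject_table",
    "qc_filter",
    "read_matrix",
    "write_matrix",
    "read_time_series",
    "read_connectome_matrix",
    "read_edge_list",
    "write_edge_list",
    "edges_to_matrix",
]

#: Cohort groups in severity order: healthy controls, then patients ordered by
#: the HAMD suicide-item score 0..4.
GROUPS: tuple[str, ...] = ("HC", "MDDNSI", "MDDmSI", "MDDmoSI", "MDDSSI", "MDDSB")
MDD_GROUPS: tuple[str, ...] = GROUPS[1:]
GROUP_OF_SCORE = {0: "MDDNSI", 1: "MDDmSI", 2: "MDDmoSI", 3: "MDDSSI", 4: "MDDSB"}

#: Canonical network names of the ten resting-state networks.
NETWORK_NAMES_10 = ("AUD", "CON", "DAN", "DMN", "FPN", "SAN", "SMN", "SUB", "VAN", "VIS")


@dataclass(frozen=True)
class AtlasPartition:
    """Assignment of atlas nodes to named resting-state networks.

    Attributes
    ----------
    node_ids:
        1-based node labels in file order.
    network_of_node:
        Network name for each node, aligned with ``node_ids``.
    network_names:
        Networks in first-appearance order.
    """

    node_ids: tuple[int, ...]
    network_of_node: tuple[str, ...]
    network_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.network_of_node):
            raise DataError("node_ids and network_of_node lengths differ")
        if len(set(self.node_ids)) != len(self.node_ids):
            dups = pd.Series(self.node_ids)
            dup = dups[dups.duplicated()].iloc[0]
            raise DataError(f"duplicate node id {dup} in partition")
        names = self.network_names or tuple(dict.fromkeys(self.network_of_node))
        object.__setattr__(self, "network_names", names)
        if any(not n for n in self.network_of_node):
            raise DataError("empty network name in partition")
        if len(names) < 2:
            raise DataError("partition must contain at least 2 networks")
        unknown = set(self.network_of_node) - set(names)
        if unknown:
            raise DataError(f"nodes assigned to unknown networks: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def indices(self, network: str) -> np.ndarray:
        """0-based positions of all nodes in ``network``."""
        if network not in self.network_names:
            raise DataError(f"unknown network {network!r}")
        mask = np.asarray([n == network for n in self.network_of_node])
        return np.flatnonzero(mask)

    def labels(self) -> np.ndarray:
        """Integer network label per node (index into ``network_names``)."""
        lut = {n: i for i, n in enumerate(self.network_names)}
        return np.asarray([lut[n] for n in self.network_of_node], dtype=int)


def read_partition(path: str | Path) -> AtlasPartition:
    """Read a two-column (node_id, network) partition file.

    A first line whose id field is non-numeric is treated as a header.
    """
    rows: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            if lineno == 1 and not parts[0].lstrip("-").isdigit():
                continue  # header
            try:
                nid = int(parts[0])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad node id {parts[0]!r}") from exc
            rows.append((nid, parts[1]))
    if not rows:
        raise DataError(f"{path}: empty partition file")
    return AtlasPartition(
        node_ids=tuple(r[0] for r in rows),
        network_of_node=tuple(r[1] for r in rows),
    )


def write_partition(partition: AtlasPartition, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tnetwork\n")
        for nid, net in zip(partition.node_ids, partition.network_of_node):
            fh.write(f"{nid}\t{net}\n")


def default_partition() -> AtlasPartition:
    """The packaged synthetic 226-node / 10-network partition."""
    ref = resources.files("conngrad.data") / "power226_synthetic.tsv"
    with resources.as_file(ref) as p:
        return read_partition(p)


def assign_suicidality_group(hamd_suicide: int | None, is_patient: bool) -> str:
    """Map a HAMD suicide-item score to a severity-gradient group label.

    Patients: 0 -> MDDNSI (no suicidal ideation), 1 -> MDDmSI (mild),
    2 -> MDDmoSI (moderate), 3 -> MDDSSI (severe), 4 -> MDDSB (suicidal
    behavior).  Non-patients map to HC regardless of score.
    """
    if not is_patient:
        return "HC"
    if hamd_suicide is None or hamd_suicide != int(hamd_suicide):
        raise DataError(f"suicide item score must be an integer 0-4, got {hamd_suicide!r}")
    score = int(hamd_suicide)
    if score not in GROUP_OF_SCORE:
        raise DataError(f"suicide item score out of range 0-4: {score}")
    return GROUP_OF_SCORE[score]


SUBJECT_COLUMNS = [
    "subject_id", "site", "group", "age", "sex", "education", "mean_fd",
    "hamd_total", "hamd_suicide", "hamd_anxiety", "hamd_weight",
    "hamd_retardation", "hamd_sleep",
]


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject phenotype CSV.

    Only structurally critical fields are validated here; each analysis stage
    checks its own requirements (multi-site tables are ragged in practice).
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except FileNotFoundError as exc:
        raise DataError(f"subject table not found: {path}") from exc
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataError(f"{path}: duplicate subject_id {dup!r}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise DataError(f"{path}: unknown group labels {sorted(bad)}")
    if "hamd_suicide" in df.columns:
        patients = df["group"] != "HC"
        scores = df.loc[patients, "hamd_suicide"].dropna()
        if not scores.isin([0, 1, 2, 3, 4]).all():
            raise DataError(f"{path}: patient suicide-item scores outside 0-4")
        expect = scores.map(GROUP_OF_SCORE)
        actual = df.loc[scores.index, "group"]
        if (expect != actual).any():
            sid = df.loc[scores.index[expect != actual], "subject_id"].iloc[0]
            raise DataError(f"{path}: group inconsistent with suicide item for {sid!r}")
    return df


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def qc_filter(
    subjects: pd.DataFrame, fd_threshold: float = 0.2
) -> tuple[pd.DataFrame, list[dict]]:
    """Retain subjects with mean framewise displacement <= ``fd_threshold``.

    Mirrors the standard motion exclusion rule (mean FD > 0.2 mm excluded).
    Returns the retained table and an exclusion log with one record per
    excluded subject.
    """
    if "mean_fd" not in subjects.columns:
        raise DataError("subject table lacks a mean_fd column")
    fd = subjects["mean_fd"]
    if fd.isna().any():
        sid = subjects.loc[fd.isna(), "subject_id"].iloc[0]
        raise DataError(f"missing mean_fd for subject {sid!r}")
    keep = fd <= fd_threshold
    log = [
        {
            "subject_id": row.subject_id,
            "reason": f"mean_fd {row.mean_fd:g} mm > threshold {fd_threshold:g} mm",
        }
        for row in subjects.loc[~keep].itertuples()
    ]
    return subjects.loc[keep].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# numeric matrix and edge-list I/O


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace/tab-delimited numeric matrix."""
    try:
        values = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise DataError(f"{path}: could not parse numeric matrix ({exc})") from exc
    if np.isnan(values).any():
        raise DataError(f"{path}: matrix contains missing values")
    return values


def write_matrix(values: np.ndarray, path: str | Path, fmt: str = "%.10g") -> None:
    np.savetxt(path, np.asarray(values), fmt=fmt, delimiter="\t")


def read_time_series(path: str | Path, partition: AtlasPartition | None = None) -> np.ndarray:
    """Read a T x N time-series matrix, checking it against a partition."""
    ts = read_matrix(path)
    if ts.shape[0] < 3:
        raise DataError(f"{path}: need at least 3 timepoints, got {ts.shape[0]}")
    if partition is not None and ts.shape[1] != partition.n_nodes:
        raise DataError(
            f"{path}: {ts.shape[1]} columns but partition has {partition.n_nodes} nodes"
        )
    return ts


def read_connectome_matrix(path: str | Path, tol: float = 1e-8) -> np.ndarray:
    """Read a square connectivity matrix, symmetrizing tiny asymmetries.

    Asymmetry above ``tol`` (max absolute difference) is an error rather than
    silently averaged away.
    """
    m = read_matrix(path)
    if m.shape[0] != m.shape[1]:
        raise DataError(f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    asym = np.nanmax(np.abs(m - m.T)) if m.size else 0.0
    if asym > tol:
        raise DataError(f"{path}: asymmetry {asym:g} exceeds tolerance {tol:g}")
    return (m + m.T) / 2.0


def read_edge_list(path: str | Path) -> list[tuple[int, int, float]]:
    """Read a 1-based TSV edge list into 0-based (i, j, value) triples, i<j."""
    out: list[tuple[int, int, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and not parts[0].lstrip("-").isdigit():
                continue
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 3 columns")
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if i == j:
                raise DataError(f"{path}:{lineno}: self-loop on node {i}")
            if i > j:
                i, j = j, i
            out.append((i - 1, j - 1, v))
    return out


def write_edge_list(
    edges: Iterable[tuple[int, int, float]], path: str | Path
) -> None:
    """Write 0-based (i, j, value) triples as a 1-based TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_i\tnode_j\tvalue\n")
        for i, j, v in edges:
            if i == j:
                raise DataError(f"self-loop on node {i + 1}")
            a, b = (i, j) if i < j else (j, i)
            fh.write(f"{a + 1}\t{b + 1}\t{v:.10g}\n")


def edges_to_matrix(
    edges: Sequence[tuple[int, int, float]], n_nodes: int
) -> np.ndarray:
    """Densify a 0-based edge list into a symmetric matrix (zeros elsewhere)."""
    m = np.zeros((n_nodes, n_nodes))
    for i, j, v in edges:
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise DataError(f"edge ({i + 1},{j + 1}) outside 1..{n_nodes}")
        m[i, j] = m[j, i] = v
    return m
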