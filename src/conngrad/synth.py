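"""Synthetic multi-subject cohort with a planted suicidality-gradient signal.

The generator emulates the statistical structure the downstream analyses
assume, so every pipeline stage can be exercised and validated without any
real imaging data:

* six groups — HC plus five patient groups ordered by the HAMD suicide item
  (MDDNSI, MDDmSI, MDDmoSI, MDDSSI, MDDSB);
* per-subject regional time series from a hierarchical factor model: node
  ``i`` in network ``k`` is ``x_i = sqrt(lam_k) f_k + sqrt(1-lam_k) e_i``
  where the network factor ``f_k = phi_k g + sqrt(1-phi_k^2) h_k`` couples
  to a global factor ``g``.  The implied correlation matrix is exactly
  block-constant over the partition — within-network correlation ``lam_k``
  (cohesion) and between-network correlation
  ``sqrt(lam_a lam_b) phi_a phi_b`` (through the global coupling) — and is
  positive definite by construction for any ``lam`` in [0, 1) and ``phi``
  in [-1, 1];
* planted non-monotone gradient effects on three affected networks:
  cohesion rises then falls along the severity gradient (inverted U) while
  the global coupling falls then recovers (U shape), so within-network
  connectivity and the one-versus-others summary move in opposite
  directions.  Each affected network has its own curve — different
  amplitudes and trough positions — which makes the affected trio reorder
  around the median role cut across groups while the seven unaffected
  networks keep their rank;
* small additive site effects and heterogeneous baselines, so network roles
  and covariate adjustment are non-degenerate;
* clinical scores generated from each subject's *realized* connectivity:
  HAMD subfactors are linear in the subject's FC index over the planted
  edge set plus noise, with configurable signs (anxiety negative, weight
  positive by default).

Everything is reproducible from one seed: each subject draws from a
substream keyed by (seed, group index, subject index), so subject k of
group g is identical regardless of the other groups' sizes.

The ground-truth record lists every planted parameter and the exact
group-level WNC/OVO trajectories implied by the target correlation
matrices — sufficient to re-derive every planted effect, the closure
property the recovery tests rely on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasPartition, GROUPS, GROUP_OF_SCORE, default_partition
from .connectome import Connectome, compute_fc, fci
from .errors import ConfigError

__all__ = ["SyntheticConfig", "Cohort", "generate_cohort", "generate_clinical",
           "simulate_study", "target_correlation", "planted_summary_curves",
           "sign_pattern"]

#: Baseline within-network correlation (network cohesion, lam).  Three
#: strongly cohesive networks, four weakly cohesive, and the affected trio
#: (AUD, SAN, SUB) straddling the median so the planted gradient can reorder
#: them across the role cut.
DEFAULT_COHESION = {
    "CON": 0.45, "VIS": 0.42, "SMN": 0.40,
    "AUD": 0.24, "SUB": 0.23, "SAN": 0.22,
    "DAN": 0.14, "VAN": 0.13, "FPN": 0.12, "DMN": 0.11,
}

#: Baseline coupling of each network factor to the global factor (phi).
#: Solved so the baseline one-versus-others profile has three strongly
#: coupled networks (CON, SMN, VIS), four weakly coupled, and the affected
#: trio in between.
DEFAULT_COUPLING = {
    "CON": 0.738, "SMN": 0.832, "VIS": 0.742,
    "AUD": 0.674, "SAN": 0.748, "SUB": 0.747,
    "DAN": 0.378, "VAN": 0.355, "FPN": 0.314, "DMN": 0.250,
}

_GRADIENT = ("HC", "MDDNSI", "MDDmSI", "MDDmoSI", "MDDSSI", "MDDSB")


def _curve(values: Sequence[float]) -> dict[str, float]:
    return dict(zip(_GRADIENT, values))


#: Planted cohesion (within-network r) shifts per affected network: inverted
#: U along the gradient, with network-specific amplitude and a dip below
#: baseline for suicidal behavior.
DEFAULT_WNC_CURVES = {
    "AUD": _curve([0.0, 0.02, 0.05, 0.07, 0.035, -0.02]),
    "SUB": _curve([0.0, 0.04, 0.08, 0.10, 0.05, -0.03]),
    "SAN": _curve([0.0, 0.05, 0.10, 0.14, 0.07, -0.05]),
}

#: Planted global-coupling shifts per affected network: a U shape whose
#: trough sits at moderate ideation for AUD/SAN but at severe ideation for
#: SUB.  Values are on the phi scale and were solved so the implied
#: one-versus-others trajectories fall then recover by 0.012-0.056
#: correlation units per network.
DEFAULT_COUPLING_CURVES = {
    "AUD": _curve([0.0, -0.099, -0.198, -0.283, -0.126, 0.121]),
    "SAN": _curve([0.0, -0.184, -0.310, -0.414, -0.199, 0.231]),
    "SUB": _curve([0.0, -0.150, -0.270, -0.365, -0.432, -0.133]),
}

DEFAULT_N_PER_GROUP = {"HC": 50, "MDDNSI": 30, "MDDmSI": 30,
                       "MDDmoSI": 25, "MDDSSI": 20, "MDDSB": 15}

#: Group-level clinical baselines (rough magnitudes for a multi-site MDD
#: cohort; HC values nominal).
CLINICAL_BASE = {
    "hamd_total": {"HC": 2, "MDDNSI": 16, "MDDmSI": 22, "MDDmoSI": 24,
                   "MDDSSI": 26, "MDDSB": 27},
    "hamd_anxiety": {"HC": 2.0, "MDDNSI": 4.8, "MDDmSI": 5.9, "MDDmoSI": 5.7,
                     "MDDSSI": 6.1, "MDDSB": 6.0},
    "hamd_weight": {"HC": 0.2, "MDDNSI": 0.4, "MDDmSI": 0.6, "MDDmoSI": 0.7,
                    "MDDSSI": 0.7, "MDDSB": 1.2},
    "hamd_retardation": {"HC": 1.0, "MDDNSI": 5.5, "MDDmSI": 7.1,
                         "MDDmoSI": 7.6, "MDDSSI": 8.0, "MDDSB": 8.2},
    "hamd_sleep": {"HC": 1.0, "MDDNSI": 3.2, "MDDmSI": 3.9, "MDDmoSI": 4.1,
                   "MDDSSI": 4.2, "MDDSB": 3.9},
}

#: Coefficients linking the planted FC index (z-scored) to subfactor scores.
DEFAULT_CLINICAL_MODEL = {"hamd_anxiety": -1.5, "hamd_weight": 0.6,
                          "hamd_retardation": 0.0, "hamd_sleep": 0.0}
CLINICAL_NOISE_SD = {"hamd_anxiety": 1.2, "hamd_weight": 0.4,
                     "hamd_retardation": 1.8, "hamd_sleep": 1.5}
CLINICAL_CLIP = {"hamd_anxiety": (0, 14), "hamd_weight": (0, 4),
                 "hamd_retardation": (0, 12), "hamd_sleep": (0, 6)}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    The defaults are a scaled-down study: 170 subjects over six groups,
    226 nodes, 200 timepoints, four sites, and the gradient curves above on
    the three affected networks.
    """

    seed: int = 0
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    partition: AtlasPartition | None = None
    T: int = 200
    cohesion: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COHESION))
    coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING))
    wnc_curves: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_WNC_CURVES.items()})
    coupling_curves: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_COUPLING_CURVES.items()})
    site_labels: tuple[str, ...] = ("site1", "site2", "site3", "site4")
    site_shift: Mapping[str, float] = field(
        default_factory=lambda: {"site1": 0.010, "site2": -0.010,
                                 "site3": 0.005, "site4": -0.005})
    clinical_model: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_MODEL))
    female_fraction: float = 0.6
    keep_time_series: bool = False

    @property
    def affected_networks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.wnc_curves) | set(self.coupling_curves)))

    def resolved_partition(self) -> AtlasPartition:
        return self.partition if self.partition is not None else default_partition()

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if n < 2:
                raise ConfigError(f"group {g!r} needs n >= 2, got {n}")
        if self.T < 3:
            raise ConfigError("T must be at least 3")
        if not self.site_labels:
            raise ConfigError("need at least one site")
        part = self.resolved_partition()
        unknown = (set(self.wnc_curves) | set(self.coupling_curves)) - set(
            part.network_names)
        if unknown:
            raise ConfigError(f"curves reference unknown networks {sorted(unknown)}")

    def block_params(self, group: str, site: str) -> tuple[dict, dict]:
        """Per-network (cohesion, coupling) for one (group, site) cell."""
        s = self.site_shift.get(site, 0.0)
        lam, phi = {}, {}
        for k in self.resolved_partition().network_names:
            lam[k] = self.cohesion.get(k, 0.25) + \
                self.wnc_curves.get(k, {}).get(group, 0.0) + s
            phi[k] = self.coupling.get(k, 0.5) + \
                self.coupling_curves.get(k, {}).get(group, 0.0) + s
            if not (0.005 <= lam[k] <= 0.97):
                raise ConfigError(
                    f"cohesion for {k!r} in group {group!r} is {lam[k]:.3f}; "
                    "must stay in [0.005, 0.97] — reduce the planted shifts"
                )
            if abs(phi[k]) > 0.99:
                raise ConfigError(
                    f"coupling for {k!r} in group {group!r} is {phi[k]:.3f}; "
                    "must stay in [-0.99, 0.99] — reduce the coupling curves"
                )
        return lam, phi


def target_correlation(
    config: SyntheticConfig, group: str, site: str,
    partition: AtlasPartition | None = None,
) -> np.ndarray:
    """Block-constant target correlation matrix for one (group, site) cell.

    Within-network blocks carry the cohesion value; between-network blocks
    carry ``sqrt(lam_a lam_b) phi_a phi_b``.  Positive definiteness is
    structural (the matrix is the covariance of an explicit factor model),
    so no spectral repair is ever applied.
    """
    part = partition if partition is not None else config.resolved_partition()
    lam, phi = config.block_params(group, site)
    n = part.n_nodes
    C = np.zeros((n, n))
    for net in part.network_names:
        idx = part.indices(net)
        C[np.ix_(idx, idx)] = lam[net]
    for a, b in itertools.combinations(part.network_names, 2):
        r = np.sqrt(lam[a] * lam[b]) * phi[a] * phi[b]
        ia, ib = part.indices(a), part.indices(b)
        C[np.ix_(ia, ib)] = r
        C[np.ix_(ib, ia)] = r
    np.fill_diagonal(C, 1.0)
    return C


def planted_summary_curves(
    config: SyntheticConfig,
) -> dict[str, dict[str, list[float]]]:
    """Exact planted group-level WNC and OVO trajectories per network.

    Computed by summarizing the site-averaged target correlation matrix for
    each group — the curves the estimated group means converge to as the
    cohort grows.
    """
    from .connectome import summarize_networks

    part = config.resolved_partition()
    wnc: dict[str, list[float]] = {n: [] for n in part.network_names}
    ovo: dict[str, list[float]] = {n: [] for n in part.network_names}
    for g in GROUPS:
        C = np.mean([target_correlation(config, g, s, part)
                     for s in config.site_labels], axis=0)
        summ = summarize_networks(Connectome(C), part)
        for n in part.network_names:
            wnc[n].append(summ.wnc[n])
            ovo[n].append(summ.ovo[n])
    return {"wnc": wnc, "ovo": ovo}


@dataclass
class Cohort:
    """A simulated study: phenotypes, per-subject data, and ground truth."""

    subjects: pd.DataFrame
    connectomes: dict[str, Connectome]
    time_series: dict[str, np.ndarray]
    ground_truth: dict


def _subject_rng(seed: int, gi: int, si: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gi, si)))


def _sample_time_series(
    rng: np.random.Generator, T: int, partition: AtlasPartition,
    lam: Mapping[str, float], phi: Mapping[str, float],
) -> np.ndarray:
    """Draw one subject's T x N series directly from the factor model."""
    nets = partition.network_names
    g = rng.standard_normal((T, 1))
    h = rng.standard_normal((T, len(nets)))
    e = rng.standard_normal((T, partition.n_nodes))
    ts = np.empty((T, partition.n_nodes))
    for k, net in enumerate(nets):
        f = phi[net] * g[:, 0] + np.sqrt(1 - phi[net] ** 2) * h[:, k]
        idx = partition.indices(net)
        ts[:, idx] = (np.sqrt(lam[net]) * f)[:, None] \
            + np.sqrt(1 - lam[net]) * e[:, idx]
    return ts


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict]:
    """Draw the cohort's time series and demographic phenotypes.

    Returns (subjects, time_series, ground_truth).  Clinical scores are
    added separately by :func:`generate_clinical` because they depend on
    each subject's realized connectivity.
    """
    config.validate()
    part = config.resolved_partition()

    params_cache: dict[tuple[str, str], tuple[dict, dict]] = {}
    rows = []
    series: dict[str, np.ndarray] = {}
    for gi, group in enumerate(GROUPS):
        n = int(config.n_per_group.get(group, 0))
        for si in range(n):
            rng = _subject_rng(config.seed, gi, si)
            site = config.site_labels[si % len(config.site_labels)]
            if (group, site) not in params_cache:
                params_cache[(group, site)] = config.block_params(group, site)
            lam, phi = params_cache[(group, site)]
            sid = f"{group}_{si:03d}"
            series[sid] = _sample_time_series(rng, config.T, part, lam, phi)
            score = {v: k for k, v in GROUP_OF_SCORE.items()}.get(group)
            rows.append({
                "subject_id": sid,
                "site": site,
                "group": group,
                "age": int(rng.integers(18, 66)),
                "sex": "female" if rng.random() < config.female_fraction else "male",
                "education": float(np.clip(round(rng.normal(12.5, 3.4), 1), 5, 22)),
                "mean_fd": float(min(0.04 + rng.exponential(0.035), 0.5)),
                "hamd_suicide": 0 if group == "HC" else score,
            })
    subjects = pd.DataFrame(rows)

    gt_edges = []
    for net in config.affected_networks:
        idx = part.indices(net)
        gt_edges.extend(
            (int(a), int(b)) for a, b in itertools.combinations(idx, 2))
    planted = planted_summary_curves(config)
    ground_truth = {
        "seed": config.seed,
        "group_order": list(GROUPS),
        "affected_networks": list(config.affected_networks),
        "cohesion": dict(config.cohesion),
        "coupling": dict(config.coupling),
        "wnc_curves": {k: dict(v) for k, v in config.wnc_curves.items()},
        "coupling_curves": {k: dict(v)
                            for k, v in config.coupling_curves.items()},
        "planted_wnc": {n: planted["wnc"][n] for n in config.affected_networks},
        "planted_ovo": {n: planted["ovo"][n] for n in config.affected_networks},
        "site_shift": dict(config.site_shift),
        "clinical_model": dict(config.clinical_model),
        "planted_edges": gt_edges,
    }
    return subjects, series, ground_truth


def generate_clinical(
    subjects: pd.DataFrame,
    planted_fci: np.ndarray,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Attach clinical scores driven by the planted FC index.

    Each HAMD subfactor is its group baseline plus coefficient x z-scored
    planted FCI plus noise, integer-clipped to plausible ranges.  HAMD total
    rises with the suicide-item score through the group baselines.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(999_983,)))
    out = subjects.copy()
    z = np.asarray(planted_fci, dtype=float)
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    for var, coef in config.clinical_model.items():
        base = out["group"].map(CLINICAL_BASE[var]).to_numpy(dtype=float)
        lo, hi = CLINICAL_CLIP[var]
        raw = base + coef * z + rng.normal(0, CLINICAL_NOISE_SD[var], len(out))
        out[var] = np.clip(np.rint(raw), lo, hi).astype(int)
    total = out["group"].map(CLINICAL_BASE["hamd_total"]).to_numpy(dtype=float)
    total = total + rng.normal(0, 3.0, len(out))
    is_hc = (out["group"] == "HC").to_numpy()
    total = np.where(is_hc, np.clip(total, 0, 7), np.clip(total, 8, 52))
    out["hamd_total"] = np.rint(total).astype(int)
    return out


def simulate_study(config: SyntheticConfig) -> Cohort:
    """Full simulation: time series -> connectomes -> clinical scores."""
    subjects, series, gt = generate_cohort(config)
    connectomes = {sid: compute_fc(ts) for sid, ts in series.items()}
    planted = np.array([fci(connectomes[s], gt["planted_edges"])
                        for s in subjects["subject_id"]])
    subjects = generate_clinical(subjects, planted, config)
    gt["planted_fci"] = {s: float(v)
                         for s, v in zip(subjects["subject_id"], planted)}
    return Cohort(
        subjects=subjects,
        connectomes=connectomes,
        time_series=series if config.keep_time_series else {},
        ground_truth=gt,
    )


def sign_pattern(curve: Sequence[float]) -> list[int]:
    """Signs of successive differences of a trajectory (+1, -1, or 0)."""
    c = np.asarray(curve, dtype=float)
    return [int(np.sign(d)) for d in np.diff(c)]
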