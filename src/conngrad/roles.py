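"""Network-role taxonomy from within- and one-versus-others connectivity.

Each network is labelled, per group, with one of four roles determined by its
group-mean WNC (cohesion: how tightly its own nodes synchronize) and OVO
(connectedness: how strongly it couples to the rest of the brain):

===================  =============  =============
role                 WNC vs cut     OVO vs cut
===================  =============  =============
cohesive connector   >= wnc_cut     >= ovo_cut
cohesive province    >= wnc_cut     <  ovo_cut
incohesive connector <  wnc_cut     >= ovo_cut
incohesive province  <  wnc_cut     <  ovo_cut
===================  =============  =============

The default policy sets each cut to the median of the ten group-mean values
within the group — the least-parameterized reading of "based on the
distribution"; a fixed-cut policy is available.  Ties (value exactly at the
cut) resolve upward (cohesive / connector).  The thresholds used are always
recorded in the output so the assignment is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = ["ROLES", "RoleAssignment", "assign_roles", "role_trajectory"]

ROLES = (
    "cohesive connector",
    "cohesive province",
    "incohesive connector",
    "incohesive province",
)


@dataclass(frozen=True)
class RoleAssignment:
    """Role per network plus the thresholds that produced it."""

    roles: Mapping[str, str]
    wnc_cut: float
    ovo_cut: float


def _role(wnc: float, ovo: float, wnc_cut: float, ovo_cut: float) -> str:
    cohesive = "cohesive" if wnc >= wnc_cut else "incohesive"
    connector = "connector" if ovo >= ovo_cut else "province"
    return f"{cohesive} {connector}"


def assign_roles(
    wnc: Mapping[str, float],
    ovo: Mapping[str, float],
    policy: str = "median",
    wnc_cut: float | None = None,
    ovo_cut: float | None = None,
) -> RoleAssignment:
    """Assign the four-way role to each network from group-mean WNC and OVO.

    policy="median" (default) cuts at the within-group median of the
    respective ten values; policy="fixed" uses the cuts given explicitly.
    """
    if set(wnc) != set(ovo):
        raise DataError("WNC and OVO cover different network sets")
    if policy == "median":
        wcut = float(np.median(list(wnc.values())))
        ocut = float(np.median(list(ovo.values())))
    elif policy == "fixed":
        if wnc_cut is None or ovo_cut is None:
            raise ConfigError("fixed policy requires wnc_cut and ovo_cut")
        wcut, ocut = float(wnc_cut), float(ovo_cut)
    else:
        raise ConfigError(f"unknown role policy {policy!r}")
    roles = {n: _role(wnc[n], ovo[n], wcut, ocut) for n in wnc}
    return RoleAssignment(roles=roles, wnc_cut=wcut, ovo_cut=ocut)


def role_trajectory(
    assignments: Mapping[str, RoleAssignment],
    group_order: Sequence[str],
) -> pd.DataFrame:
    """Tabulate role sequences across the severity gradient.

    Returns a DataFrame indexed by network with one column per group plus a
    ``stable`` flag (True when the role never changes along ``group_order``).
    """
    missing = [g for g in group_order if g not in assignments]
    if missing:
        raise DataError(f"no role assignment for groups {missing}")
    nets = set(assignments[group_order[0]].roles)
    for g in group_order:
        if set(assignments[g].roles) != nets:
            raise DataError(f"group {g!r} covers a different network set")
    rows = {}
    for n in sorted(nets):
        seq = [assignments[g].roles[n] for g in group_order]
        rows[n] = dict(zip(group_order, seq), stable=len(set(seq)) == 1)
    return pd.DataFrame.from_dict(rows, orient="index")
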