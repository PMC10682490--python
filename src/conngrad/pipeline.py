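"""End-to-end orchestration of the analysis stages, plus run manifests.

The demo pipeline mirrors the study's analysis order on a synthetic cohort:
simulate -> QC -> connectomes -> network summaries -> roles -> covariate-
adjusted metric tests with FDR -> behavior correlations -> NBS per contrast
-> conjunction -> FCI features -> SVM classification -> sex/age
heterogeneity screens.  Every stage writes plain-text outputs into one
directory and the manifest records the config, seeds, and a digest of every
file so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas import GROUPS, MDD_GROUPS, qc_filter, write_edge_list
from .classify import run_all_contrasts
from .connectome import metric_names, summarize_cohort
from .errors import DataError
from .inference import (age_stratum, heterogeneity_screen, metric_test_table,
                        partial_pearson)
from .nbs import edge_stats, nbs_test, overlap_edges
from .roles import assign_roles, role_trajectory
from .synth import SyntheticConfig, simulate_study

__all__ = ["run_demo", "stage_seed", "write_manifest"]

CLINICAL_VARS = ("hamd_anxiety", "hamd_weight", "hamd_retardation", "hamd_sleep")
COVARIATE_COLS = ["age", "sex", "education", "site"]


def stage_seed(seed: int, stage: int) -> int:
    """Per-stage integer substream of one global seed (< 2**31)."""
    return int(np.random.SeedSequence(seed, spawn_key=(stage,))
               .generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config: dict, seed: int) -> Path:
    files = sorted(p for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "conngrad",
        "version": __version__,
        "seed": seed,
        "config": config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {p.name: _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _tidy_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    long = summaries.reset_index(names="subject_id").melt(
        id_vars="subject_id", var_name="metric", value_name="value")
    parts = long["metric"].str.split(":", expand=True)
    long["metric_type"] = parts[0]
    long["name"] = parts[1]
    return long[["subject_id", "metric_type", "name", "value"]]


def _group_mean_summary(
    summaries: pd.DataFrame, groups: pd.Series, group: str, networks
) -> tuple[dict, dict]:
    sub = summaries.loc[(groups == group).to_numpy()]
    wnc = {n: float(sub[f"WNC:{n}"].mean()) for n in networks}
    ovo = {n: float(sub[f"OVO:{n}"].mean()) for n in networks}
    return wnc, ovo


def run_demo(
    seed: int,
    outdir: str | Path,
    config: SyntheticConfig | None = None,
    alpha: float = 0.05,
    nbs_permutations: int = 200,
    clf_splits: int = 10,
    clf_cv_folds: int = 5,
    clf_permutations: int = 50,
    clf_c_grid: Sequence[float] = (0.1, 1.0, 10.0),
) -> dict:
    """Run the full pipeline on a synthetic cohort; return a summary dict.

    The classification and NBS permutation counts default to scaled-down
    values suitable for a desk-scale run; all counts are recorded in the
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = SyntheticConfig(seed=seed)
    partition = config.resolved_partition()
    networks = partition.network_names

    # --- simulate and QC ---------------------------------------------------
    cohort = simulate_study(config)
    cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
    retained, exclusions = qc_filter(cohort.subjects)
    pd.DataFrame(exclusions, columns=["subject_id", "reason"]).to_csv(
        outdir / "qc_exclusions.csv", index=False)
    sids = retained["subject_id"].tolist()
    conns = {s: cohort.connectomes[s] for s in sids}
    groups = retained.set_index("subject_id")["group"]
    covariates = retained.set_index("subject_id")[COVARIATE_COLS]

    # --- network summaries -------------------------------------------------
    summaries = summarize_cohort(conns, partition)
    _tidy_summaries(summaries).to_csv(outdir / "summaries.csv", index=False)

    # --- network roles and trajectory --------------------------------------
    assignments = {}
    role_rows = []
    for g in GROUPS:
        wnc, ovo = _group_mean_summary(summaries, groups, g, networks)
        assignments[g] = assign_roles(wnc, ovo)
        for n in networks:
            role_rows.append({"group": g, "network": n, "wnc": wnc[n],
                              "ovo": ovo[n], "role": assignments[g].roles[n]})
    pd.DataFrame(role_rows).to_csv(outdir / "roles.csv", index=False)
    (outdir / "role_thresholds.json").write_text(json.dumps(
        {g: {"wnc_cut": a.wnc_cut, "ovo_cut": a.ovo_cut}
         for g, a in assignments.items()}, indent=2))
    trajectory = role_trajectory(assignments, GROUPS)
    trajectory.to_csv(outdir / "role_trajectory.csv")

    # --- covariate-adjusted metric tests with FDR ---------------------------
    contrasts = [("omnibus", list(GROUPS))] + [
        (f"HCvs{g}", ["HC", g]) for g in MDD_GROUPS]
    tables = []
    for name, gs in contrasts:
        sel = groups.isin(gs).to_numpy()
        tab = metric_test_table(summaries.loc[sel], groups[sel],
                                covariates.loc[sel])
        tab.insert(0, "contrast", name)
        tables.append(tab)
    metric_tests = pd.concat(tables, ignore_index=True)
    metric_tests.to_csv(outdir / "metric_tests.csv", index=False)

    # --- behavior correlations (pooled MDD) ---------------------------------
    mdd = groups.isin(MDD_GROUPS).to_numpy()
    corr_rows = []
    for metric in metric_names(partition):
        for var in CLINICAL_VARS:
            r, p = partial_pearson(
                summaries.loc[mdd, metric].to_numpy(),
                retained.loc[mdd, var].to_numpy(dtype=float),
                covariates.loc[mdd],
            )
            corr_rows.append({"metric": metric, "clinical": var, "r": r, "p": p})
    pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)

    # --- NBS per HC-vs-subgroup contrast ------------------------------------
    nbs_summary = {}
    sig_sets = {}
    for k, g in enumerate(MDD_GROUPS):
        a_ids = [s for s in sids if groups[s] == g]
        b_ids = [s for s in sids if groups[s] == "HC"]
        cov = covariates.loc[a_ids + b_ids]
        res = nbs_test(
            [conns[s] for s in a_ids], [conns[s] for s in b_ids],
            covariates=cov, n_permutations=nbs_permutations,
            seed=stage_seed(seed, 100 + k), contrast=(g, "HC"),
        )
        sig = res.significant_edges(alpha)
        sig_sets[g] = sig
        nbs_summary[f"{g}_vs_HC"] = {
            "primary_threshold": res.primary_threshold,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
            "components": [
                {"direction": c.direction, "size": c.size, "p": c.p,
                 "p_corrected": c.p_corrected}
                for c in res.components
            ],
            "n_significant_edges": len(sig),
        }
        if sig:
            tfull = edge_stats([conns[s] for s in a_ids],
                               [conns[s] for s in b_ids], cov)
            write_edge_list([(i, j, tfull[i, j]) for i, j in sorted(sig)],
                            outdir / f"nbs_edges_{g}_vs_HC.tsv")
    (outdir / "nbs_summary.json").write_text(json.dumps(nbs_summary, indent=2))

    # --- conjunction (pairwise overlap) and feature edge set ----------------
    # an edge qualifies when at least two contrasts both flag it ("common
    # connections between arbitrary two groups"); falls back to the union of
    # all flagged edges if no edge overlaps
    nonempty = [s for s in sig_sets.values() if s]
    conj = overlap_edges(nonempty, min_count=2) if len(nonempty) >= 2 else frozenset()
    write_edge_list([(i, j, 1.0) for i, j in sorted(conj)],
                    outdir / "conjunction.tsv")
    if conj:
        feature_edges = conj
        feature_source = "pairwise_overlap"
    else:
        feature_edges = frozenset().union(*nonempty) if nonempty else frozenset()
        feature_source = "union"
    if not feature_edges:
        raise DataError("NBS found no differential edges; nothing to classify")

    # --- classification ------------------------------------------------------
    reports, skipped = run_all_contrasts(
        conns, groups.to_dict(), feature_edges, mode="fci",
        partition=partition, n_splits=clf_splits, cv_folds=clf_cv_folds,
        n_permutations=clf_permutations, seed=stage_seed(seed, 200),
        c_grid=clf_c_grid,
    )
    clf_rows = []
    for (a, b), rep in reports.items():
        clf_rows.append({
            "contrast": f"{a}_vs_{b}",
            "accuracy": rep.accuracy, "accuracy_sd": rep.accuracy_sd,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "auc": rep.auc, "auc_sd": rep.auc_sd,
            "permutation_p": rep.permutation_p,
            "n_splits": rep.n_splits, "cv_folds": rep.cv_folds,
            "n_permutations": rep.n_permutations,
        })
    pd.DataFrame(clf_rows).to_csv(outdir / "classification.csv", index=False)
    (outdir / "classification_skipped.json").write_text(json.dumps(
        [{"contrast": list(s["contrast"]), "reason": s["reason"]}
         for s in skipped], indent=2))

    # --- heterogeneity screens ----------------------------------------------
    het_tables = []
    mdd_rows = retained.loc[mdd].set_index("subject_id")
    het_data = summaries.loc[mdd].join(
        mdd_rows[list(CLINICAL_VARS) + ["hamd_total"]])
    for split, strata in (
        ("sex", mdd_rows["sex"]),
        ("age", age_stratum(mdd_rows["age"].to_numpy()).set_axis(mdd_rows.index)),
    ):
        tab = heterogeneity_screen(het_data, strata.loc[het_data.index], alpha)
        tab.insert(0, "split", split)
        het_tables.append(tab)
    heterogeneity = pd.concat(het_tables, ignore_index=True)
    heterogeneity.to_csv(outdir / "heterogeneity.csv", index=False)

    # --- report and manifest -------------------------------------------------
    n_metrics = len(metric_names(partition))
    summary = {
        "seed": seed,
        "n_subjects": len(cohort.subjects),
        "n_retained": len(retained),
        "n_excluded": len(exclusions),
        "n_metrics_per_contrast": n_metrics,
        "n_metric_contrasts": len(contrasts),
        "n_roles": len(role_rows),
        "stable_networks": int(trajectory["stable"].sum()),
        "nbs_significant_edges": {g: len(s) for g, s in sig_sets.items()},
        "n_conjunction_edges": len(conj),
        "feature_source": feature_source,
        "n_feature_edges": len(feature_edges),
        "n_classification_reports": len(reports),
        "n_classification_skipped": len(skipped),
        "n_heterogeneity_rows": len(heterogeneity),
    }
    lines = [
        "conngrad demo run",
        "=================",
        f"seed: {seed}",
        f"subjects simulated: {summary['n_subjects']} "
        f"(retained after QC: {summary['n_retained']})",
        f"metric tests: {n_metrics} metrics x {len(contrasts)} contrasts",
        f"role assignments: {len(role_rows)} (networks x groups); "
        f"{summary['stable_networks']} networks role-stable",
        "NBS significant edges per contrast: "
        + ", ".join(f"{g}:{len(s)}" for g, s in sig_sets.items()),
        f"conjunction edges: {len(conj)} (features from {feature_source}, "
        f"{len(feature_edges)} edges)",
        f"classification reports: {len(reports)} "
        f"({len(skipped)} skipped)",
        f"heterogeneity rows: {len(heterogeneity)}",
    ]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    cfg = dataclasses.asdict(config)
    cfg.pop("partition", None)
    cfg.update({"nbs_permutations": nbs_permutations,
                "clf_splits": clf_splits, "clf_cv_folds": clf_cv_folds,
                "clf_permutations": clf_permutations,
                "clf_c_grid": list(clf_c_grid), "alpha": alpha})
    write_manifest(outdir, cfg, seed)
    return summary
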