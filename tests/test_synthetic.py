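import numpy as np
import pytest
import scipy.stats as sps

from conngrad.atlas import GROUPS, AtlasPartition
from conngrad.connectome import compute_fc, summarize_networks
from conngrad.errors import ConfigError
from conngrad.synth import (SyntheticConfig, generate_cohort, sign_pattern,
                            simulate_study, target_correlation)


def tiny_partition():
    """16 nodes in 4 networks of 4 — keeps simulation tests fast."""
    return AtlasPartition(tuple(range(1, 17)),
                          ("W",) * 4 + ("X",) * 4 + ("Y",) * 4 + ("Z",) * 4)


def tiny_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        partition=tiny_partition(),
        n_per_group={g: 4 for g in GROUPS},
        T=120,
        cohesion={"W": 0.4, "X": 0.3, "Y": 0.25, "Z": 0.2},
        coupling={"W": 0.6, "X": 0.5, "Y": 0.45, "Z": 0.4},
        wnc_curves={"X": {"MDDmoSI": 0.15}},
        coupling_curves={"X": {"MDDmoSI": -0.2}},
        site_labels=("s1", "s2"),
        site_shift={"s1": 0.005, "s2": -0.005},
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestTargetCorrelation:
    def test_block_structure_and_pd(self):
        cfg = tiny_config()
        C = target_correlation(cfg, "HC", "s1")
        part = cfg.partition
        # within block X constant, equal to cohesion + site shift
        idx = part.indices("X")
        block = C[np.ix_(idx, idx)]
        off = block[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.3 + 0.005)
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_default_config_pd_everywhere(self):
        cfg = SyntheticConfig()
        for g in GROUPS:
            C = target_correlation(cfg, g, "site1")
            assert np.linalg.eigvalsh(C)[0] > 0

    def test_excessive_shift_rejected(self):
        cfg = tiny_config(wnc_curves={"X": {"MDDmoSI": 0.9}})
        with pytest.raises(ConfigError, match="cohesion"):
            target_correlation(cfg, "MDDmoSI", "s1")


class TestGenerateCohort:
    def test_determinism(self):
        s1, ts1, gt1 = generate_cohort(tiny_config(seed=9))
        s2, ts2, gt2 = generate_cohort(tiny_config(seed=9))
        assert s1.equals(s2)
        for k in ts1:
            np.testing.assert_array_equal(ts1[k], ts2[k])
        assert gt1["planted_wnc"] == gt2["planted_wnc"]

    def test_subjects_stable_under_other_group_sizes(self):
        cfg_a = tiny_config(seed=4)
        npg = {g: 4 for g in GROUPS}
        npg["MDDSB"] = 8
        cfg_b = tiny_config(seed=4, n_per_group=npg)
        _, ts_a, _ = generate_cohort(cfg_a)
        _, ts_b, _ = generate_cohort(cfg_b)
        np.testing.assert_array_equal(ts_a["MDDmSI_002"], ts_b["MDDmSI_002"])

    def test_no_effect_limit_recovers_baseline(self):
        """With no planted curves, sample within-block r ~ cohesion."""
        cfg = tiny_config(seed=1, wnc_curves={}, coupling_curves={},
                          n_per_group={"HC": 30}, T=600,
                          site_shift={"s1": 0.0, "s2": 0.0})
        _, series, _ = generate_cohort(cfg)
        part = cfg.partition
        vals = []
        for ts in series.values():
            s = summarize_networks(compute_fc(ts), part)
            vals.append(s.wnc["X"])
        assert np.mean(vals) == pytest.approx(0.3, abs=0.02)

    def test_planted_wnc_shift_recovered(self):
        """+0.15 on X within-block for MDDmoSI is recovered vs HC."""
        diffs = []
        for seed in range(10):
            cfg = tiny_config(seed=seed, n_per_group={"HC": 12, "MDDmoSI": 12},
                              coupling_curves={})
            _, series, _ = generate_cohort(cfg)
            part = cfg.partition
            w = {"HC": [], "MDDmoSI": []}
            for sid, ts in series.items():
                g = sid.rsplit("_", 1)[0]
                w[g].append(summarize_networks(compute_fc(ts), part).wnc["X"])
            diffs.append(np.mean(w["MDDmoSI"]) - np.mean(w["HC"]))
        assert np.mean(diffs) == pytest.approx(0.15, abs=0.03)

    def test_group_sizes_and_suicide_scores(self):
        subjects, _, _ = generate_cohort(tiny_config(seed=2))
        assert subjects.groupby("group").size().to_dict() == {
            g: 4 for g in GROUPS}
        mdd = subjects[subjects.group != "HC"]
        from conngrad.atlas import assign_suicidality_group
        for _, row in mdd.iterrows():
            assert assign_suicidality_group(row.hamd_suicide, True) == row.group


class TestClinical:
    def test_zero_coefficients_give_independence(self):
        cfg = tiny_config(seed=3, n_per_group={"HC": 50, "MDDNSI": 50},
                          clinical_model={"hamd_anxiety": 0.0,
                                          "hamd_weight": 0.0,
                                          "hamd_retardation": 0.0,
                                          "hamd_sleep": 0.0})
        cohort = simulate_study(cfg)
        fci = np.array([cohort.ground_truth["planted_fci"][s]
                        for s in cohort.subjects["subject_id"]])
        r = np.corrcoef(fci, cohort.subjects["hamd_anxiety"])[0, 1]
        assert abs(r) < 0.2

    def test_negative_anxiety_coefficient_recovered(self):
        """The planted negative FCI-anxiety link is detectable at n=150."""
        hits = 0
        for seed in range(10):
            cfg = tiny_config(seed=seed,
                              n_per_group={"MDDNSI": 75, "MDDmSI": 75})
            cohort = simulate_study(cfg)
            fci = np.array([cohort.ground_truth["planted_fci"][s]
                            for s in cohort.subjects["subject_id"]])
            r, p = sps.pearsonr(fci, cohort.subjects["hamd_anxiety"])
            hits += (r < 0) and (p < 0.05)
        assert hits >= 9

    def test_hamd_total_rises_with_severity(self):
        cohort = simulate_study(tiny_config(seed=5))
        means = cohort.subjects.groupby("group")["hamd_total"].mean()
        assert means["HC"] < means["MDDNSI"] < means["MDDSB"]


class TestGroundTruthClosure:
    def test_planted_curves_rederivable(self):
        """Ground truth suffices to re-derive every planted trajectory."""
        cfg = tiny_config(seed=6)
        _, _, gt = generate_cohort(cfg)
        rebuilt = SyntheticConfig(
            seed=gt["seed"], partition=cfg.partition,
            n_per_group=dict(cfg.n_per_group), T=cfg.T,
            cohesion=gt["cohesion"], coupling=gt["coupling"],
            wnc_curves=gt["wnc_curves"], coupling_curves=gt["coupling_curves"],
            site_labels=cfg.site_labels, site_shift=gt["site_shift"],
        )
        from conngrad.synth import planted_summary_curves
        curves = planted_summary_curves(rebuilt)
        for n in gt["affected_networks"]:
            np.testing.assert_allclose(curves["wnc"][n], gt["planted_wnc"][n])
            np.testing.assert_allclose(curves["ovo"][n], gt["planted_ovo"][n])

    def test_default_curves_are_nonmonotone(self):
        """WNC rises then falls; OVO falls then recovers."""
        gt = SyntheticConfig()
        from conngrad.synth import planted_summary_curves
        curves = planted_summary_curves(gt)
        for n in gt.affected_networks:
            w = sign_pattern(curves["wnc"][n])
            o = sign_pattern(curves["ovo"][n])
            assert w[0] == 1 and w[-1] == -1
            assert o[0] == -1 and o[-1] == 1


def test_sign_pattern():
    assert sign_pattern([0, 1, 3, 2, 2]) == [1, 1, -1, 0]
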