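import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from conngrad.errors import DataError
from conngrad.inference import (age_stratum, demographic_table, fdr_adjust,
                                heterogeneity_screen, metric_group_test,
                                metric_test_table, partial_pearson)


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg adjusted p-values from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert fdr_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            fdr_adjust([0.5, 1.2])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            np.testing.assert_allclose(fdr_adjust(p), bh_stepup(p), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_monotone_in_raw_p(self, p):
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(p) - 1e-12).all()


class TestGroupTest:
    def test_reduces_to_oneway_anova(self, rng):
        y = rng.standard_normal(60)
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        res = metric_group_test(y, groups)
        f, p = sps.f_oneway(y[:20], y[20:40], y[40:])
        assert res.statistic == pytest.approx(f)
        assert res.p == pytest.approx(p)

    def test_power_with_covariates(self, rng, covariates_frame):
        """A 1.5 SD group shift is detected through covariate adjustment."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            y = np.r_[r.standard_normal(30), r.standard_normal(30) + 1.5]
            cov = covariates_frame(60, r)
            res = metric_group_test(y, ["a"] * 30 + ["b"] * 30, cov)
            hits += res.p < 0.01
        assert hits >= 18

    def test_null_calibration(self):
        """Raw p under the null is uniform: rejection rate ~ alpha."""
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            r = np.random.default_rng(10_000 + rep)
            y = r.standard_normal(40)
            res = metric_group_test(y, ["a"] * 20 + ["b"] * 20)
            rejections += res.p < 0.05
        assert abs(rejections / n_reps - 0.05) <= 0.04

    def test_site_confounded_with_group_rejected(self, rng):
        y = rng.standard_normal(20)
        cov = pd.DataFrame({"site": ["x"] * 10 + ["y"] * 10})
        with pytest.raises(DataError, match="collinear"):
            metric_group_test(y, ["a"] * 10 + ["b"] * 10, cov)

    def test_table_has_one_row_per_metric(self, rng):
        metrics = pd.DataFrame(rng.standard_normal((30, 5)),
                               columns=list("vwxyz"))
        tab = metric_test_table(metrics, ["a"] * 15 + ["b"] * 15)
        assert len(tab) == 5
        assert (tab["p_fdr"] >= tab["p"] - 1e-12).all()


class TestDemographics:
    def test_chi2_hand_example(self):
        """Perfectly separated 2x2 table (10,0 / 0,10): chi2 = 20."""
        subjects = pd.DataFrame({
            "group": ["g1"] * 10 + ["g2"] * 10,
            "sex": ["f"] * 10 + ["m"] * 10,
            "age": np.tile(np.arange(10.0), 2),
            "education": np.tile(np.arange(10.0), 2),
        })
        out = demographic_table(subjects)
        chi2 = out["tests"].set_index("variable").loc["sex", "statistic"]
        assert chi2 == pytest.approx(20.0)

    def test_lsd_matches_pooled_t(self, rng):
        subjects = pd.DataFrame({
            "group": ["a"] * 12 + ["b"] * 12,
            "age": rng.normal(30, 5, 24),
            "education": rng.normal(12, 2, 24),
            "sex": rng.choice(["f", "m"], 24),
        })
        out = demographic_table(subjects)
        lsd = out["lsd"]["age"]
        # two groups: LSD pairwise t equals the classic pooled two-sample t
        t, p = sps.ttest_ind(subjects["age"][:12], subjects["age"][12:])
        assert lsd.loc["a", "b"] == pytest.approx(p)

    def test_single_group_rejected(self):
        subjects = pd.DataFrame({"group": ["a"] * 5, "age": np.arange(5.0),
                                 "education": np.arange(5.0),
                                 "sex": ["f"] * 5})
        with pytest.raises(DataError):
            demographic_table(subjects)


class TestPartialPearson:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        r, p = partial_pearson(x, y)
        r0, p0 = sps.pearsonr(x, y)
        assert r == pytest.approx(r0)
        assert p == pytest.approx(p0)

    def test_matches_first_order_closed_form(self, rng):
        """r_xy.z from the textbook formula on a 3-variable toy."""
        z = rng.standard_normal(80)
        x = 0.6 * z + rng.standard_normal(80)
        y = -0.4 * z + rng.standard_normal(80)
        rxy = sps.pearsonr(x, y)[0]
        rxz = sps.pearsonr(x, z)[0]
        ryz = sps.pearsonr(y, z)[0]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        r, _ = partial_pearson(x, y, pd.DataFrame({"z": z}))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.standard_normal((60, 4)),
                          columns=["x", "y", "c1", "c2"])
        df["x"] += 0.5 * df["c1"]
        df["y"] += 0.5 * df["c1"]
        r, p = partial_pearson(df["x"].to_numpy(), df["y"].to_numpy(),
                               df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-9)

    def test_covariate_copy_gives_zero(self, rng):
        z = rng.standard_normal(40)
        x = rng.standard_normal(40)
        r, p = partial_pearson(x, z.copy(), pd.DataFrame({"z": z}))
        assert abs(r) < 1e-8


class TestHeterogeneity:
    def test_exact_small_sample_enumeration(self):
        """(1,2) vs (3,4): two-sided exact rank-sum p = 1/3."""
        data = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        out = heterogeneity_screen(data, ["a", "a", "b", "b"])
        assert out["p"].iloc[0] == pytest.approx(1 / 3)

    def test_identical_heavy_ties_near_one(self):
        data = pd.DataFrame({"v": [1.0, 1.0, 2.0, 1.0, 1.0, 2.0] * 4})
        out = heterogeneity_screen(data, ["a", "b"] * 12)
        assert out["p"].iloc[0] > 0.8

    def test_log_scale_cutoff(self):
        """The conventional significance line sits at log10(0.05) ~ -1.301."""
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"v": np.r_[rng.normal(0, 1, 30),
                                        rng.normal(3, 1, 30)]})
        out = heterogeneity_screen(data, ["a"] * 30 + ["b"] * 30)
        row = out.iloc[0]
        assert row["significant"] == (row["log10_p"] < np.log10(0.05))
        assert np.log10(0.05) == pytest.approx(-1.30103, abs=1e-5)

    def test_empty_stratum_rejected(self):
        data = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(DataError):
            heterogeneity_screen(data, ["a", "a", "a"])


def test_age_split_boundaries():
    s = age_stratum(np.array([18, 37, 38, 65, 17, 66]))
    assert list(s[:4]) == ["younger", "younger", "older", "older"]
    assert s[4:].isna().all()
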