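import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mirlink.diffexpr as de
from mirlink.datamodel import CountMatrix, SampleSheet

from conftest import nb_matrix


class TestCPM:
    def test_definition(self):
        df = pd.DataFrame({"s1": [10, 999990]}, index=["f1", "rest"])
        c = de.cpm(CountMatrix(df, "mrna"))
        assert c.loc["f1", "s1"] == pytest.approx(10.0)

    def test_all_zero_feature_is_zero(self, tiny_counts):
        df = tiny_counts.counts.copy()
        df.loc["geneB"] = 0
        c = de.cpm(CountMatrix(df, "mrna"))
        assert (c.loc["geneB"] == 0).all()

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 100, (20, 6)),
                          index=[f"f{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(6)])
        c = de.cpm(CountMatrix(df, "mrna"))
        assert np.allclose(c.sum(axis=0), 1e6)

    def test_zero_library_named_in_error(self):
        df = pd.DataFrame({"s1": [1], "empty": [0]}, index=["f1"])
        with pytest.raises(ValueError, match="empty"):
            de.cpm(CountMatrix(df, "mrna"))


class TestLowExpressionFilter:
    def cm(self, cpm_rows):
        # scale to library size 1e6 so CPM equals the requested values
        df = pd.DataFrame(
            cpm_rows, index=[f"f{i}" for i in range(len(cpm_rows))],
            columns=[f"s{j}" for j in range(len(cpm_rows[0]))], dtype=float,
        )
        df.loc["pad"] = 1e6 - df.sum(axis=0)
        return CountMatrix(df.astype(int), "mirna")

    def test_half_of_samples_rule(self):
        cm = self.cm([[12, 11, 0, 0]])
        kept = de.filter_low_expression(cm, de.DEConfig())
        assert "f0" in kept.feature_ids

    def test_below_threshold_removed(self):
        cm = self.cm([[9, 9, 9, 9]])
        kept = de.filter_low_expression(cm, de.DEConfig())
        assert "f0" not in kept.feature_ids

    def test_matches_brute_force_and_idempotent(self):
        rng = np.random.default_rng(3)
        cm, _ = nb_matrix(rng, n_features=200, n_tumor=3, n_normal=3,
                          log2_mean=3, log2_sd=3)
        cfg = de.DEConfig()
        kept = de.filter_low_expression(cm, cfg)
        c = de.cpm(cm)
        need = int(np.ceil(cfg.cpm_frac * cm.shape[1]))
        expected = [f for f in cm.feature_ids
                    if (c.loc[f] >= cfg.cpm_min).sum() >= need]
        assert kept.feature_ids == expected
        again = de.filter_low_expression(kept, cfg)
        assert again.feature_ids == kept.feature_ids


class TestNormFactors:
    def test_scalar_multiple_columns_give_unit_factors(self):
        rng = np.random.default_rng(4)
        base = rng.integers(10, 1000, 100)
        df = pd.DataFrame({f"s{k}": base * (k + 1) for k in range(4)},
                          index=[f"f{i}" for i in range(100)])
        nf = de.norm_factors(CountMatrix(df, "mrna"))
        assert np.allclose(nf.factors, 1.0, atol=1e-9)

    def test_single_feature_falls_back_to_unit(self):
        df = pd.DataFrame({"s1": [100], "s2": [300]}, index=["f1"])
        nf = de.norm_factors(CountMatrix(df, "mrna"))
        assert np.allclose(nf.factors, 1.0)

    def test_planted_de_leaves_factors_near_one(self):
        # moderate abundance spread so planted DE cannot dominate the library
        rng = np.random.default_rng(5)
        lfc = np.zeros(500)
        lfc[rng.choice(500, 25, replace=False)] = rng.choice([-2.0, 2.0], 25)
        cm, _ = nb_matrix(rng, n_features=500, n_tumor=4, n_normal=4,
                          phi=0.0, lfc=lfc, log2_mean=8, log2_sd=1,
                          depth_sd=0.5)
        nf = de.norm_factors(cm)
        assert np.abs(nf.factors - 1.0).max() < 0.05

    def test_geometric_mean_is_one(self, default_study):
        _, mirna, mrna, _, _ = default_study
        for m in (mirna, mrna):
            nf = de.norm_factors(m)
            assert abs(np.log(nf.factors).mean()) < 1e-9


class TestDispersions:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(6)
        cm, sheet = nb_matrix(rng, n_features=500, n_tumor=20, n_normal=20,
                              phi=0.0)
        d = de.estimate_dispersions(cm, sheet)
        assert np.median(d) < 0.05

    def test_identical_within_group_counts_raw_zero(self):
        df = pd.DataFrame([[5, 5, 9, 9]], index=["f0"],
                          columns=["s0", "s1", "s2", "s3"])
        cm = CountMatrix(df, "mrna")
        sheet = SampleSheet(pd.DataFrame(
            {"group": ["tumor", "tumor", "normal", "normal"]},
            index=cm.sample_ids))
        # a single feature: the shrinkage target (median of raw) is also 0
        assert de.estimate_dispersions(cm, sheet).iloc[0] == 0.0

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(7)
        cm, sheet = nb_matrix(rng, n_features=2000, n_tumor=10, n_normal=10,
                              phi=0.2)
        d = de.estimate_dispersions(cm, sheet)
        assert 0.1 <= np.median(d) <= 0.3


class TestNBTest:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        cm, sheet = nb_matrix(rng, n_features=2000, n_tumor=10, n_normal=10,
                              phi=0.1)
        table = de.nb_test(cm, sheet)
        ks = stats.kstest(table["p_raw"], "uniform")
        assert ks.pvalue > 0.01

    def test_all_zero_feature_neutral(self):
        rng = np.random.default_rng(9)
        cm, sheet = nb_matrix(rng, n_features=20, n_tumor=4, n_normal=4)
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        table = de.nb_test(CountMatrix(counts, "mrna"), sheet)
        rec = table.iloc[0]
        assert rec["log2fc"] == 0.0
        assert rec["p_raw"] == 1.0

    def test_sensitivity_on_planted_lfc(self):
        rng = np.random.default_rng(10)
        lfc = np.zeros(2000)
        idx = rng.choice(2000, 200, replace=False)
        lfc[idx] = rng.choice([-3.0, 3.0], 200)
        cm, sheet = nb_matrix(rng, n_features=2000, n_tumor=8, n_normal=8,
                              phi=0.2, lfc=lfc)
        table = de.nb_test(cm, sheet)
        called = table.iloc[idx]
        hit = ((called["direction"] == "up") & (lfc[idx] > 0)) | (
            (called["direction"] == "down") & (lfc[idx] < 0))
        assert hit.mean() >= 0.9

    def test_group_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(11)
        cm, sheet = nb_matrix(rng, n_features=100, n_tumor=5, n_normal=5)
        swapped = SampleSheet(sheet.table.assign(
            group=sheet.table["group"].map(
                {"tumor": "normal", "normal": "tumor"})))
        a = de.nb_test(cm, sheet)
        b = de.nb_test(cm, swapped)
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-9)
        assert np.allclose(a["p_raw"], b["p_raw"], atol=1e-9)

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(12)
        cm, _ = nb_matrix(rng, n_features=10, n_tumor=3, n_normal=3)
        bad = SampleSheet(pd.DataFrame(
            {"group": ["tumor"] * 5 + ["normal"]}, index=cm.sample_ids))
        with pytest.raises(Exception, match="at least 2"):
            de.nb_test(cm, bad)


def bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j>=i} (m/j) p_(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            p[order[j]] * m / (j + 1) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBHAdjust:
    def test_singleton_identity(self):
        assert de.bh_adjust([0.01]) == pytest.approx([0.01])

    def test_hand_worked_example(self):
        assert de.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_dominates_input(self, p):
        q = de.bh_adjust(p)
        assert np.allclose(q, bh_brute_force(p), atol=0, rtol=0)
        assert (q >= np.asarray(p) - 1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.uniform(size=500)
        q = de.bh_adjust(p)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(14)
        p = np.sort(rng.uniform(size=100))
        q = de.bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestClassify:
    def test_large_effect_small_p_but_subthreshold_lfc_is_ns(self):
        t = pd.DataFrame({"feature_id": ["f"], "log2fc": [1.5],
                          "p_raw": [1e-6], "p_adj": [1e-5],
                          "direction": ["ns"]})
        out, counts = de.classify(t)
        assert out["direction"].iloc[0] == "ns"
        assert counts == {"n_up": 0, "n_down": 0}

    def test_random_records_match_brute_force(self):
        rng = np.random.default_rng(15)
        t = pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(100)],
            "log2fc": rng.normal(0, 3, 100),
            "p_raw": rng.uniform(0, 0.05, 100),
            "p_adj": rng.uniform(0, 0.05, 100),
            "direction": "ns",
        })
        cfg = de.DEConfig()
        out, counts = de.classify(t, cfg)
        expect = []
        for r in t.itertuples():
            sig = r.p_raw < cfg.p_threshold and r.p_adj < cfg.fdr_threshold
            if sig and r.log2fc > cfg.lfc_threshold:
                expect.append("up")
            elif sig and r.log2fc < -cfg.lfc_threshold:
                expect.append("down")
            else:
                expect.append("ns")
        assert list(out["direction"]) == expect
        assert counts["n_up"] == expect.count("up")
        assert counts["n_down"] == expect.count("down")


class TestLatentFactors:
    def test_pure_noise_rarely_yields_factors(self):
        ks = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            cm, sheet = nb_matrix(rng, n_features=300, n_tumor=6, n_normal=6,
                                  phi=0.0, log2_mean=8, log2_sd=1.5,
                                  depth_sd=0.0)
            ks.append(de.estimate_latent_factors(cm, sheet, seed=s).shape[1])
        assert np.mean(np.array(ks) == 0) >= 0.9

    def test_planted_batch_recovered(self):
        rng = np.random.default_rng(7)
        base = np.exp2(rng.normal(6, 1.5, 300))
        batch = np.array([1, 0] * 6)
        touched = rng.choice(300, 90, replace=False)
        shift = np.ones((300, 12))
        shift[np.ix_(touched, np.where(batch == 1)[0])] = 2.0
        counts = rng.poisson(base[:, None] * shift)
        cm = CountMatrix(
            pd.DataFrame(counts, index=[f"f{i}" for i in range(300)],
                         columns=[f"s{i}" for i in range(12)]), "mrna")
        sheet = SampleSheet(pd.DataFrame(
            {"group": ["tumor"] * 6 + ["normal"] * 6}, index=cm.sample_ids))
        f = de.estimate_latent_factors(cm, sheet, seed=1)
        assert f.shape[1] >= 1
        assert abs(np.corrcoef(f.iloc[:, 0], batch)[0, 1]) > 0.8

    def test_explicit_zero_factors_changes_nothing(self):
        rng = np.random.default_rng(16)
        cm, sheet = nb_matrix(rng, n_features=50, n_tumor=4, n_normal=4)
        f = de.estimate_latent_factors(cm, sheet, k=0)
        assert f.shape == (8, 0)
        a = de.nb_test(cm, sheet)
        b = de.nb_test(cm, sheet, latent=f)
        pd.testing.assert_frame_equal(a, b)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(17)
        cm, sheet = nb_matrix(rng, n_features=50, n_tumor=4, n_normal=4)
        with pytest.raises(ValueError, match="k="):
            de.estimate_latent_factors(cm, sheet, k=6)
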