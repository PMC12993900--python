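import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glyco.stats import (
    benjamini_hochberg,
    diet_anova,
    pca_metrics,
    rm_correlation,
    spearman_screen,
    variance_f_test,
)


class TestRmCorrelation:
    def test_single_subject_equals_pearson(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        got = rm_correlation(x, y, ["a"] * 10)
        want, _ = sps.pearsonr(x, y)
        assert got.r == pytest.approx(want)

    def test_two_subject_worked_example(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [11, 12, 13, 1, 2, 3]
        res = rm_correlation(x, y, ["A", "A", "A", "B", "B", "B"])
        assert res.r == pytest.approx(1.0)
        assert res.df == 3
        assert res.n_subjects == 2

    def test_offset_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        subj = np.repeat(["a", "b", "c"], 4)
        base = rm_correlation(x, y, subj)
        offsets = np.repeat([100.0, -50.0, 3.0], 4)
        moved = rm_correlation(x + offsets, y, subj)
        assert moved.r == pytest.approx(base.r, rel=1e-12)
        assert moved.p == pytest.approx(base.p, rel=1e-9)

    def test_small_subjects_dropped_with_warning(self, rng):
        x = np.r_[rng.normal(size=6), 5.0]
        y = np.r_[rng.normal(size=6), 5.0]
        subj = np.array(["a"] * 3 + ["b"] * 3 + ["c"])
        with pytest.warns(UserWarning, match="dropped"):
            res = rm_correlation(x, y, subj)
        assert res.n_subjects == 2
        assert res.n_obs == 6

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=20)
        subj = np.repeat(list("abcde"), 4)
        y = x + rng.normal(0, 0.8, size=20)
        got = rm_correlation(x, y, subj)
        df = pd.DataFrame({"x": x, "y": y, "s": subj})
        want = pingouin.rm_corr(data=df, x="x", y="y", subject="s")
        assert got.r == pytest.approx(float(want["r"].iloc[0]), abs=1e-6)
        assert got.df == int(want["dof"].iloc[0])
        assert got.p == pytest.approx(float(want["pval"].iloc[0]), rel=1e-6)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            subj = np.repeat(np.arange(6), 4)
            x = rng.normal(size=24)
            y = rng.normal(size=24)
            if rm_correlation(x, y, subj).p <= 0.05:
                hits += 1
        assert 0.02 <= hits / n_sims <= 0.08


class TestSpearmanScreen:
    def _tables(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        night = pd.DataFrame({"animal_id": ids, "m1": rng.normal(size=n),
                              "m2": rng.normal(size=n)})
        post = pd.DataFrame({"animal_id": ids, "k1": rng.normal(size=n)})
        return night, post

    def test_monotone_transform_gives_rho_one(self):
        ids = list("abcde")
        x = np.array([1.0, 2, 3, 4, 5])
        night = pd.DataFrame({"animal_id": ids, "m": x})
        post = pd.DataFrame({"animal_id": ids, "k": np.exp(x)})
        out = spearman_screen(night, post)
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert out.iloc[0]["flag"] == "significant"

    def test_reversed_ranks_gives_minus_one(self):
        ids = list("abcde")
        x = np.array([1.0, 2, 3, 4, 5])
        night = pd.DataFrame({"animal_id": ids, "m": x})
        post = pd.DataFrame({"animal_id": ids, "k": -x})
        out = spearman_screen(night, post)
        assert out.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_monotone_invariance(self):
        night, post = self._tables()
        base = spearman_screen(night, post)
        night2 = night.copy()
        night2["m1"] = np.exp(night2["m1"])  # strictly monotone transform
        again = spearman_screen(night2, post)
        pd.testing.assert_frame_equal(base, again)

    def test_constant_column_skipped_with_warning(self):
        night, post = self._tables()
        night["m1"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_screen(night, post)
        assert not (out["night_metric"] == "m1").any()

    def test_flags_match_thresholds(self):
        night, post = self._tables(n=7, seed=3)
        out = spearman_screen(night, post)
        for _, row in out.iterrows():
            if row["p"] <= 0.05:
                assert row["flag"] == "significant"
            elif row["p"] <= 0.10:
                assert row["flag"] == "trend"
            else:
                assert row["flag"] == "ns"

    def test_too_few_animals_errors(self):
        night, post = self._tables(n=3)
        with pytest.raises(ValueError):
            spearman_screen(night, post)

    def test_copula_recovery(self):
        # engineered dependence rho ~ 0.9, n = 7, many seeds: median close
        rng = np.random.default_rng(11)
        estimates = []
        for _ in range(200):
            z = rng.normal(size=7)
            x = z + rng.normal(0, 0.3, 7)
            y = z + rng.normal(0, 0.3, 7)
            ids = [f"p{i}" for i in range(7)]
            out = spearman_screen(
                pd.DataFrame({"animal_id": ids, "m": x}),
                pd.DataFrame({"animal_id": ids, "k": y}),
            )
            estimates.append(out.iloc[0]["rho"])
        true_rho = 6 / np.pi * np.arcsin(1 / (1 + 0.09) / 2)
        assert abs(np.median(estimates) - true_rho) < 0.1

    def test_fdr_column(self):
        night, post = self._tables(n=8, seed=5)
        out = spearman_screen(night, post, fdr=True)
        assert "p_adjusted" in out.columns
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()


class TestDietAnova:
    def test_identical_groups(self):
        values = [1.0, 2, 3, 1, 2, 3]
        f, p = diet_anova(values, ["HS"] * 3 + ["HF"] * 3)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_equals_squared_t(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 8)
        f, p_f = diet_anova(np.r_[a, b], ["A"] * 8 + ["B"] * 8)
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_type_one_error(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(500):
            values = rng.normal(size=16)
            _, p = diet_anova(values, ["A"] * 8 + ["B"] * 8)
            if p <= 0.05:
                hits += 1
        assert 0.03 <= hits / 500 <= 0.08

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            diet_anova([1.0, 2, 3], ["A", "A", "B"])


class TestVarianceFTest:
    def test_equal_samples_give_one(self):
        a = [1.0, 2, 3, 4]
        f, p = variance_f_test(a, a)
        assert f == 1.0
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        f, _ = variance_f_test([0, 2, 0, 2], [0, 1, 0, 1])
        assert f == pytest.approx(4.0)

    def test_reciprocal_on_swap(self, rng):
        a, b = rng.normal(0, 2, 10), rng.normal(0, 1, 12)
        f1, p1 = variance_f_test(a, b)
        f2, p2 = variance_f_test(b, a)
        assert f1 == pytest.approx(1 / f2)
        assert p1 == pytest.approx(p2)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 2.0], [5.0, 5.0])


class TestPcaMetrics:
    def test_perfectly_correlated_columns(self, rng):
        x = rng.normal(size=10)
        table = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca_metrics(table)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthogonal_equal_variance(self):
        # balanced +-1 design: empirically uncorrelated equal-variance columns
        a = np.array([1.0, 1, -1, -1])
        b = np.array([1.0, -1, 1, -1])
        res = pca_metrics(pd.DataFrame({"a": a, "b": b}))
        np.testing.assert_allclose(res.explained_variance_ratio, [0.5, 0.5])

    def test_reconstruction_identity(self, rng):
        table = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        res = pca_metrics(table)
        z = (table - table.mean()) / table.std(ddof=1)
        np.testing.assert_allclose(res.reconstruct(), z.to_numpy(), atol=1e-9)

    def test_explained_fractions_sum_to_one(self, rng):
        table = pd.DataFrame(rng.normal(size=(9, 4)))
        res = pca_metrics(table)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_constant_column_named_in_error(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=6), "flat": np.ones(6)})
        with pytest.raises(ValueError, match="flat"):
            pca_metrics(table)

    def test_missing_cells_rejected(self, rng):
        table = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        table.loc[2, "b"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_metrics(table)


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
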