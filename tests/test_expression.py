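import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelome import expression
from allelome.glm import fit_nb_glm, size_factors


class TestTPM:
    def test_rate_normalisation(self):
        counts = pd.DataFrame({"s": [10, 20]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2000})
        out = expression.tpm(counts, lengths)
        assert out["s"].tolist() == [500000.0, 500000.0]

    def test_single_gene_takes_whole_million(self):
        out = expression.tpm(pd.DataFrame({"s": [7]}, index=["g"]), pd.Series({"g": 500}))
        assert out["s"].iloc[0] == pytest.approx(1e6)

    def test_scale_invariance_and_column_sums(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(30, 4)), index=[f"g{i}" for i in range(30)]
        )
        counts.iloc[0] += 1  # no all-zero sample
        lengths = pd.Series(rng.integers(200, 5000, size=30), index=counts.index)
        out = expression.tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)
        doubled = expression.tpm(counts * 2, lengths)
        pd.testing.assert_frame_equal(out, doubled)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="all-zero"):
            expression.tpm(counts, pd.Series({"g1": 100, "g2": 100}))


class TestTpmClasses:
    def test_boundary_mapping(self):
        vals = pd.Series([0.0, 1.0, 10.0001, 100.0, 100.1, 0.5, 10.0])
        labels = expression.tpm_classes(vals)
        assert labels.tolist() == ["I", "II", "IV", "IV", "V", "II", "III"]

    def test_exhaustive_partition(self, rng):
        vals = pd.Series(rng.uniform(0, 200, 500))
        labels = expression.tpm_classes(vals)
        assert labels.notna().all()
        assert labels.value_counts().sum() == 500

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expression.tpm_classes(pd.Series([-1.0]))


class TestNBGLMOracles:
    def test_matches_statsmodels_negative_binomial(self, rng):
        import statsmodels.api as sm

        y = rng.negative_binomial(10, 0.3, size=12).astype(float)
        y[0] += 1
        X = np.column_stack([np.ones(12), np.r_[np.zeros(6), np.ones(6)]])
        alpha = 0.08
        mine = fit_nb_glm(y, X, alpha)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        assert np.allclose(mine.beta, ref.params, atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(mine.cov)), ref.bse, rtol=1e-4)

    def test_poisson_limit(self):
        import statsmodels.api as sm

        y = np.array([4.0, 7, 5, 12, 15, 11])
        X = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)]])
        mine = fit_nb_glm(y, X, alpha=1e-10)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(mine.beta, ref.params, atol=1e-3)


class TestDEG:
    def test_identical_conditions_null(self):
        counts = pd.DataFrame(
            {f"a{i}": [100, 50, 20] for i in range(3)}
            | {f"b{i}": [100, 50, 20] for i in range(3)},
            index=["g1", "g2", "g3"],
        )
        cond = ["A"] * 3 + ["B"] * 3
        out = expression.test_deg(counts, cond, ("A", "B"))
        assert np.allclose(out["log2FC"], 0.0, atol=1e-8)
        assert not out["flag"].any()

    def test_size_factors_of_identical_libraries_are_one(self, rng):
        col = rng.integers(1, 100, size=40)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(size_factors(counts), 1.0)

    def test_fourfold_change_recovered(self, rng):
        # 40 changed genes among 160 stable ones, so median-of-ratios size
        # factors are anchored by the unchanged majority
        n_deg, n_stable, disp = 40, 160, 0.05
        mu_stable = rng.uniform(50, 500, size=n_stable)

        def draw(mu, cols):
            lam = rng.gamma(1 / disp, np.outer(mu, np.full(cols, disp)))
            return rng.poisson(lam)

        top = np.column_stack([draw(np.full(n_deg, 200.0), 3), draw(np.full(n_deg, 50.0), 3)])
        bottom = np.column_stack([draw(mu_stable, 3), draw(mu_stable, 3)])
        counts = pd.DataFrame(
            np.vstack([top, bottom]),
            index=[f"deg{i}" for i in range(n_deg)] + [f"g{i}" for i in range(n_stable)],
            columns=[f"s{i}" for i in range(6)],
        )
        out = expression.test_deg(counts, ["A"] * 3 + ["B"] * 3, ("A", "B"))
        deg_rows = out.loc[[f"deg{i}" for i in range(n_deg)]]
        assert abs(deg_rows["log2FC"].mean() + 2.0) < 0.3
        assert deg_rows["flag"].mean() >= 0.9
        stable_rows = out.loc[[f"g{i}" for i in range(n_stable)]]
        assert stable_rows["flag"].mean() <= 0.05

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 30], "b2": [0, 28]},
            index=["dead", "live"],
        )
        out = expression.test_deg(counts, ["A", "A", "B", "B"], ("A", "B"))
        assert bool(out.loc["dead", "excluded"])
        assert np.isnan(out.loc["dead", "log2FC"])


class TestRankSum:
    def test_exact_small_sample_value(self):
        p = expression.rank_sum_test(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_identical_tied_samples_give_one(self):
        p = expression.rank_sum_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert p == pytest.approx(1.0)

    def test_large_sample_shift_detected(self, rng):
        x = rng.normal(0, 1, 300)
        y = rng.normal(0.5, 1, 300)
        assert expression.rank_sum_test(x, y) < 0.05

    def test_class_comparison_letters(self, rng):
        classes = pd.Series(["I"] * 50 + ["V"] * 50, index=[f"g{i}" for i in range(100)])
        levels = pd.Series(
            np.r_[rng.normal(0.6, 0.05, 50), rng.normal(0.2, 0.05, 50)],
            index=classes.index,
        )
        table, letters = expression.class_methylation_comparison(classes, levels)
        assert table["p"].iloc[0] < 0.05
        assert letters["I"] != letters["V"]


class TestBinCorrelation:
    def make_cube(self, bin_series, n_phases=6):
        return np.asarray(bin_series)[None, :, :]

    def test_negative_monotone_relation(self):
        # declining bin methylation against rising log2 expression
        levels = np.array([[0.9, 0.6, 0.3, 0.2, 0.1, 0.05]])
        cube = levels[None, :, :]
        log_tpm = pd.DataFrame(
            [np.log2([1, 2, 4, 8, 16, 32])], index=["g"], columns=list("abcdef")
        )
        out = expression.bin_expression_correlation(cube, ["g"], log_tpm, "CG")
        assert out["r"].iloc[0] < -0.9
        assert bool(out["significant"].iloc[0])
        assert out["sign"].iloc[0] == "negative"

    def test_constant_bin_skipped(self):
        cube = np.full((1, 1, 6), 0.4)
        tpm = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"], columns=list("abcdef"))
        out = expression.bin_expression_correlation(cube, ["g"], tpm, "CG")
        assert len(out) == 0

    def test_r_threshold_alone_is_not_significance(self):
        # engineered r = 0.61 exactly at n = 6: p ~ 0.2, so the p criterion
        # dominates the |r| > 0.6 criterion at few phases
        x = np.array([1.0, 2, 3, 4, 5, 6])
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        z = np.array([1.0, -1, 1, -1, 1, -1])
        z = z - z.mean()
        z = z - (z @ xs) * xs  # orthogonal to x
        z /= np.linalg.norm(z)
        target_r = 0.61
        y = target_r * xs + np.sqrt(1 - target_r**2) * z
        r, p = expression.pearson_with_p(y[None, :], x[None, :])
        assert abs(r[0]) == pytest.approx(0.61, abs=1e-9)
        assert p[0] > 0.05

    def test_sign_summary_counts_gene_by_strongest_bin(self):
        recs = pd.DataFrame(
            {
                "gene_id": ["g", "g", "h"],
                "bin": [0, 1, 0],
                "context": "CG",
                "r": [0.7, -0.9, 0.8],
                "p": [0.01, 0.001, 0.01],
                "significant": [True, True, True],
                "sign": ["positive", "negative", "positive"],
            }
        )
        out = expression.correlation_sign_summary(recs).set_index("context")
        assert out.loc["CG", "n_genes"] == 2
        assert out.loc["CG", "n_negative"] == 1  # g counted by its |r|=0.9 bin
        assert out.loc["CG", "frac_negative"] == pytest.approx(0.5)
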