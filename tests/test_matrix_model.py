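"""Deciles, L x E matrix, gradient field, regression and LMG importances."""

import numpy as np
import pandas as pd
import pytest

from ctsplice.matrix_model import (
    DEFAULT_PREDICTORS,
    GSIRegression,
    MatrixModelError,
    assign_deciles,
    build_le_matrix,
    fit_gsi_regression,
    gradient_field,
    lmg_importance,
    prepare_regression_table,
    progressive_subset_sweep,
    stratify_by_length,
)


class TestDeciles:
    def test_uniform_values_split_evenly(self):
        dec = assign_deciles(np.arange(1, 101))
        assert dec.value_counts().tolist() == [10] * 10
        assert dec.iloc[99] == 10 and dec.iloc[0] == 1

    def test_sizes_differ_by_at_most_one(self):
        dec = assign_deciles(np.random.default_rng(0).normal(size=101))
        sizes = dec.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_degenerate_input_warns_but_splits(self):
        with pytest.warns(UserWarning, match="degenerate"):
            dec = assign_deciles(np.ones(40))
        assert dec.value_counts().tolist() == [4] * 10

    def test_too_few_values_error(self):
        with pytest.raises(MatrixModelError):
            assign_deciles([1, 2, 3])

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(2, 1, 137)
        base = assign_deciles(vals)
        for f in (np.log2, np.sqrt, lambda x: 5 * x + 3):
            assert base.equals(assign_deciles(f(vals)))

    def test_nan_values_stay_unassigned(self):
        vals = [np.nan] + list(range(20))
        dec = assign_deciles(vals)
        assert pd.isna(dec.iloc[0])
        assert dec.dropna().size == 20


class TestLEMatrix:
    @staticmethod
    def _genes(n=400, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "gene_length": rng.lognormal(9, 1, n),
                "premrna_rpkm": rng.lognormal(1, 1, n),
            }
        )

    def test_constant_statistic_fills_cells_with_constant(self):
        genes = self._genes()
        genes["gsi"] = 1.35
        le = build_le_matrix(genes, "gsi")
        assert le.counts.to_numpy().sum() == len(genes)
        vals = le.means.to_numpy()
        assert np.allclose(vals[~np.isnan(vals)], 1.35)

    def test_independent_axes_give_near_uniform_cell_counts(self):
        genes = self._genes(n=5000, seed=3)
        genes["gsi"] = 0.0
        le = build_le_matrix(genes, "gsi")
        counts = le.counts.to_numpy()
        assert counts.sum() == 5000
        # expectation 50 per cell; Poisson-binomial spread stays well inside
        assert counts.min() > 15 and counts.max() < 100

    def test_structured_statistic_orders_cell_means(self):
        genes = self._genes(n=3000, seed=5)
        rng = np.random.default_rng(6)
        genes["gsi"] = (
            0.8 * np.log2(genes["gene_length"])
            - 0.6 * np.log2(genes["premrna_rpkm"])
            + rng.normal(0, 0.2, len(genes))
        )
        le = build_le_matrix(genes, "gsi")
        m = le.means.to_numpy()
        col_trend = np.nanmean(m[9] - m[0])      # along length deciles
        row_trend = np.nanmean(m[:, 9] - m[:, 0])  # along expression deciles
        assert col_trend > 0.5
        assert row_trend < -0.5

    def test_long_format_round_trip(self):
        genes = self._genes(n=200, seed=7)
        genes["gsi"] = 1.0
        long = build_le_matrix(genes, "gsi").to_long()
        assert len(long) == 100
        assert long["n"].sum() == 200


class TestGradient:
    @staticmethod
    def _grid(fn):
        idx = pd.RangeIndex(1, 11)
        return pd.DataFrame(
            [[fn(i, j) for j in range(1, 11)] for i in range(1, 11)],
            index=idx, columns=idx,
        )

    def test_constant_matrix_has_zero_field(self):
        grad = gradient_field(self._grid(lambda i, j: 3.0))
        assert np.allclose(grad[["dL", "dE", "magnitude"]], 0.0)
        assert len(grad) == 64  # interior 8x8

    def test_linear_ramp_gives_unit_vectors(self):
        grad = gradient_field(self._grid(lambda i, j: float(i)))
        assert np.allclose(grad["dL"], 1.0) and np.allclose(grad["dE"], 0.0)

    def test_plane_gives_exact_gradient(self):
        grad = gradient_field(self._grid(lambda i, j: 2.0 * i - 3.0 * j))
        assert np.allclose(grad["dL"], 2.0)
        assert np.allclose(grad["dE"], -3.0)
        assert np.allclose(grad["magnitude"], np.sqrt(13.0))

    def test_transpose_swaps_axes(self):
        grid = self._grid(lambda i, j: i**2 - 0.5 * j * i)
        g = gradient_field(grid).sort_values(["L_decile", "E_decile"])
        gt = gradient_field(grid.T).sort_values(["E_decile", "L_decile"])
        # transposed-grid cell (j, i) corresponds to original cell (i, j)
        assert np.allclose(g["dL"].to_numpy(), gt["dE"].to_numpy())
        assert np.allclose(g["dE"].to_numpy(), gt["dL"].to_numpy())

    def test_missing_neighbor_falls_back_one_sided(self):
        grid = self._grid(lambda i, j: float(i))
        grid.iloc[2, 3] = np.nan
        grad = gradient_field(grid).set_index(["L_decile", "E_decile"])
        flagged = grad[grad["one_sided"]]
        assert len(flagged) > 0

    def test_all_missing_interior_errors(self):
        grid = self._grid(lambda i, j: np.nan)
        with pytest.raises(MatrixModelError):
            gradient_field(grid)


def _linear_dataset(n=500, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "gene_length": rng.lognormal(9, 1.2, n),
            "premrna_rpkm": rng.lognormal(1, 1, n),
            "n_introns": rng.integers(1, 30, n).astype(float),
            "mean_5ss": rng.normal(8, 2, n),
            "mean_3ss": rng.normal(6, 2, n),
            "gc_ratio": rng.normal(1.2, 0.1, n),
        }
    )
    df = prepare_regression_table(df)
    coef = {"log2_gene_length": 0.4, "log2_premrna_rpkm": -0.3,
            "n_introns": 0.02, "mean_5ss": 0.05, "mean_3ss": 0.03,
            "gc_ratio": 0.5}
    df["gsi"] = sum(c * df[k] for k, c in coef.items()) + 0.7
    df["gsi"] += rng.normal(0, noise, n)
    return df, coef


class TestRegression:
    def test_noiseless_recovery_is_exact(self):
        df, coef = _linear_dataset(noise=0.0)
        fit = fit_gsi_regression(df)
        for name, value in coef.items():
            assert fit.coefficients[name] == pytest.approx(value, abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(0.7, abs=1e-8)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_response_has_negligible_r2(self):
        df, _ = _linear_dataset(n=2000, seed=2)
        rng = np.random.default_rng(3)
        df["gsi"] = rng.normal(0, 1, len(df))
        fit = fit_gsi_regression(df)
        assert fit.r_squared <= 0.05

    def test_coefficient_error_shrinks_with_sample_size(self):
        errs = []
        for n in (200, 3200):
            df, coef = _linear_dataset(n=n, noise=0.5, seed=4)
            fit = fit_gsi_regression(df)
            errs.append(abs(fit.coefficients["log2_gene_length"]
                            - coef["log2_gene_length"]))
        assert errs[1] < errs[0]

    def test_rank_deficient_design_names_collinear_pair(self):
        df, _ = _linear_dataset(n=100)
        df["dup"] = df["mean_5ss"]
        with pytest.raises(MatrixModelError, match="mean_5ss.*dup"):
            fit_gsi_regression(df, predictors=("mean_5ss", "dup"))

    def test_missing_rows_are_dropped_and_counted(self):
        df, _ = _linear_dataset(n=100)
        df.loc[df.index[:7], "gc_ratio"] = np.nan
        model = GSIRegression().fit(df)
        assert model.n_dropped_ == 7 and model.n_used_ == 93

    def test_dominant_predictor_enters_sweep_first(self):
        df, _ = _linear_dataset(n=1500, seed=8)
        rng = np.random.default_rng(9)
        df["gsi"] = 1.0 * df["log2_gene_length"] + rng.normal(0, 0.3, len(df))
        sweep = progressive_subset_sweep(df)
        assert sweep.iloc[0]["added"] == "log2_gene_length"
        assert sweep["r_squared"].is_monotonic_increasing

    def test_get_set_params_round_trip(self):
        model = GSIRegression(predictors=("mean_5ss",))
        params = model.get_params()
        clone = GSIRegression().set_params(**params)
        assert clone.get_params() == params

    def test_stratify_by_length(self):
        df, _ = _linear_dataset(n=200)
        short = stratify_by_length(df, "short")
        long = stratify_by_length(df, "long")
        assert len(short) == len(long) == 40
        assert short["gene_length"].max() < long["gene_length"].min()


class TestLMG:
    def test_orthogonal_predictors_get_marginal_r2(self):
        rng = np.random.default_rng(0)
        n = 4096
        x1 = np.repeat([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, -1.0], n // 2)
        y = 2 * x1 + 1 * x2 + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        imp = lmg_importance(X, y)

        def marginal(x):
            r = np.corrcoef(x, y)[0, 1]
            return r * r

        assert imp["x1"] == pytest.approx(marginal(x1), abs=1e-10)
        assert imp["x2"] == pytest.approx(marginal(x2), abs=1e-10)

    def test_duplicated_predictors_share_their_contribution(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = x + rng.normal(0, 0.3, 300)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        imp = lmg_importance(X, y)
        assert imp["a"] == pytest.approx(imp["b"], abs=1e-12)

    def test_importances_sum_to_r2(self):
        df, _ = _linear_dataset(n=400, noise=0.4, seed=5)
        fit = fit_gsi_regression(df)
        assert fit.importance.sum() == pytest.approx(fit.r_squared, abs=1e-8)
        assert (fit.importance >= -1e-10).all()

    def test_permutation_invariance_of_importances(self):
        df, _ = _linear_dataset(n=300, noise=0.4, seed=6)
        f1 = fit_gsi_regression(df, predictors=DEFAULT_PREDICTORS)
        f2 = fit_gsi_regression(df, predictors=DEFAULT_PREDICTORS[::-1])
        for name in DEFAULT_PREDICTORS:
            assert f1.importance[name] == pytest.approx(
                f2.importance[name], abs=1e-10)

    def test_too_many_predictors_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 11)))
        X.columns = [f"p{i}" for i in range(11)]
        with pytest.raises(MatrixModelError, match="limit"):
            lmg_importance(X, np.zeros(50))
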