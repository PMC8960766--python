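"""TMM normalization, moderated testing, and differential GSI calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctsplice import synthetic_data as sd
from ctsplice.differential import (
    DifferentialError,
    ModerationParams,
    delta_gsi_classify,
    fit_moderated_linear_model,
    fit_variance_prior,
    log2fc_expression,
    squeeze_variances,
    tmm_factors,
)


def _tmm_matrices():
    """Three constructed count matrices; the third has 5% inflated genes.

    Expected factors for the third matrix were computed with the standard
    Bioconductor TMM implementation (calcNormFactors, method='TMM') on the
    identical matrix and frozen here.
    """
    rng = np.random.default_rng(42)
    base = rng.negative_binomial(5, 0.02, 500).astype(float) + 1
    m1 = pd.DataFrame({"s1": base, "s2": base}).round().astype(int)
    m2 = pd.DataFrame({"s1": base, "s2": 2 * base}).round().astype(int)
    m3 = pd.DataFrame({"s1": base.copy(), "s2": base.copy()})
    idx = rng.choice(500, 25, replace=False)
    m3.loc[idx, "s2"] = m3.loc[idx, "s2"] * 8
    m3 = m3.round().astype(int)
    return m1, m2, m3


EDGER_M3_FACTORS = (1.1621724564, 0.8604574945)


class TestTMM:
    def test_identical_and_pure_depth_columns_give_unit_factors(self):
        m1, m2, _ = _tmm_matrices()
        assert tmm_factors(m1).tolist() == pytest.approx([1.0, 1.0], abs=1e-9)
        assert tmm_factors(m2).tolist() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_inflated_sample_matches_reference_implementation(self):
        _, _, m3 = _tmm_matrices()
        f = tmm_factors(m3)
        assert f.tolist() == pytest.approx(list(EDGER_M3_FACTORS), abs=1e-6)

    def test_factors_have_geometric_mean_one(self):
        _, _, m3 = _tmm_matrices()
        f = tmm_factors(m3).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DifferentialError, match="2 samples"):
            tmm_factors(pd.DataFrame({"s1": [1, 2, 3]}))
        with pytest.raises(DifferentialError, match="all-zero"):
            tmm_factors(pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}))


def _limma_fixture():
    """300-gene two-condition matrix; moderation results were verified
    against the reference empirical-Bayes implementation (limma lmFit +
    eBayes) on the identical matrix; its prior and first rows are frozen."""
    rng = np.random.default_rng(11)
    n = 300
    base = rng.normal(1.5, 1.0, n)
    eff = np.zeros(n)
    eff[:30] = -0.8
    mat = pd.DataFrame(
        {
            "vehicle_rep1": base + rng.normal(0, 0.1, n),
            "vehicle_rep2": base + rng.normal(0, 0.1, n),
            "treatment_rep1": base + eff + rng.normal(0, 0.1, n),
            "treatment_rep2": base + eff + rng.normal(0, 0.1, n),
        },
        index=[f"g{i}" for i in range(n)],
    )
    design = pd.DataFrame(
        {"sample": mat.columns,
         "condition": ["vehicle"] * 2 + ["treatment"] * 2,
         "replicate": [1, 2, 1, 2]}
    )
    return mat, design


LIMMA_PRIOR_DF = 22.07413998
LIMMA_PRIOR_VAR = 0.00975008
LIMMA_ROWS = {  # gene: (logFC, t, p)
    "g0": (-0.8995143222, -8.928002445, 4.174597867e-09),
    "g1": (-0.7196767284, -7.410007603, 1.168647238e-07),
    "g2": (-0.7377425263, -7.223729036, 1.796263532e-07),
    "g3": (-1.048118035, -9.789622764, 7.205798732e-10),
}


class TestModeratedModel:
    def test_matches_reference_empirical_bayes(self):
        mat, design = _limma_fixture()
        res = fit_moderated_linear_model(mat, design)
        assert res.attrs["prior_df"] == pytest.approx(LIMMA_PRIOR_DF, abs=1e-6)
        assert res.attrs["prior_var"] == pytest.approx(LIMMA_PRIOR_VAR,
                                                       abs=1e-6)
        for gene, (fc, t, p) in LIMMA_ROWS.items():
            assert res.loc[gene, "delta"] == pytest.approx(fc, abs=1e-8)
            assert res.loc[gene, "t_moderated"] == pytest.approx(t, abs=1e-6)
            assert res.loc[gene, "p_value"] == pytest.approx(p, rel=1e-6)

    def test_without_moderation_equals_ordinary_t_test(self):
        mat, design = _limma_fixture()
        res = fit_moderated_linear_model(mat, design, moderate=False)
        gene = "g5"
        t, p = stats.ttest_ind(
            mat.loc[gene, ["treatment_rep1", "treatment_rep2"]],
            mat.loc[gene, ["vehicle_rep1", "vehicle_rep2"]],
            equal_var=True,
        )
        assert res.loc[gene, "t_moderated"] == pytest.approx(t)
        assert res.loc[gene, "p_value"] == pytest.approx(p)

    def test_zero_prior_df_keeps_gene_variances(self):
        s2 = np.array([0.1, 0.5, 2.0])
        out = squeeze_variances(s2, 2.0, ModerationParams(0.0, 1.0))
        assert out == pytest.approx(s2)

    def test_infinite_prior_df_collapses_to_prior_variance(self):
        s2 = np.array([0.1, 0.5, 2.0])
        out = squeeze_variances(s2, 2.0, ModerationParams(np.inf, 0.3))
        assert out == pytest.approx([0.3, 0.3, 0.3])

    def test_prior_fit_recovers_known_hyperparameters(self):
        """Variances drawn from s0^2 * F(d, d0) are re-estimated closely."""
        rng = np.random.default_rng(0)
        d, d0, s0 = 2.0, 10.0, 0.04
        s2 = s0 * rng.f(d, d0, 20000) * 1.0
        prior = fit_variance_prior(s2, d)
        assert prior.prior_df == pytest.approx(d0, rel=0.15)
        assert prior.prior_var == pytest.approx(s0, rel=0.1)

    def test_label_swap_negates_delta_and_preserves_p(self):
        mat, design = _limma_fixture()
        fwd = fit_moderated_linear_model(mat, design,
                                         ("treatment", "vehicle"))
        rev = fit_moderated_linear_model(mat, design,
                                         ("vehicle", "treatment"))
        assert np.allclose(fwd["delta"], -rev["delta"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_null_type_one_error_is_calibrated(self):
        """Identical condition means: p approximately uniform, ~5% below .05."""
        rng = np.random.default_rng(123)
        n = 1000
        mat = pd.DataFrame(
            rng.normal(0, 0.1, (n, 4)),
            columns=["vehicle_rep1", "vehicle_rep2",
                     "treatment_rep1", "treatment_rep2"],
        )
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = fit_moderated_linear_model(mat, design)
        frac = (res["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_single_replicate_rejected(self):
        mat, _ = _limma_fixture()
        design = pd.DataFrame(
            {"sample": mat.columns[:3],
             "condition": ["vehicle", "vehicle", "treatment"],
             "replicate": [1, 2, 1]}
        )
        with pytest.raises(DifferentialError, match="variance"):
            fit_moderated_linear_model(mat, design)


class TestDeltaGSIClassification:
    def test_reported_example_magnitude(self):
        """A gene dropping from GSI 2.21 to 1.11 has dGSI -1.10 and is
        classified decreased when replicates agree."""
        rng = np.random.default_rng(2)
        n = 50
        base = rng.normal(1.5, 0.8, n)
        mat = pd.DataFrame(
            {
                "vehicle_rep1": base + rng.normal(0, 0.02, n),
                "vehicle_rep2": base + rng.normal(0, 0.02, n),
                "treatment_rep1": base + rng.normal(0, 0.02, n),
                "treatment_rep2": base + rng.normal(0, 0.02, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        mat.loc["g0", ["vehicle_rep1", "vehicle_rep2"]] = 2.21
        mat.loc["g0", ["treatment_rep1", "treatment_rep2"]] = 1.11
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = delta_gsi_classify(mat, design)
        assert res.loc["g0", "delta_gsi"] == pytest.approx(-1.10, abs=1e-9)
        assert res.loc["g0", "class"] == "decreased"

    def test_magnitude_cutoff_blocks_small_significant_shifts(self):
        """dGSI = 0.4 stays 'unchanged' no matter how small the p-value."""
        rng = np.random.default_rng(3)
        n = 200
        base = rng.normal(1.0, 0.5, n)
        noise = lambda: rng.normal(0, 0.01, n)
        shift = np.zeros(n)
        shift[0] = 0.4
        mat = pd.DataFrame(
            {
                "vehicle_rep1": base + noise(),
                "vehicle_rep2": base + noise(),
                "treatment_rep1": base + shift + noise(),
                "treatment_rep2": base + shift + noise(),
            }
        )
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = delta_gsi_classify(mat, design)
        assert res.loc[0, "p_value"] < 0.05
        assert abs(res.loc[0, "delta_gsi"]) < 0.5
        assert res.loc[0, "class"] == "unchanged"

    def test_identical_conditions_are_unchanged(self):
        rng = np.random.default_rng(4)
        half = pd.DataFrame(rng.normal(1, 0.5, (100, 2)),
                            columns=["vehicle_rep1", "vehicle_rep2"])
        mat = pd.concat(
            [half, half.rename(columns={"vehicle_rep1": "treatment_rep1",
                                        "vehicle_rep2": "treatment_rep2"})],
            axis=1,
        )
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = delta_gsi_classify(mat, design)
        assert (res["delta_gsi"] == 0).all()
        assert (res["class"] == "unchanged").all()

    def test_classification_counts_invariant_to_row_order(self):
        mat, _, _ = sd.simulate_gsi_matrix(n_genes=500, seed=5)
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        a = delta_gsi_classify(mat, design)["class"].value_counts()
        shuffled = mat.sample(frac=1.0, random_state=0)
        b = delta_gsi_classify(shuffled, design)["class"].value_counts()
        assert a.to_dict() == b.to_dict()

    def test_missing_gsi_rows_are_excluded_and_reported(self):
        mat, design = _limma_fixture()
        mat.loc["g7", "vehicle_rep1"] = np.nan
        res = delta_gsi_classify(mat, design)
        assert "g7" not in res.index
        assert "g7" in res.attrs["excluded"]


class TestExpression:
    def test_doubled_counts_give_log2fc_near_one(self):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(5, 0.8, 400) + 1
        mat = pd.DataFrame(
            {
                "vehicle_rep1": rng.poisson(mu),
                "vehicle_rep2": rng.poisson(mu),
                "treatment_rep1": rng.poisson(mu),
                "treatment_rep2": rng.poisson(mu),
            }
        )
        mat.loc[0, ["treatment_rep1", "treatment_rep2"]] = rng.poisson(
            2 * mu[0], 2)
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = log2fc_expression(mat, design)
        assert res.loc[0, "log2fc"] == pytest.approx(1.0, abs=0.05)

    def test_null_genes_center_at_zero(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(
            rng.poisson(100, (500, 4)),
            columns=["vehicle_rep1", "vehicle_rep2",
                     "treatment_rep1", "treatment_rep2"],
        )
        design = pd.DataFrame(
            {"sample": mat.columns,
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = log2fc_expression(mat, design)
        assert abs(res["log2fc"].mean()) < 0.02
        assert res["log2fc"].abs().median() < 0.15

    def test_true_fold_change_recovered(self):
        """Genes with true FC 4 cluster near log2FC = 2."""
        rng = np.random.default_rng(8)
        n = 500
        mu = rng.lognormal(5, 1, n)
        eff = np.ones(n)
        eff[:50] = 4.0
        cols = {}
        for cond, scale in (("vehicle", np.ones(n)), ("treatment", eff)):
            for rep in (1, 2):
                cols[f"{cond}_rep{rep}"] = rng.poisson(mu * scale)
        mat = pd.DataFrame(cols)
        design = pd.DataFrame(
            {"sample": list(cols),
             "condition": ["vehicle"] * 2 + ["treatment"] * 2,
             "replicate": [1, 2, 1, 2]}
        )
        res = log2fc_expression(mat, design)
        est = res.loc[:49, "log2fc"].median()
        # 10% of genes inflated pulls TMM slightly; estimates stay near 2
        assert est == pytest.approx(2.0, abs=0.2)
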