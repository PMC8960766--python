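"""Two-condition differential analysis of GSI and expression.

Implements the replicated contrast machinery: TMM (trimmed mean of
M-values) between-sample normalization factors for count matrices, an
empirical-Bayes moderated two-group linear model, the differential-GSI
classification rule (|dGSI| >= 0.5 and p < 0.05), and log2 fold changes
of expression.

The moderated model is the standard hierarchical treatment of per-gene
variances: each gene's residual variance s2_g (d residual df) is shrunk
toward a prior s2_0 with d0 prior df estimated from the whole s2
distribution by method of moments on log s2 (scaled-F model), giving

    s2_post = (d0 * s2_0 + d * s2_g) / (d0 + d)

and a moderated t statistic with d + d0 degrees of freedom.  With two
replicates per condition this borrowing of strength across genes is
what makes the test usable at all.  Precision weights (the voom trend)
are deliberately not modelled; classification uses raw p-values with an
informational BH-FDR column, matching the stated cutoff rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


class DifferentialError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _quantile_factor(counts: np.ndarray, lib_size: np.ndarray,
                     p: float = 0.75) -> np.ndarray:
    return np.array([
        np.percentile(counts[:, j], p * 100) / lib_size[j]
        for j in range(counts.shape[1])
    ])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              n_obs: float, n_ref: float,
              log_ratio_trim: float = 0.3,
              sum_trim: float = 0.05,
              do_weighting: bool = True,
              a_cutoff: float = -1e10) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / n_obs / obs + (n_ref - ref) / n_ref / ref
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if len(log_r) == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = math.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & \
           (rank_e >= lo_s) & (rank_e <= hi_s)
    if do_weighting:
        f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    else:
        f = np.nanmean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per sample.

    Follows the standard procedure: the reference sample is the one whose
    75th count-fraction percentile is closest to the mean across samples;
    per-sample factors come from a doubly trimmed (30% on M, 5% on A),
    inverse-variance weighted mean of log ratios against the reference;
    factors are rescaled to geometric mean 1.  Columns are samples.
    """
    counts = count_matrix.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise DifferentialError("need >= 2 samples for TMM")
    if np.any(counts < 0):
        raise DifferentialError("negative counts")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        bad = count_matrix.columns[lib == 0].tolist()
        raise DifferentialError(f"all-zero sample(s): {bad}")
    f75 = _quantile_factor(counts, lib)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref])
        for j in range(counts.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=count_matrix.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


@dataclass
class ModerationParams:
    """Prior df and variance of the hierarchical variance model."""

    prior_df: float
    prior_var: float


def fit_variance_prior(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) from per-gene variances.

    Models s2 ~ s0^2 * F(df, d0); moments of log s2 give closed-form
    estimates via the digamma/trigamma identities.  Genes with
    non-positive variance are excluded from the moment fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise DifferentialError("need >= 2 positive variances to fit prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0 = math.exp(
            e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0 = math.exp(e_mean)
    return ModerationParams(prior_df=d0, prior_var=s0)


def squeeze_variances(
    s2: np.ndarray, df: float, prior: ModerationParams
) -> np.ndarray:
    """Posterior variances shrunk toward the prior."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.prior_df):
        return np.full_like(s2, prior.prior_var)
    return (prior.prior_df * prior.prior_var + df * s2) / (prior.prior_df + df)


def fit_moderated_linear_model(
    values: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("treatment", "vehicle"),
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group moderated test on a genes x samples matrix.

    ``values`` must already be on the log2 scale (GSI, or log2 normalized
    expression).  ``design`` has columns sample/condition; ``contrast``
    is (treatment, reference).  Rows with any missing value across the
    contrasted samples are excluded (reported via the ``excluded``
    attribute on the result).

    Returns a DataFrame indexed like ``values`` (complete rows) with
    delta, t_moderated, p_value, s2, s2_post, df_total.
    """
    treat, ref = contrast
    cols_t = design.loc[design["condition"] == treat, "sample"].tolist()
    cols_r = design.loc[design["condition"] == ref, "sample"].tolist()
    for name, cols in (("treatment", cols_t), ("reference", cols_r)):
        if len(cols) < 2:
            raise DifferentialError(
                f"need >= 2 {name} samples for variance estimation"
            )
    sub = values[cols_t + cols_r]
    complete = sub.dropna()
    n_t, n_r = len(cols_t), len(cols_r)
    df_resid = n_t + n_r - 2
    if df_resid == 0:
        raise DifferentialError("zero residual degrees of freedom")
    yt = complete[cols_t].to_numpy(dtype=float)
    yr = complete[cols_r].to_numpy(dtype=float)
    delta = yt.mean(axis=1) - yr.mean(axis=1)
    ss = ((yt - yt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((yr - yr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if moderate:
        prior = fit_variance_prior(s2, df_resid)
        s2_post = squeeze_variances(s2, df_resid, prior)
        df_total = df_resid + prior.prior_df
    else:
        prior = ModerationParams(prior_df=0.0, prior_var=float("nan"))
        s2_post = s2
        df_total = float(df_resid)
    se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "delta": delta,
            "t_moderated": t,
            "p_value": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
        },
        index=complete.index,
    )
    out.attrs["excluded"] = sorted(set(sub.index) - set(complete.index))
    out.attrs["prior_df"] = prior.prior_df
    out.attrs["prior_var"] = prior.prior_var
    return out


# ---------------------------------------------------------------------------
# Differential GSI and expression
# ---------------------------------------------------------------------------

def _bh_fdr(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0, 1)
    return out


def classify(delta: float, p: float, delta_cutoff: float,
             p_cutoff: float) -> str:
    if p < p_cutoff and delta >= delta_cutoff:
        return "increased"
    if p < p_cutoff and delta <= -delta_cutoff:
        return "decreased"
    return "unchanged"


def delta_gsi_classify(
    gsi_matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("treatment", "vehicle"),
    delta_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Differential GSI with the magnitude + significance rule.

    The matrix holds per-sample GSI on the log2 scale; the test is run
    on linear values re-logged inside the model (mathematically the GSI
    values themselves), dGSI is the difference of condition means, and a
    gene is called increased/decreased only when |dGSI| meets
    ``delta_cutoff`` and the moderated p-value is below ``p_cutoff``.
    An FDR column is included for information and plays no role in
    classification.  Genes missing GSI in any contrasted sample are
    excluded (listed in ``result.attrs['excluded']``).
    """
    res = fit_moderated_linear_model(gsi_matrix, design, contrast)
    res = res.rename(columns={"delta": "delta_gsi"})
    res["fdr"] = _bh_fdr(res["p_value"].to_numpy())
    res["class"] = [
        classify(d, p, delta_cutoff, p_cutoff)
        for d, p in zip(res["delta_gsi"], res["p_value"])
    ]
    return res


def log2fc_expression(
    count_matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str] = ("treatment", "vehicle"),
    pseudocount: float = 0.5,
    delta_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Moderated log2 fold change of TMM-normalized expression counts.

    Counts are normalized by effective library size (library size x TMM
    factor), stabilised with a small pseudocount, log2-transformed, and
    passed through the same moderated two-group machinery as dGSI.
    """
    factors = tmm_factors(count_matrix)
    lib = count_matrix.sum(axis=0)
    eff = lib * factors
    log_norm = np.log2(
        (count_matrix + pseudocount) / eff.to_numpy()[None, :] * 1e6
    )
    res = fit_moderated_linear_model(log_norm, design, contrast)
    res = res.rename(columns={"delta": "log2fc"})
    res["fdr"] = _bh_fdr(res["p_value"].to_numpy())
    res["class"] = [
        classify(d, p, delta_cutoff, p_cutoff)
        for d, p in zip(res["log2fc"], res["p_value"])
    ]
    return res
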