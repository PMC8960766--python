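"""Decile machinery, the L x E matrix, and the GSI structural regression.

The central descriptive device is a 10 x 10 grid of gene-length deciles
(L, rows) by pre-mRNA-expression deciles (E, columns): each cell holds
the mean of a chosen per-gene statistic (GSI, splice-site strength, GC
ratio) over the genes falling in that length/expression bin, together
with a count matrix.  A finite-difference gradient field on the grid
shows along which axis the statistic varies fastest.

The explanatory model is an ordinary least squares regression of GSI on
structural predictors (log2 gene length, log2 pre-mRNA level, intron
number, donor/acceptor site strength, exon/intron GC ratio), reported
with the Pearson correlation of predicted vs observed GSI, total R2,
and an LMG relative-importance decomposition: each predictor's share of
R2 averaged over all orders in which predictors could enter the model,
computed exactly by subset enumeration.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class MatrixModelError(ValueError):
    pass


def assign_deciles(values, n_bins: int = 10) -> pd.Series:
    """Rank-based split of a numeric vector into near-equal deciles (1..10).

    Ties are broken by stable input order, so decile sizes always differ
    by at most one.  Degenerate (all-equal) input triggers a warning but
    is still split by order.
    """
    s = pd.Series(values).astype(float)
    defined = s.dropna()
    if len(defined) < n_bins:
        raise MatrixModelError(
            f"need >= {n_bins} defined values, got {len(defined)}"
        )
    if defined.nunique() == 1:
        warnings.warn("degenerate decile input: all values equal")
    ranks = defined.rank(method="first")
    labels = np.ceil(ranks * n_bins / len(defined)).astype(int).clip(1, n_bins)
    out = pd.Series(np.nan, index=s.index, dtype=float)
    out[defined.index] = labels
    return out.astype("Int64")


@dataclass
class LEMatrix:
    """10x10 cell means + counts of a per-gene statistic over (L, E) deciles."""

    stat: str
    means: pd.DataFrame            # index = length decile, columns = expression decile
    counts: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = self.means.stack(future_stack=True).rename("mean").reset_index()
        long.columns = ["L_decile", "E_decile", "mean"]
        long["n"] = self.counts.stack(future_stack=True).to_numpy()
        long["stat"] = self.stat
        return long


def build_le_matrix(
    genes: pd.DataFrame,
    stat: str,
    length_column: str = "gene_length",
    expression_column: str = "premrna_rpkm",
) -> LEMatrix:
    """Cell-wise means of ``stat`` over length x expression deciles.

    Deciles are rank-based, so any monotone transform of length or
    expression yields the same assignment.  Empty cells are NaN in the
    mean matrix and 0 in the count matrix.
    """
    df = genes.dropna(subset=[stat, length_column, expression_column]).copy()
    df["L_decile"] = assign_deciles(df[length_column])
    df["E_decile"] = assign_deciles(df[expression_column])
    means = pd.DataFrame(np.nan, index=pd.RangeIndex(1, 11),
                         columns=pd.RangeIndex(1, 11))
    counts = pd.DataFrame(0, index=pd.RangeIndex(1, 11),
                          columns=pd.RangeIndex(1, 11))
    grouped = df.groupby(["L_decile", "E_decile"], observed=True)[stat]
    for (li, ej), vals in grouped:
        means.loc[li, ej] = vals.mean()
        counts.loc[li, ej] = len(vals)
    means.index.name = counts.index.name = "L_decile"
    means.columns.name = counts.columns.name = "E_decile"
    return LEMatrix(stat=stat, means=means, counts=counts)


def gradient_field(matrix: LEMatrix | pd.DataFrame) -> pd.DataFrame:
    """Finite-difference gradient of the L x E cell means on interior cells.

    Central differences with unit decile spacing along each axis for
    cells with both neighbours defined; one-sided difference (flagged)
    when one neighbour is missing.  Returns rows (L_decile, E_decile,
    dL, dE, magnitude, one_sided).
    """
    means = matrix.means if isinstance(matrix, LEMatrix) else matrix
    m = means.to_numpy(dtype=float)
    n_rows, n_cols = m.shape
    rows = []
    for i in range(1, n_rows - 1):
        for j in range(1, n_cols - 1):
            if math.isnan(m[i, j]):
                continue

            def diff(lo: float, hi: float) -> tuple[float, bool]:
                has_lo, has_hi = not math.isnan(lo), not math.isnan(hi)
                if has_lo and has_hi:
                    return (hi - lo) / 2.0, False
                if has_hi:
                    return hi - m[i, j], True
                if has_lo:
                    return m[i, j] - lo, True
                return math.nan, True

            dL, one_l = diff(m[i - 1, j], m[i + 1, j])
            dE, one_e = diff(m[i, j - 1], m[i, j + 1])
            if math.isnan(dL) or math.isnan(dE):
                continue
            rows.append(
                {
                    "L_decile": means.index[i],
                    "E_decile": means.columns[j],
                    "dL": dL,
                    "dE": dE,
                    "magnitude": math.hypot(dL, dE),
                    "one_sided": one_l or one_e,
                }
            )
    if not rows:
        raise MatrixModelError("no defined interior cells for gradient")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regression of GSI on structural features
# ---------------------------------------------------------------------------

DEFAULT_PREDICTORS = (
    "log2_gene_length",
    "log2_premrna_rpkm",
    "n_introns",
    "mean_5ss",
    "mean_3ss",
    "gc_ratio",
)


def prepare_regression_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Add the log2-transformed predictor columns the regression uses.

    Gene length and expression span orders of magnitude; they enter the
    model on the log2 scale (deciles are rank-based and unaffected).
    """
    out = genes.copy()
    out["log2_gene_length"] = np.log2(out["gene_length"].astype(float))
    with np.errstate(divide="ignore"):
        out["log2_premrna_rpkm"] = np.log2(out["premrna_rpkm"].astype(float))
    out.loc[~np.isfinite(out["log2_premrna_rpkm"]), "log2_premrna_rpkm"] = np.nan
    return out


def _r_squared(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    """R2 of OLS (with intercept) on the selected predictor columns."""
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    if not cols:
        return 0.0
    design = np.column_stack([np.ones(n), X[:, cols]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ beta) ** 2).sum())
    return 1.0 - rss / tss


def lmg_importance(X: pd.DataFrame, y) -> pd.Series:
    """Exact LMG decomposition of regression R2 over predictors.

    Each predictor's importance is its average increment to R2 over all
    orderings of the predictors (equivalently a Shapley value on the R2
    game), enumerated over all 2^p subsets.  Importances are >= 0 up to
    numerical noise and sum to the full-model R2.
    """
    names = list(X.columns)
    p = len(names)
    if p > 10:
        raise MatrixModelError(
            f"{p} predictors: exact LMG enumerates 2^p subsets, limit is 10; "
            "reduce the predictor set"
        )
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    cache: dict[tuple[int, ...], float] = {}

    def r2(cols: tuple[int, ...]) -> float:
        if cols not in cache:
            cache[cols] = _r_squared(Xa, ya, cols)
        return cache[cols]

    fact = [math.factorial(i) for i in range(p + 1)]
    importance = np.zeros(p)
    others = list(range(p))
    for k in range(p):
        rest = [c for c in others if c != k]
        for size in range(p):
            weight = fact[size] * fact[p - size - 1] / fact[p]
            for subset in itertools.combinations(rest, size):
                gain = r2(tuple(sorted(subset + (k,)))) - r2(subset)
                importance[k] += weight * gain
    return pd.Series(importance, index=names, name="lmg_importance")


@dataclass
class RegressionFit:
    """OLS fit of GSI on structural predictors, with LMG importances."""

    predictors: list[str]
    coefficients: pd.Series            # includes 'intercept'
    predicted: pd.Series
    observed: pd.Series
    pearson_r: float
    r_squared: float
    importance: pd.Series
    n_used: int
    n_dropped: int


class GSIRegression:
    """Least-squares model of GSI on structural gene features.

    Follows the fit/attributes convention: ``fit`` stores trailing-
    underscore attributes (``coef_``, ``r_squared_``, ``importance_``)
    and returns self; ``predict`` maps a feature table to predicted GSI.
    Complete-case analysis: genes missing any predictor or the response
    are dropped (counts recorded).
    """

    def __init__(self, predictors=DEFAULT_PREDICTORS, response: str = "gsi"):
        self.predictors = list(predictors)
        self.response = response

    def fit(self, table: pd.DataFrame) -> "GSIRegression":
        cols = self.predictors + [self.response]
        complete = table.dropna(subset=cols)
        self.n_used_ = len(complete)
        self.n_dropped_ = len(table) - len(complete)
        if self.n_used_ <= len(self.predictors) + 1:
            raise MatrixModelError(
                f"only {self.n_used_} complete cases for "
                f"{len(self.predictors)} predictors"
            )
        X = complete[self.predictors].to_numpy(dtype=float)
        y = complete[self.response].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(y)), X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            corr = np.corrcoef(X, rowvar=False)
            pairs = [
                (self.predictors[a], self.predictors[b])
                for a in range(len(self.predictors))
                for b in range(a + 1, len(self.predictors))
                if abs(corr[a, b]) > 1 - 1e-10
            ]
            raise MatrixModelError(
                f"rank-deficient design (rank {rank} < {design.shape[1]}); "
                f"collinear predictors: {pairs or 'unidentified'}"
            )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ beta
        self.coef_ = pd.Series(beta, index=["intercept"] + self.predictors)
        self.predicted_ = pd.Series(fitted, index=complete.index)
        self.observed_ = pd.Series(y, index=complete.index)
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float(((y - fitted) ** 2).sum())
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else 0.0
        self.pearson_r_ = (
            float(stats.pearsonr(fitted, y).statistic) if tss > 0 else math.nan
        )
        self.importance_ = lmg_importance(complete[self.predictors], y)
        return self

    def predict(self, table: pd.DataFrame) -> pd.Series:
        X = table[self.predictors].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(X)), X])
        return pd.Series(design @ self.coef_.to_numpy(), index=table.index)

    def get_params(self, deep: bool = True) -> dict:
        return {"predictors": list(self.predictors), "response": self.response}

    def set_params(self, **params) -> "GSIRegression":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def to_fit(self) -> RegressionFit:
        return RegressionFit(
            predictors=list(self.predictors),
            coefficients=self.coef_,
            predicted=self.predicted_,
            observed=self.observed_,
            pearson_r=self.pearson_r_,
            r_squared=self.r_squared_,
            importance=self.importance_,
            n_used=self.n_used_,
            n_dropped=self.n_dropped_,
        )


def fit_gsi_regression(
    table: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    response: str = "gsi",
) -> RegressionFit:
    """OLS of GSI on the chosen predictors (complete cases).

    Thin functional wrapper over :class:`GSIRegression`.
    """
    return GSIRegression(predictors=predictors, response=response).fit(table).to_fit()


def relative_importance(fit: RegressionFit, table: pd.DataFrame) -> pd.Series:
    """Recompute the LMG percentage-of-variance decomposition for a fit."""
    complete = table.dropna(subset=fit.predictors + ["gsi"])
    return lmg_importance(complete[fit.predictors], complete["gsi"].to_numpy())


def progressive_subset_sweep(
    table: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    response: str = "gsi",
) -> pd.DataFrame:
    """Forward sweep: add the predictor with the largest R2 gain each step.

    Mirrors the reported model-building strategy of fitting models with
    increasing numbers of structural variables; returns one row per step
    with the predictor added, cumulative R2 and Pearson r.
    """
    complete = table.dropna(subset=list(predictors) + [response])
    X = complete[list(predictors)]
    y = complete[response].to_numpy(dtype=float)
    chosen: list[str] = []
    remaining = list(predictors)
    rows = []
    while remaining:
        best, best_r2 = None, -np.inf
        for cand in remaining:
            cols = tuple(
                sorted(X.columns.get_loc(c) for c in chosen + [cand])
            )
            r2 = _r_squared(X.to_numpy(dtype=float), y, cols)
            if r2 > best_r2:
                best, best_r2 = cand, r2
        chosen.append(best)
        remaining.remove(best)
        rows.append(
            {"step": len(chosen), "added": best, "predictors": tuple(chosen),
             "r_squared": best_r2, "pearson_r": math.sqrt(max(best_r2, 0.0))}
        )
    return pd.DataFrame(rows)


def stratify_by_length(
    table: pd.DataFrame, which: str, length_column: str = "gene_length"
) -> pd.DataFrame:
    """Gene subsets by length decile: 'short' = deciles 1-2, 'long' = 9-10."""
    dec = assign_deciles(table[length_column])
    if which == "short":
        mask = dec.isin([1, 2])
    elif which == "long":
        mask = dec.isin([9, 10])
    else:
        raise MatrixModelError("which must be 'short' or 'long'")
    return table.loc[mask.fillna(False)].copy()
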