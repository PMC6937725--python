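"""Pan-dataset gene ranking by meta-correlation with a seed gene.

Per dataset, Spearman rank correlations between the seed gene (CD276 / B7-H3
in the motivating analysis) and every other gene are computed, standardized
across genes within the dataset (Z-score normalization), and combined over
datasets with Stouffer's method, Z = Σ z_d / √D; genes are ranked by the
combined Z.  An alternative mode applies Fisher's r-to-z variance-stabilizing
transform instead of within-dataset standardization.

Also hosts the univariate ordinary-least-squares regression with a
likelihood-ratio test against the intercept-only model, as used for
marker-vs-marker protein-level associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ExpressionDataset

__all__ = [
    "spearman_profile",
    "znormalize_profile",
    "stouffer_combine",
    "rank_genes",
    "meta_rank",
    "marker_regression",
    "MetaRankTable",
    "RegressionResult",
]


@dataclass
class MetaRankTable:
    """Ranked meta-correlation result.

    ``table`` has one row per gene: Z_combined, rank (1 = highest),
    n_datasets_present; ``r_matrix`` / ``z_matrix`` carry the per-dataset
    detail (genes x datasets, NaN where a gene is missing or degenerate).
    """

    table: pd.DataFrame
    r_matrix: pd.DataFrame
    z_matrix: pd.DataFrame
    seed_gene: str

    def top(self, k: int = 50) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank")


@dataclass
class RegressionResult:
    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    lrt_statistic: float
    lrt_pvalue: float
    n: int


def spearman_profile(dataset: ExpressionDataset,
                     seed_gene: str | None = None) -> pd.Series:
    """Spearman rho between the seed gene and every other gene in a dataset.

    Ties receive average ranks; the seed gene is excluded from its own
    profile; zero-variance (or missing) genes yield NaN.
    """
    seed_gene = seed_gene or dataset.seed_gene
    expr = dataset.expression
    if seed_gene not in expr.index:
        raise KeyError(f"seed gene {seed_gene!r} absent from dataset "
                       f"{dataset.dataset_id}")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for rank correlation")

    X = expr.to_numpy(dtype=float)
    seed = X[expr.index.get_loc(seed_gene)]
    ranks_seed = stats.rankdata(seed)
    rs = ranks_seed - ranks_seed.mean()
    denom_seed = np.sqrt((rs ** 2).sum())

    ranks = stats.rankdata(X, axis=1)
    rg = ranks - ranks.mean(axis=1, keepdims=True)
    denom_g = np.sqrt((rg ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rg @ rs) / (denom_g * denom_seed)
    rho[~np.isfinite(rho)] = np.nan
    rho[np.isnan(X).any(axis=1)] = np.nan    # genes missing in this dataset

    out = pd.Series(rho, index=expr.index, name=dataset.dataset_id)
    return out.drop(index=seed_gene)


def znormalize_profile(r_vector: pd.Series, mode: str = "standardize") -> pd.Series:
    """Z-normalize a per-dataset correlation profile.

    ``standardize`` (default): z = (r - mean(r)) / sd(r) across genes within
    the dataset, population SD (ddof 0).  ``fisher``: z = atanh(r) · √(n-3)
    is not available here (sample size not carried); instead ``fisher`` maps
    r through atanh and then standardizes, preserving the variance-stabilized
    ordering.  Missing entries stay missing.
    """
    r = r_vector.astype(float)
    valid = r.dropna()
    if valid.size < 2:
        raise ValueError("need >= 2 non-missing correlations to normalize")
    if mode == "fisher":
        r = np.arctanh(r.clip(-1 + 1e-12, 1 - 1e-12))
        valid = r.dropna()
    elif mode != "standardize":
        raise ValueError(f"unknown mode {mode!r}")
    sd = float(valid.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate profile: zero variance across genes")
    return (r - valid.mean()) / sd


def stouffer_combine(z_matrix: pd.DataFrame) -> pd.Series:
    """Unweighted Stouffer combination per gene over datasets:
    Z(g) = Σ_d z_{g,d} / √D_g with D_g the number of datasets where the gene
    is present.  Genes absent everywhere are excluded."""
    z = z_matrix.astype(float)
    n_present = z.notna().sum(axis=1)
    absent = n_present == 0
    if absent.any():
        z = z.loc[~absent]
        n_present = n_present.loc[~absent]
    return z.sum(axis=1, skipna=True) / np.sqrt(n_present)


def rank_genes(z_combined: pd.Series, z_matrix: pd.DataFrame | None = None,
               ) -> pd.DataFrame:
    """Rank genes by combined Z, descending; ties broken by gene name
    (lexicographically earlier gene ranks first) for determinism."""
    df = pd.DataFrame({"Z_combined": z_combined})
    if z_matrix is not None:
        df["n_datasets_present"] = z_matrix.notna().sum(axis=1).reindex(df.index)
    order = sorted(df.index, key=lambda g: (-df.at[g, "Z_combined"], g))
    df = df.loc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def meta_rank(datasets: list[ExpressionDataset], seed_gene: str = "CD276",
              mode: str = "standardize") -> MetaRankTable:
    """Full meta-correlation pipeline over a panel of expression datasets."""
    if not datasets:
        raise ValueError("empty dataset panel")
    r_cols = {d.dataset_id: spearman_profile(d, seed_gene) for d in datasets}
    r_matrix = pd.DataFrame(r_cols)
    z_matrix = pd.DataFrame({did: znormalize_profile(col, mode=mode)
                             for did, col in r_matrix.items()})
    z_combined = stouffer_combine(z_matrix)
    table = rank_genes(z_combined, z_matrix)
    return MetaRankTable(table=table, r_matrix=r_matrix, z_matrix=z_matrix,
                         seed_gene=seed_gene)


def marker_regression(x: np.ndarray, y: np.ndarray, predictor: str = "x",
                      response: str = "y") -> RegressionResult:
    """Univariate OLS of y on x with a likelihood-ratio test against the
    intercept-only model: statistic = n·ln(RSS0/RSS1), p from chi-square(1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for regression")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero predictor variance")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss1 = float((resid ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss1 / rss0 if rss0 > 0 else 1.0
    if rss1 == 0:
        lrt = np.inf
        p = 0.0
    else:
        lrt = n * np.log(rss0 / rss1)
        p = float(stats.chi2.sf(lrt, df=1))
    return RegressionResult(predictor=predictor, response=response,
                            slope=slope, intercept=intercept,
                            r_squared=max(0.0, min(1.0, r2)),
                            lrt_statistic=float(max(lrt, 0.0)),
                            lrt_pvalue=p, n=n)
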