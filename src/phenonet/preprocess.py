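"""Count-matrix preprocessing: filtering, normalization, unwanted-variation
removal, and variance stabilization.

The stages mirror a standard bulk RNA-seq / small-RNA-seq pipeline for
whole-blood cohorts: drop features with extreme single-sample reads
(hemolysis-type outliers), drop absent and low-variance features, scale
libraries to a common upper quartile, remove residual-derived unwanted
variation factors, and variance-stabilize the corrected counts so that
downstream correlation-based analyses see homoscedastic data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import design_matrix

__all__ = [
    "FilterParams",
    "FILTER_PRESETS",
    "remove_outlier_features",
    "filter_features",
    "exclude_samples",
    "upper_quartile_normalize",
    "ruvr_correct",
    "estimate_dispersion",
    "vst",
]


@dataclass(frozen=True)
class FilterParams:
    """Feature-filter thresholds.

    A feature is kept iff it has strictly more than ``min_count`` reads in at
    least ``min_samples`` samples and a sample standard deviation of at least
    ``min_sd``.  ``max_single_read`` (if set) removes features with any single
    sample count above it before the expression filter.
    """

    min_count: int = 10
    min_samples: int = 200
    min_sd: float = 10.0
    max_single_read: int | None = 5_000_000


#: Named presets carrying the whole-blood cohort thresholds: miRNAs need
#: >10 reads in >=200 subjects and SD>=10; genes need >10 reads in >=500
#: samples and SD>=30 (after protein-coding subsetting, which is here an
#: optional user-supplied whitelist).
FILTER_PRESETS: dict[str, FilterParams] = {
    "mirna-copdgene": FilterParams(10, 200, 10.0, 5_000_000),
    "mrna-copdgene": FilterParams(10, 500, 30.0, None),
}


def remove_outlier_features(counts: pd.DataFrame, max_single_read: int) -> pd.DataFrame:
    """Drop features with any single sample count above ``max_single_read``."""
    if max_single_read <= 0:
        raise ValueError("max_single_read must be positive")
    if counts.shape[1] == 0:
        return counts.copy()
    keep = (counts.to_numpy() <= max_single_read).all(axis=1)
    return counts.loc[keep]


def filter_features(counts: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Apply the expressed/variable feature filter; preserves feature order."""
    n_samples = counts.shape[1]
    if params.min_samples > n_samples:
        warnings.warn(
            f"min_samples={params.min_samples} exceeds n_samples={n_samples}; "
            "no feature can pass"
        )
        return counts.iloc[:0]
    x = counts.to_numpy(dtype=float)
    expressed = (x > params.min_count).sum(axis=1) >= params.min_samples
    sd = x.std(axis=1, ddof=1) if n_samples > 1 else np.zeros(len(counts))
    return counts.loc[expressed & (sd >= params.min_sd)]


def exclude_samples(
    counts: pd.DataFrame,
    exclude: list[str] | None = None,
    min_total_reads: int = 200_000,
) -> pd.DataFrame:
    """Drop listed samples plus any with library size below ``min_total_reads``.

    Stands in for the cohort's manual removals (bad batches, missing
    clinical data) plus the low-depth rule.
    """
    out = counts.drop(columns=list(exclude or []), errors="ignore")
    keep = out.sum(axis=0) >= min_total_reads
    return out.loc[:, keep]


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by its upper quartile of nonzero counts.

    The per-sample 75th percentile (linear interpolation between order
    statistics, computed on nonzero counts only) is divided by the geometric
    mean of those percentiles across samples, and the sample's counts are
    divided by that factor.  Within-sample value ordering is preserved, and
    the normalized upper quartiles agree across samples.
    """
    x = counts.to_numpy(dtype=float)
    q = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        nz = x[:, j][x[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has all-zero counts")
        q[j] = np.percentile(nz, 75)
    factors = q / np.exp(np.mean(np.log(q)))
    return pd.DataFrame(x / factors, index=counts.index, columns=counts.columns)


def ruvr_correct(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    k: int = 1,
    covariate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Remove unwanted variation estimated from regression residuals.

    Per-feature least-squares regressions of the (log-scale) expression on
    the known design produce a residual matrix; its top-``k`` singular
    factors over samples are taken as unwanted-variation covariates, and
    their fitted contribution is subtracted from the expression.  This is a
    deterministic least-squares rendering of residual-based unwanted
    variation removal (the canonical formulation fits a negative-binomial
    GLM; the residual-factor logic is identical).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return expr.copy()
    n = expr.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    X = design_matrix(design, covariate_columns or list(design.columns))
    X = X.loc[expr.columns].to_numpy()
    Yt = expr.to_numpy().T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Yt, rcond=None)
    resid = Yt - X @ beta
    # unwanted factors = top-k left singular vectors of the residuals over samples
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    W = u[:, :k] * s[:k]
    full = np.column_stack([X, W])
    coef, *_ = np.linalg.lstsq(full, Yt, rcond=None)
    corrected = Yt - W @ coef[X.shape[1] :]
    return pd.DataFrame(corrected.T, index=expr.index, columns=expr.columns)


def estimate_dispersion(values: pd.DataFrame | np.ndarray) -> float:
    """Moment estimate of a common NB dispersion alpha across features.

    Least-squares fit of the quadratic mean-variance relation
    ``Var = mu + alpha * mu^2`` over features; clipped to a small positive
    floor so the transform stays defined for near-Poisson data.
    """
    x = np.asarray(values, dtype=float)
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    denom = float(np.sum(m**4))
    alpha = float(np.sum((v - m) * m**2) / denom) if denom > 0 else 0.0
    return max(alpha, 1e-8)


def vst(
    values: pd.DataFrame, dispersion: float | None = None
) -> pd.DataFrame:
    """Closed-form NB variance-stabilizing transform.

    Applies ``x -> (2/sqrt(alpha)) * asinh(sqrt(alpha * x))`` with ``alpha``
    the NB dispersion (moment-estimated across features when not supplied).
    Strictly increasing in x, vst(0)=0, and it approaches ``2*sqrt(x)`` as
    alpha -> 0.
    """
    x = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("vst requires nonnegative values")
    alpha = estimate_dispersion(x) if dispersion is None else float(dispersion)
    if alpha <= 0:
        raise ValueError("dispersion must be positive")
    out = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out
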