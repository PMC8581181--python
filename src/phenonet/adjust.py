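"""Covariate residualization regimes for omics matrices and phenotypes.

Three regimes are supported, mirroring the usual question of how much
clinical structure to regress out of blood expression data before network
integration:

* ``none`` — standardize only.
* ``partial`` — residualize omics on sex, age, race.  A lung-function
  phenotype that is already expressed as percent-of-predicted (and hence
  already adjusted for sex, age and race) is left untouched; an imaging
  phenotype is additionally adjusted for scanner model.
* ``full`` — partial plus current smoking status and white-blood-cell
  percentages.

Residualization is per-row ordinary least squares with an intercept;
residuals are exactly orthogonal to each predictor column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentRegime",
    "REGIMES",
    "design_matrix",
    "residualize",
    "standardize_features",
    "standardize_phenotype",
    "apply_regime",
]

#: WBC percentage columns entering design matrices.  The eosinophil percent
#: is omitted: the three percentages are compositional (they sum to ~100),
#: so including all three alongside an intercept is exactly collinear.
WBC = ["wbc_neutrophil", "wbc_lymphocyte"]


@dataclass(frozen=True)
class AdjustmentRegime:
    name: str
    omics_covariates: tuple[str, ...]
    # phenotype name -> covariates regressed out of that phenotype
    phenotype_covariates: dict = field(default_factory=dict)


REGIMES: dict[str, AdjustmentRegime] = {
    "none": AdjustmentRegime("none", (), {}),
    "partial": AdjustmentRegime(
        "partial",
        ("sex", "age", "race"),
        {
            # percent-of-predicted FEV1 already accounts for sex/age/race
            "fev1pp": [],
            "pct_emphysema": ["sex", "age", "race", "scanner"],
            "synthetic": ["sex", "age", "race"],
        },
    ),
    "full": AdjustmentRegime(
        "full",
        ("sex", "age", "race", "smoking", *WBC),
        {
            "fev1pp": ["smoking", *WBC],
            "pct_emphysema": ["sex", "age", "race", "scanner", "smoking", *WBC],
            "synthetic": ["sex", "age", "race", "smoking", *WBC],
        },
    ),
}


def design_matrix(covariates: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Intercept + named covariates, one-hot coding categoricals.

    Categorical columns are dummy-coded dropping the first of the sorted
    levels, so the coding is deterministic.
    """
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise KeyError(f"unknown covariate columns: {missing}")
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for c in columns:
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                parts.append(
                    (col.astype(str) == lev).astype(float).rename(f"{c}[{lev}]")
                )
        else:
            parts.append(col.astype(float).rename(c))
    X = pd.concat(parts, axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear among columns {list(X.columns)}"
        )
    return X


def residualize(
    data: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
    columns: list[str],
) -> pd.DataFrame | pd.Series:
    """OLS residuals of each feature (row) or of a phenotype on covariates.

    An empty column list centers the data (intercept-only fit).  Samples
    with missing covariate values are dropped with a warning.
    """
    is_series = isinstance(data, pd.Series)
    mat = data.to_frame().T if is_series else data
    cov = covariates.loc[mat.columns]
    ok = cov[columns].notna().all(axis=1) if columns else pd.Series(True, index=cov.index)
    if not ok.all():
        warnings.warn(f"dropping {(~ok).sum()} samples with missing covariates")
        mat = mat.loc[:, ok]
        cov = cov.loc[ok]
    X = design_matrix(cov, columns).to_numpy()
    Yt = mat.to_numpy(dtype=float).T
    beta, *_ = np.linalg.lstsq(X, Yt, rcond=None)
    resid = Yt - X @ beta
    out = pd.DataFrame(resid.T, index=mat.index, columns=mat.columns)
    return out.iloc[0] if is_series else out


def standardize_features(expr: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each feature row to mean 0, sd 1 (ddof=1)."""
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns)


def standardize_phenotype(y: pd.Series) -> pd.Series:
    sd = y.std(ddof=1)
    return (y - y.mean()) / (sd if sd > 0 else 1.0)


def apply_regime(
    mrna: pd.DataFrame,
    mirna: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    regime: str | AdjustmentRegime,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Adjust both omics blocks and the phenotype under one named regime.

    Omics features are residualized on the regime's covariates and then
    standardized; the phenotype is residualized on its phenotype-specific
    covariate list and re-centered/scaled afterwards.
    """
    if isinstance(regime, str):
        if regime not in REGIMES:
            raise KeyError(f"unknown regime {regime!r}")
        regime = REGIMES[regime]
    name = phenotype.name or "synthetic"
    if regime.name != "none" and name not in regime.phenotype_covariates:
        raise KeyError(f"unknown phenotype name {name!r} for regime {regime.name}")
    cols = list(regime.omics_covariates)
    if cols:
        mrna = residualize(mrna, covariates, cols)
        mirna = residualize(mirna, covariates, cols)
    pheno_cols = regime.phenotype_covariates.get(name, [])
    if pheno_cols:
        phenotype = residualize(phenotype, covariates, pheno_cols)
    return (
        standardize_features(mrna),
        standardize_features(mirna),
        standardize_phenotype(phenotype).rename(name),
    )
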