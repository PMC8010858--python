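"""Polygenic-score prediction with covariates and incremental R^2.

The PGS regression follows the standard design for family samples: the
phenotype is regressed on the standardized score plus age, age^2, sex,
genotyping platform and ten genetic principal components; the p-value
comes from a family-clustered GEE fit, while the incremental explained
variance is the nested-model R^2 difference from companion least-squares
fits on complete cases.  Significance uses the multiple-testing-corrected
threshold p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import gee_fit

__all__ = ["PGSRegressionResult", "pgs_regression", "select_best_variant", "ALPHA"]

ALPHA = 0.001  # Bonferroni-corrected significance threshold


@dataclass
class PGSRegressionResult:
    coefficient: float
    se: float
    pvalue: float
    delta_r2: float  # incremental explained variance of the PGS
    covariates: list[str]
    significant: bool
    n_obs: int
    n_clusters: int


def _build_covariates(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design block; categorical columns are dummy-coded against a
    reference level."""
    blocks, names = [], []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns)
        else:
            blocks.append(np.asarray(s, float)[:, None])
            names.append(col)
    return np.column_stack(blocks) if blocks else np.empty((len(covariates), 0)), names


def pgs_regression(
    phenotype,
    pgs,
    covariates: pd.DataFrame | None,
    clusters,
) -> PGSRegressionResult:
    """Test whether a polygenic score predicts a phenotype.

    Returns the GEE coefficient with robust SE and p-value, and the
    incremental R^2 of the score over the covariates (nested OLS fits on
    complete cases; point estimates ignore clustering, inference does
    not).
    """
    phenotype = np.asarray(phenotype, float)
    pgs = np.asarray(pgs, float)
    if np.nanstd(pgs) == 0:
        raise ValueError("constant PGS")
    n = len(phenotype)
    if covariates is None:
        covariates = pd.DataFrame(index=range(n))
    cov_block, cov_names = _build_covariates(covariates.reset_index(drop=True))
    clusters = np.asarray(clusters)
    complete = (
        np.isfinite(phenotype) & np.isfinite(pgs) & np.all(np.isfinite(cov_block), axis=1)
    )
    y, s, c, cl = phenotype[complete], pgs[complete], cov_block[complete], clusters[complete]
    x_full = np.column_stack([np.ones(len(y)), c, s])
    names = ["const", *cov_names, "pgs"]
    fit = gee_fit(y, x_full, cl, names=names)

    x_base = np.column_stack([np.ones(len(y)), c])
    r2_base = sm.OLS(y, x_base).fit().rsquared
    r2_full = sm.OLS(y, x_full).fit().rsquared
    delta_r2 = max(0.0, r2_full - r2_base)

    p = float(fit.pvalues["pgs"])
    return PGSRegressionResult(
        coefficient=float(fit.params["pgs"]),
        se=float(fit.se["pgs"]),
        pvalue=p,
        delta_r2=float(delta_r2),
        covariates=names[1:-1],
        significant=p < ALPHA,
        n_obs=int(len(y)),
        n_clusters=int(len(np.unique(cl))),
    )


def select_best_variant(
    phenotype,
    pgs_variants: pd.DataFrame,
    covariates: pd.DataFrame | None,
    clusters,
) -> tuple[str, pd.DataFrame]:
    """Pick the causal-fraction PGS variant maximizing incremental R^2.

    ``pgs_variants`` holds one column per variant (e.g. labeled by the
    assumed fraction of causal variants).  Returns the chosen label plus
    the per-variant results table.
    """
    if pgs_variants.shape[1] < 1:
        raise ValueError("need at least one PGS variant column")
    rows = []
    for label in pgs_variants.columns:
        res = pgs_regression(phenotype, pgs_variants[label], covariates, clusters)
        rows.append(
            {
                "variant": label,
                "coefficient": res.coefficient,
                "se": res.se,
                "pvalue": res.pvalue,
                "delta_r2": res.delta_r2,
                "significant": res.significant,
            }
        )
    table = pd.DataFrame(rows).set_index("variant")
    return str(table["delta_r2"].idxmax()), table
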