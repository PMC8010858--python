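"""Scikit-learn-style estimators over the twinwell library.

Each estimator follows the sklearn contract as far as family data allows:
construction stores hyperparameters only, ``fit`` accepts a pandas
DataFrame (one row per individual with the standard family columns),
fitted quantities get trailing underscores, and ``get_params`` /
``set_params`` come from :class:`sklearn.base.BaseEstimator`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .phenotypes import resilience_scores
from .pgs import pgs_regression
from .sem import (
    FamilyData,
    common_pathway_spec,
    decompose_latent,
    fit as sem_fit,
    longitudinal_bivariate_spec,
    lrt,
)
from .mrdoc import DEFAULT_RE_GRID, fit_mrdoc, rE_sensitivity

__all__ = [
    "ResilienceScorer",
    "CommonPathwayModel",
    "LongitudinalBivariateModel",
    "MRDoCModel",
    "PGSPredictor",
]

SEM_VARS = ["wellbeing_t1", "wellbeing_t2", "resilience_t1", "resilience_t2"]


class ResilienceScorer(TransformerMixin, BaseEstimator):
    """Append per-wave outcome-based resilience scores to a phenotype table.

    For each wave, standardizes anxious-depression and life-event counts,
    regresses the former on the latter with family-clustered GEE, and
    stores predicted-minus-observed residuals as ``resilience_<wave>``.
    """

    def __init__(self, waves=("t1", "t2"), working="independence"):
        self.waves = waves
        self.working = working

    def fit(self, X: pd.DataFrame, y=None):
        self.slopes_ = {}
        self.fits_ = {}
        for w in self.waves:
            rs = resilience_scores(X[f"anxdep_{w}"], X[f"life_events_{w}"], X["family_id"], working=self.working)
            self.slopes_[w] = rs.slope
            self.fits_[w] = rs.fit
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "slopes_")
        out = X.copy()
        for w in self.waves:
            rs = resilience_scores(out[f"anxdep_{w}"], out[f"life_events_{w}"], out["family_id"], working=self.working)
            out[f"resilience_{w}"] = rs.scores.to_numpy()
        return out


class CommonPathwayModel(BaseEstimator):
    """Bivariate two-wave common-pathway twin-sibling model (FIML).

    Fitted attributes: ``result_`` (engine FitResult), ``h2_`` latent
    heritabilities per trait, ``decomposition_`` (when the latent part is
    sex-equal), ``m2ll_``, ``aic_``.
    """

    def __init__(
        self,
        include_d: bool = False,
        sex_specific_latent: bool = False,
        sex_specific_specific: bool = True,
        sex_specific_means: bool = True,
        standardize: bool = True,
        n_starts: int = 2,
        seed: int = 0,
        compute_se: bool = True,
    ):
        self.include_d = include_d
        self.sex_specific_latent = sex_specific_latent
        self.sex_specific_specific = sex_specific_specific
        self.sex_specific_means = sex_specific_means
        self.standardize = standardize
        self.n_starts = n_starts
        self.seed = seed
        self.compute_se = compute_se

    def _spec(self):
        return common_pathway_spec(
            include_d=self.include_d,
            sex_specific_latent=self.sex_specific_latent,
            sex_specific_specific=self.sex_specific_specific,
            sex_specific_means=self.sex_specific_means,
        )

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        if isinstance(X, FamilyData):
            data = X
        else:
            if self.standardize:
                from .phenotypes import zscore

                X = X.copy()
                for v in SEM_VARS:  # latent shares are scale-free
                    X[v] = zscore(X[v]).to_numpy()
            data = FamilyData.from_frame(X, SEM_VARS)
        self.result_ = sem_fit(spec, data, n_starts=self.n_starts, seed=self.seed, compute_se=self.compute_se)
        self.m2ll_ = self.result_.m2ll
        self.aic_ = self.result_.aic
        if not self.sex_specific_latent:
            self.decomposition_ = decompose_latent(self.result_)
            self.h2_ = dict(zip(self.decomposition_.traits, self.decomposition_.h2))
            self.genetic_covariance_pct_ = self.decomposition_.genetic_covariance_pct
        return self

    def compare(self, other: "CommonPathwayModel"):
        """LRT of this (nested) model against a fuller fitted model."""
        check_is_fitted(self, "result_")
        check_is_fitted(other, "result_")
        return lrt(other.result_, self.result_, force=True)


class LongitudinalBivariateModel(BaseEstimator):
    """AE (or ADE) bivariate model of trait A at wave 1 and trait B at
    wave 2, estimating cross-trait rA and rE with drop-one LRTs."""

    def __init__(
        self,
        var_a: str = "resilience_t1",
        var_b: str = "wellbeing_t2",
        include_d: bool = False,
        sex_specific: bool = False,
        n_starts: int = 2,
        seed: int = 0,
    ):
        self.var_a = var_a
        self.var_b = var_b
        self.include_d = include_d
        self.sex_specific = sex_specific
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        spec = longitudinal_bivariate_spec(
            self.var_a, self.var_b, include_d=self.include_d, sex_specific=self.sex_specific
        )
        data = FamilyData.from_frame(X, [self.var_a, self.var_b])
        self.result_ = sem_fit(spec, data, n_starts=self.n_starts, seed=self.seed)
        if not self.sex_specific:
            self.r_a_ = self.result_.estimates["r_a"]
            self.r_e_ = self.result_.estimates["r_e"]
            null_ra = sem_fit(spec.fix(r_a=0.0), data, n_starts=self.n_starts, seed=self.seed, compute_se=False)
            null_re = sem_fit(spec.fix(r_e=0.0), data, n_starts=self.n_starts, seed=self.seed, compute_se=False)
            self.p_drop_ra_ = lrt(self.result_, null_ra)[2]
            self.p_drop_re_ = lrt(self.result_, null_re)[2]
        return self


class MRDoCModel(BaseEstimator):
    """MR-DoC estimator over (pgs, exposure, outcome) twin-pair tables.

    Fitted attributes: ``g1_`` causal path, ``b1_``, ``b2_``,
    ``explained_variance_`` (% of outcome variance), ``p_g1_``,
    ``result_``.
    """

    def __init__(self, r_e: float = 0.0, n_starts: int = 3, seed: int = 0):
        self.r_e = r_e
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        self.result_ = fit_mrdoc(X, rE_fixed=self.r_e, n_starts=self.n_starts, seed=self.seed)
        est = self.result_.estimates
        self.g1_ = est["g1"]
        self.b1_ = est["b1"]
        self.b2_ = est["b2"]
        self.explained_variance_ = self.result_.explained_variance
        self.p_g1_ = self.result_.lrt_g1[2]
        return self

    def sensitivity(self, X: pd.DataFrame, grid=DEFAULT_RE_GRID) -> pd.DataFrame:
        return rE_sensitivity(X, grid=grid, n_starts=self.n_starts, seed=self.seed)


class PGSPredictor(BaseEstimator):
    """Polygenic-score prediction of one phenotype column.

    Fitted attributes: ``coefficient_``, ``pvalue_``, ``delta_r2_``,
    ``significant_``.
    """

    def __init__(self, phenotype: str = "wellbeing_t2", pgs: str = "pgs_wb", covariate_cols=None):
        self.phenotype = phenotype
        self.pgs = pgs
        self.covariate_cols = covariate_cols

    def fit(self, X: pd.DataFrame, y=None):
        covs = X[list(self.covariate_cols)] if self.covariate_cols else None
        res = pgs_regression(X[self.phenotype], X[self.pgs], covs, X["family_id"])
        self.coefficient_ = res.coefficient
        self.pvalue_ = res.pvalue
        self.delta_r2_ = res.delta_r2
        self.significant_ = res.significant
        self.result_ = res
        return self
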