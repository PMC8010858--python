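"""Score standardization, family-clustered regression, and the
outcome-based resilience score.

Resilience is operationalized as the difference between the *predicted*
level of anxious-depressed symptoms given the number of stressful life
events and the *actual* level: both scores are standardized, the
anxious-depressed score is regressed on the life-event count with a
generalized estimating equation (GEE) that corrects for familial
clustering, and the signed residual (predicted minus observed) is the
resilience score -- positive means fewer symptoms than expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GEEFit", "ResilienceScore", "zscore", "gee_fit", "resilience_scores", "age_effects"]


@dataclass
class GEEFit:
    """Population-averaged regression fit with cluster-robust inference."""

    params: pd.Series
    se: pd.Series  # robust (sandwich) standard errors
    zvalues: pd.Series
    pvalues: pd.Series
    working: str
    n_clusters: int
    n_obs: int

    def __post_init__(self):
        if (self.se < 0).any():
            raise ValueError("negative standard error")

    def predict(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return x @ self.params.to_numpy()


def zscore(values, ddof: int = 1) -> pd.Series:
    """Standardize to mean 0, SD 1 (denominator n - 1); NaN propagates.

    Raises on fewer than two non-missing values or zero variance.
    """
    s = pd.Series(np.asarray(values, float))
    obs = s.dropna()
    if len(obs) < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = obs.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot standardize a constant vector")
    return (s - obs.mean()) / sd


def _check_design(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a minimal set of columns involved in the collinearity
        keep, bad = [], []
        for j in range(x.shape[1]):
            trial = x[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j] if names is not None else j)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def gee_fit(
    y,
    x,
    clusters,
    working: str = "exchangeable",
    names=None,
) -> GEEFit:
    """Gaussian GEE regression with cluster-robust sandwich errors.

    ``working`` selects the working correlation: 'exchangeable' (default,
    one common within-family correlation) or 'independence' (equivalent to
    OLS point estimates with cluster-robust errors).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    clusters = np.asarray(clusters)
    if not (len(y) == len(x) == len(clusters)):
        raise ValueError("y, X and clusters must have equal length")
    keep = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    y, x, clusters = y[keep], x[keep], clusters[keep]
    if len(np.unique(clusters)) < 2:
        raise ValueError("need at least 2 clusters")
    if names is None:
        names = [f"x{j}" for j in range(x.shape[1])]
    _check_design(x, names)
    cov_struct = {"exchangeable": sm.cov_struct.Exchangeable, "independence": sm.cov_struct.Independence}
    if working not in cov_struct:
        raise ValueError(f"unknown working correlation {working!r}")
    import warnings as _warnings

    # a perfect linear fit breaks the working-correlation update (zero
    # scale); solve it directly with exactly-zero sandwich errors
    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    if np.var(y - x @ beta_ols) < 1e-24:
        params = beta_ols
        se = np.zeros_like(beta_ols)
        zv = np.where(params != 0, np.inf, 0.0)
        pv = np.where(params != 0, 0.0, 1.0)
    else:
        model = sm.GEE(y, x, groups=clusters, family=sm.families.Gaussian(), cov_struct=cov_struct[working]())
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit()
        params = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        zv = np.asarray(res.tvalues, float)
        pv = np.asarray(res.pvalues, float)
    idx = pd.Index(names)
    return GEEFit(
        params=pd.Series(params, index=idx),
        se=pd.Series(se, index=idx),
        zvalues=pd.Series(zv, index=idx),
        pvalues=pd.Series(pv, index=idx),
        working=working,
        n_clusters=len(np.unique(clusters)),
        n_obs=len(y),
    )


@dataclass
class ResilienceScore:
    """Per-individual resilience values plus the fitted life-event slope."""

    scores: pd.Series
    slope: float
    slope_se: float
    fit: GEEFit
    missing: pd.Series = field(repr=False, default=None)


def resilience_scores(anx_dep, life_events, clusters, working: str = "independence") -> ResilienceScore:
    """Outcome-based resilience: predicted minus observed standardized
    anxious-depression given standardized life-event count.

    The regression (intercept + slope) is fitted by GEE on complete cases;
    individuals missing either input get a missing resilience score.  The
    default working correlation is 'independence': the population-averaged
    point estimate then solves the ordinary normal equations, so the
    resulting scores are exactly orthogonal to the life-event predictor
    (clustering only affects standard errors, never the score itself);
    'exchangeable' changes the slope weighting and loses exact
    orthogonality.
    """
    anx_dep = pd.Series(np.asarray(anx_dep, float))
    life_events = pd.Series(np.asarray(life_events, float))
    if len(anx_dep) != len(life_events):
        raise ValueError("anx_dep and life_events must have equal length")
    complete = anx_dep.notna() & life_events.notna()
    if complete.sum() < 3:
        raise ValueError("too few complete observations for the resilience regression")
    z_ad = zscore(anx_dep.where(complete))
    z_le = zscore(life_events.where(complete))
    xmat = np.column_stack([np.ones(int(complete.sum())), z_le[complete]])
    fit = gee_fit(z_ad[complete], xmat, np.asarray(clusters)[complete.to_numpy()], working=working, names=["const", "life_events"])
    predicted = fit.params["const"] + fit.params["life_events"] * z_le
    scores = predicted - z_ad  # fewer symptoms than predicted => positive
    return ResilienceScore(
        scores=scores,
        slope=float(fit.params["life_events"]),
        slope_se=float(fit.se["life_events"]),
        fit=fit,
        missing=~complete,
    )


def age_effects(phenotype, age, clusters, working: str = "exchangeable") -> GEEFit:
    """GEE regression of a phenotype on age and age^2 (plus intercept).

    Age is centered at 40 years before squaring to tame collinearity; the
    sign of the quadratic term is unaffected.
    """
    age = np.asarray(age, float)
    ac = age - 40.0
    x = np.column_stack([np.ones_like(ac), ac, ac**2])
    return gee_fit(phenotype, x, clusters, working=working, names=["const", "age", "age2"])
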