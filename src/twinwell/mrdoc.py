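"""The MR-DoC model: Mendelian randomization fused with the
direction-of-causation twin design.

A polygenic score S serves as genetic instrument for the exposure X
(path b1) while twin pairs supply the cross-twin cross-trait covariance
that lets the causal path g1 from X to the outcome Y be estimated with
the instrument's *pleiotropic* path b2 (S directly to Y) left free --
the assumption ordinary MR must make (b2 = 0) becomes an estimated
parameter.  When both traits are AE traits the environmental correlation
rE is not identified alongside g1 and must be fixed (conventionally to
zero); :func:`rE_sensitivity` profiles the causal estimate over a grid
of fixed rE values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem import engine
from .sem.specs import mrdoc_spec

__all__ = [
    "MRDoCResult",
    "WeakInstrumentWarning",
    "mrdoc_expected_cov",
    "fit_mrdoc",
    "causal_explained_variance",
    "rE_sensitivity",
    "DEFAULT_RE_GRID",
]

DEFAULT_RE_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.8)
VAR_NAMES = ("pgs", "exposure", "outcome")


class WeakInstrumentWarning(UserWarning):
    """The PGS does not reliably predict the exposure (first stage weak)."""


def mrdoc_expected_cov(theta: dict[str, float], zygosity: str) -> np.ndarray:
    """Model-implied 6x6 covariance of (S, X, Y) x 2 twins.

    ``theta`` holds b1, g1, b2, a_x, e_x, a_y, e_y, r_a, r_e, sigma_s
    (SD of the PGS).  Cross-twin blocks scale the PGS and A terms by 1
    (MZ) or 0.5 (DZ); E terms never cross.
    """
    spec = mrdoc_spec(r_e_fixed=theta.get("r_e", 0.0))
    full = {p.label: theta.get(p.label, p.fixed if p.fixed is not None else p.start) for p in spec.params}
    for m in ("mu_s", "mu_x", "mu_y"):
        full.setdefault(m, 0.0)
    if zygosity.upper().startswith("MZ"):
        zyg = "MZ"
    elif zygosity.upper().startswith("DZ") or zygosity.upper() == "DOS":
        zyg = "DZ"
    else:
        raise ValueError(f"unknown zygosity label {zygosity!r}")
    _, sigma = spec.family_moments(full, ("twin1", "twin2"), ("F", "F"), zyg)
    return sigma


@dataclass
class MRDoCResult:
    """Fitted MR-DoC model with the g1 = 0 likelihood-ratio test."""

    estimates: dict[str, float]
    se: dict[str, float]
    m2ll: float
    r_e: float
    lrt_g1: tuple[float, int, float]  # (delta -2LL, delta df, p)
    explained_variance: float  # % of Var(Y) due to the causal path
    var_x: float
    var_y: float
    converged: bool
    weak_instrument: bool
    fit: engine.FitResult
    fit_null: engine.FitResult


def _first_stage_check(data_frame: pd.DataFrame) -> bool:
    """Weak-instrument screen: Cov(S, X) must clearly differ from zero."""
    sub = data_frame[["pgs", "exposure"]].dropna()
    n = len(sub)
    if n < 10:
        return True
    r = np.corrcoef(sub["pgs"], sub["exposure"])[0, 1]
    z = abs(np.arctanh(np.clip(r, -0.999999, 0.999999))) * np.sqrt(max(n - 3, 1))
    return z < 3.0


def fit_mrdoc(
    pairs: pd.DataFrame,
    rE_fixed: float = 0.0,
    n_starts: int = 3,
    seed: int = 0,
) -> MRDoCResult:
    """FIML fit of the MR-DoC model to (pgs, exposure, outcome) twin pairs.

    ``pairs`` needs columns family_id, zygosity (MZ*/DZ*), role, sex,
    pgs, exposure, outcome; both MZ and DZ pairs must be present.  The
    causal path is tested by an LRT of g1 = 0 against the g1-free model.
    """
    zyg = pairs["zygosity"].astype(str)
    if not (zyg.str.startswith("MZ").any() and (zyg.str.startswith("DZ") | (zyg == "DOS")).any()):
        raise ValueError("MR-DoC needs both MZ and DZ twin pairs")
    weak = _first_stage_check(pairs)
    if weak:
        warnings.warn(
            "weak instrument: the PGS shows no clear association with the exposure",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    # MZ co-twins carry the identical polygenic score, which makes the 6x6
    # implied covariance singular; enter the score once per MZ pair (the
    # duplicate is marginalized out, losing no information).
    pairs = pairs.copy()
    mz_twin2 = zyg.str.startswith("MZ").to_numpy() & (pairs["role"] == "twin2").to_numpy()
    pairs.loc[mz_twin2, "pgs"] = np.nan
    spec = mrdoc_spec(r_e_fixed=rE_fixed)
    data = engine.FamilyData.from_frame(pairs, list(VAR_NAMES))
    res = engine.fit(spec, data, n_starts=n_starts, seed=seed)
    spec0 = spec.fix(g1=0.0)
    res0 = engine.fit(spec0, data, n_starts=n_starts, seed=seed, compute_se=False)
    lrt = engine.lrt(res, res0)

    theta = dict(res.estimates)
    theta["r_e"] = rE_fixed
    sigma = mrdoc_expected_cov(theta, "MZ")
    var_x, var_y = float(sigma[1, 1]), float(sigma[2, 2])
    ev = causal_explained_variance_from(theta["g1"], var_x, var_y)
    return MRDoCResult(
        estimates=theta,
        se=res.se,
        m2ll=res.m2ll,
        r_e=rE_fixed,
        lrt_g1=lrt,
        explained_variance=ev,
        var_x=var_x,
        var_y=var_y,
        converged=res.converged,
        weak_instrument=weak,
        fit=res,
        fit_null=res0,
    )


def causal_explained_variance_from(g1: float, var_x: float, var_y: float) -> float:
    if var_y <= 0:
        raise ValueError("Var(outcome) must be positive")
    return float(100.0 * g1**2 * var_x / var_y)


def causal_explained_variance(result: MRDoCResult) -> float:
    """Percentage of outcome variance explained by the causal path:
    100 * g1^2 * Var(X) / Var(Y), with both variances assembled from the
    fitted model algebra."""
    return causal_explained_variance_from(result.estimates["g1"], result.var_x, result.var_y)


def rE_sensitivity(
    pairs: pd.DataFrame,
    grid=DEFAULT_RE_GRID,
    n_starts: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the MR-DoC model for each fixed environmental correlation.

    Returns one row per grid value: -2LL, g1, explained variance (%) and
    the g1 = 0 LRT p-value.  Individual grid failures are recorded as
    NaN rows so the rest of the profile survives.
    """
    rows = []
    for r_e in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", WeakInstrumentWarning)
                res = fit_mrdoc(pairs, rE_fixed=float(r_e), n_starts=n_starts, seed=seed)
            rows.append(
                {
                    "r_e": r_e,
                    "m2ll": res.m2ll,
                    "g1": res.estimates["g1"],
                    "explained_variance": res.explained_variance,
                    "p_g1": res.lrt_g1[2],
                    "converged": res.converged,
                    "error": "",
                }
            )
        except Exception as exc:  # pragma: no cover - defensive per-grid isolation
            rows.append(
                {
                    "r_e": r_e,
                    "m2ll": np.nan,
                    "g1": np.nan,
                    "explained_variance": np.nan,
                    "p_g1": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
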