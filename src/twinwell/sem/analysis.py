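"""Variance/covariance decomposition and twin-group correlations.

The bivariate common-pathway fit yields, per trait, the standardized
latent variance components (h2 = latent A share, d2, e2) and the
cross-trait latent correlations rG (rA), rD, rE.  The genetic share of
the latent covariance follows from path tracing:

    cov_G = rG * sqrt(h2_1 * h2_2)        (+ rD * sqrt(d2_1 * d2_2))
    cov_E = rE * sqrt(e2_1 * e2_2)
    % genetic = 100 * (cov_G) / (cov_G + cov_E)

Twin and twin-sibling correlations come from a constrained saturated
model (exchangeable members, one cross-member correlation matrix per
relationship class) fitted by FIML, with Fisher-z confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .engine import FamilyData, FitResult
from .specs import correlation_spec

__all__ = [
    "VarianceDecomposition",
    "decompose_latent",
    "covariance_shares",
    "solve_rg_from_share",
    "twin_group_correlations",
    "choose_model_family",
    "GroupCorrelations",
]


# ---------------------------------------------------------------------------
# latent decomposition
# ---------------------------------------------------------------------------


def covariance_shares(
    h2: tuple[float, float],
    e2: tuple[float, float],
    r_g: float,
    r_e: float,
    d2: tuple[float, float] = (0.0, 0.0),
    r_d: float = 0.0,
) -> tuple[float, float]:
    """(% genetic, % environmental) of the latent cross-trait covariance."""
    cov_g = r_g * math.sqrt(h2[0] * h2[1]) + r_d * math.sqrt(d2[0] * d2[1])
    cov_e = r_e * math.sqrt(e2[0] * e2[1])
    total = cov_g + cov_e
    if total == 0:
        raise ZeroDivisionError("zero latent covariance: shares undefined")
    return 100.0 * cov_g / total, 100.0 * cov_e / total


def solve_rg_from_share(
    genetic_share_pct: float,
    h2: tuple[float, float],
    e2: tuple[float, float],
    r_e: float,
) -> float:
    """Invert :func:`covariance_shares` for rG given the genetic share (%)."""
    s = genetic_share_pct / 100.0
    if not 0 < s < 1:
        raise ValueError("share must be strictly between 0 and 100%")
    return s / (1.0 - s) * r_e * math.sqrt(e2[0] * e2[1]) / math.sqrt(h2[0] * h2[1])


@dataclass
class VarianceDecomposition:
    """Standardized shares from a bivariate common-pathway fit."""

    traits: tuple[str, str]
    h2: tuple[float, float]  # latent additive-genetic share per trait
    d2: tuple[float, float]
    e2: tuple[float, float]
    r_g: float
    r_d: float
    r_e: float
    genetic_covariance_pct: float
    environmental_covariance_pct: float
    # per (trait, wave, sex): dict label -> {"latent", "specific_a", "specific_d", "specific_e"}
    wave_shares: dict = field(default_factory=dict)

    def __post_init__(self):
        for t in range(2):
            total = self.h2[t] + self.d2[t] + self.e2[t]
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"latent shares of trait {self.traits[t]} sum to {total}, not 1")


def decompose_latent(fit: FitResult, traits=("wellbeing", "resilience"), waves=("t1", "t2")) -> VarianceDecomposition:
    """Standardized variance/covariance decomposition of a common-pathway fit.

    Requires a fit whose latent part is not sex-specific (the final-model
    configuration).  Latent factors have unit variance, so squared latent
    paths are directly the standardized shares and the correlation
    parameters are rG/rD/rE.
    """
    if not fit.converged:
        raise ValueError("decomposition requires a converged fit")
    est = fit.estimates
    if "r_a" not in est:
        raise ValueError("latent part is sex-specific; equate it before decomposing")

    def get(label, default=0.0):
        return est.get(label, default)

    h2, d2, e2 = [], [], []
    for t in traits:
        a2 = get(f"a_lat_{t}") ** 2
        dd2 = get(f"d_lat_{t}") ** 2
        h2.append(a2)
        d2.append(dd2)
        e2.append(max(0.0, 1.0 - a2 - dd2))
    r_g, r_d, r_e = get("r_a"), get("r_d"), get("r_e")
    gen_pct, env_pct = covariance_shares(tuple(h2), tuple(e2), r_g, r_e, tuple(d2), r_d)

    wave_shares = {}
    sexes = ["F", "M"] if any(k.endswith("_F") for k in est) else [""]
    for t in traits:
        for w in waves:
            for s in sexes:
                sfx = f"_{s}" if s else ""
                lam = get(f"lam_{t}_{w}{sfx}", get(f"lam_{t}_{w}"))
                a_s = get(f"as_{t}_{w}{sfx}", get(f"as_{t}_{w}"))
                d_s = get(f"ds_{t}_{w}{sfx}", get(f"ds_{t}_{w}"))
                e_s = get(f"es_{t}_{w}{sfx}", get(f"es_{t}_{w}"))
                total = lam**2 + a_s**2 + d_s**2 + e_s**2
                key = (t, w, s or "all")
                wave_shares[key] = {
                    "latent": lam**2 / total,
                    "specific_a": a_s**2 / total,
                    "specific_d": d_s**2 / total,
                    "specific_e": e_s**2 / total,
                }
    return VarianceDecomposition(
        traits=tuple(traits),
        h2=tuple(h2),
        d2=tuple(d2),
        e2=tuple(e2),
        r_g=r_g,
        r_d=r_d,
        r_e=r_e,
        genetic_covariance_pct=gen_pct,
        environmental_covariance_pct=env_pct,
        wave_shares=wave_shares,
    )


# ---------------------------------------------------------------------------
# twin-group correlations
# ---------------------------------------------------------------------------


@dataclass
class GroupCorrelations:
    """Per-zygosity ML correlation tables with Fisher-z CIs."""

    variables: list[str]
    groups: dict  # zygosity -> {"cross_twin": DataFrame, "within": DataFrame, "ci": dict, "n_pairs": int}
    fits: dict = field(default_factory=dict, repr=False)


def twin_group_correlations(
    families: pd.DataFrame,
    variables,
    groups=("MZM", "DZM", "MZF", "DZF", "DOS"),
    include_siblings: bool = False,
    n_starts: int = 1,
    seed: int = 0,
) -> GroupCorrelations:
    """Cross-twin (cross-trait) correlations per zygosity group.

    Each group gets its own constrained saturated fit: members
    exchangeable, one cross-member correlation matrix per relationship
    class present.  Groups without at least two complete pairs on any
    variable are marked unavailable.
    """
    variables = list(variables)
    out = {}
    fits = {}
    for zyg in groups:
        sub = families[families["zygosity"] == zyg]
        if not include_siblings:
            sub = sub[sub["role"].isin(["twin1", "twin2"])]
        # need some complete pairs
        n_pairs = 0
        if len(sub):
            twins = sub[sub["role"].isin(["twin1", "twin2"])]
            wide = twins.pivot(index="family_id", columns="role", values=variables[0])
            if "twin1" in wide and "twin2" in wide:
                n_pairs = int((wide["twin1"].notna() & wide["twin2"].notna()).sum())
        if n_pairs < 2:
            out[zyg] = {"available": False, "n_pairs": n_pairs}
            continue
        classes = ["mz"] if zyg.startswith("MZ") else ["dz"]
        if include_siblings and (sub["role"] == "sibling").any():
            classes.append("sib")
        spec = correlation_spec(variables, classes=tuple(classes), name=f"corr_{zyg}")
        data = FamilyData.from_frame(sub, variables)
        res = engine.fit(spec, data, n_starts=n_starts, seed=seed)
        fits[zyg] = res
        p = len(variables)
        cls = classes[0]
        cross = np.empty((p, p))
        ci = {}
        for i in range(p):
            for j in range(i, p):
                lab = f"zx_{cls}_{variables[i]}__{variables[j]}"
                z = res.estimates[lab]
                se = res.se.get(lab, np.nan)
                cross[i, j] = cross[j, i] = math.tanh(z)
                ci[(variables[i], variables[j])] = (
                    math.tanh(z - 1.96 * se) if np.isfinite(se) else np.nan,
                    math.tanh(z + 1.96 * se) if np.isfinite(se) else np.nan,
                )
        within = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                within[i, j] = within[j, i] = math.tanh(res.estimates[f"zw_{variables[i]}__{variables[j]}"])
        out[zyg] = {
            "available": True,
            "n_pairs": n_pairs,
            "cross_twin": pd.DataFrame(cross, index=variables, columns=variables),
            "within": pd.DataFrame(within, index=variables, columns=variables),
            "ci": ci,
        }
    return GroupCorrelations(variables=variables, groups=out, fits=fits)


def choose_model_family(r_mz, r_dz) -> dict:
    """ADE when the MZ correlations exceed twice the DZ/sibling
    correlations (averaged), else ACE; ties go to ACE.

    Accepts scalars or sequences of per-variable correlations.
    """
    mz = float(np.mean(np.asarray(r_mz, float)))
    dz = float(np.mean(np.asarray(r_dz, float)))
    margin = mz - 2.0 * dz
    return {
        "family": "ADE" if margin > 0 else "ACE",
        "r_mz_mean": mz,
        "r_dz_mean": dz,
        "margin": margin,
    }
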