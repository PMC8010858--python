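"""Model-spec builders for the twin-sibling model zoo.

Builders return :class:`~twinwell.sem.engine.ModelSpec` objects:

* :func:`common_pathway_spec` -- the bivariate two-wave psychometric
  (common-pathway) model: per trait a latent factor with unit variance
  decomposed into A (+ D) + E, loading on the wave-1 and wave-2 scores,
  with wave-specific A (+ D) + E residuals; cross-trait latent
  correlations rA (rD) rE.  Sex-specificity flags implement the model
  ladder (full sex-specific ADE -> equal sexes -> equal latent part only
  -> D = 0).
* :func:`longitudinal_bivariate_spec` -- two observed variables per person
  (trait A at wave 1, trait B at wave 2) with an AE (or ADE)
  decomposition and cross-trait correlations, used for longitudinal
  genetic/environmental-correlation tests.
* :func:`mrdoc_spec` -- the MR-DoC model over (PGS, exposure, outcome)
  per twin: causal path g1, instrument strength b1, pleiotropy b2, with
  the environmental correlation fixed for identification.
* :func:`saturated_spec` / :func:`correlation_spec` -- direct
  mean/SD/correlation parameterizations with twin-exchangeability and
  relationship-class constraints.
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np
from scipy import linalg

from .engine import (
    DirectModelSpec,
    LatentModelSpec,
    ModelSpec,
    Param,
    Structure,
    relationship,
)

__all__ = [
    "common_pathway_spec",
    "common_pathway_ladder",
    "longitudinal_bivariate_spec",
    "mrdoc_spec",
    "saturated_spec",
    "correlation_spec",
]

SEXES = ("F", "M")


def _sex_suffixes(flag: bool) -> list[str]:
    return ["_F", "_M"] if flag else [""]


def _sfx(flag: bool, sex: str) -> str:
    return f"_{sex}" if flag else ""


# ---------------------------------------------------------------------------
# common pathway
# ---------------------------------------------------------------------------


def common_pathway_spec(
    traits: tuple[str, str] = ("wellbeing", "resilience"),
    waves: tuple[str, str] = ("t1", "t2"),
    include_d: bool = True,
    sex_specific_latent: bool = True,
    sex_specific_specific: bool = True,
    sex_specific_means: bool = True,
    name: str | None = None,
    parent: str | None = None,
) -> LatentModelSpec:
    """Bivariate two-wave common-pathway model spec.

    Identification: each latent trait factor has unit variance (its A/D
    paths are free, the E path is derived as sqrt(1 - a^2 - d^2)) and both
    wave loadings are free.  Variance paths are bounded at zero so the
    usual sign indeterminacy is resolved; a latent A share of exactly the
    bound is a boundary solution, not an error.

    ``sex_specific_specific`` governs the wave loadings *and* the
    time-specific residual paths (the parts that stay sex-specific in the
    final model); ``sex_specific_latent`` governs the latent decomposition
    and the cross-trait correlations.
    """
    if name is None:
        bits = ["cp", "ADE" if include_d else "AE"]
        if not sex_specific_latent:
            bits.append("eqlat")
        if not sex_specific_specific:
            bits.append("eqspec")
        name = "_".join(bits)
    var_names = [f"{t}_{w}" for t in traits for w in waves]
    n_t, n_w = len(traits), len(waves)
    params: list[Param] = []

    for s in _sex_suffixes(sex_specific_latent):
        for t in traits:
            params.append(Param(f"a_lat_{t}{s}", 0.75, 0.0, 1.0))
            if include_d:
                params.append(Param(f"d_lat_{t}{s}", 0.1, 0.0, 1.0))
        params.append(Param(f"r_a{s}", 0.5, -1.0, 1.0))
        if include_d:
            params.append(Param(f"r_d{s}", 0.2, -1.0, 1.0))
        params.append(Param(f"r_e{s}", 0.5, -1.0, 1.0))
    for s in _sex_suffixes(sex_specific_specific):
        for t in traits:
            for w in waves:
                params.append(Param(f"lam_{t}_{w}{s}", 0.8, 0.0, 10.0))
                params.append(Param(f"as_{t}_{w}{s}", 0.45, 0.0, 10.0))
                if include_d:
                    params.append(Param(f"ds_{t}_{w}{s}", 0.1, 0.0, 10.0))
                params.append(Param(f"es_{t}_{w}{s}", 0.45, 0.0, 10.0))
    for s in _sex_suffixes(sex_specific_means):
        for t in traits:
            for w in waves:
                params.append(Param(f"mu_{t}_{w}{s}", 0.0, -np.inf, np.inf))

    kinds = [("A", n_t + n_t * n_w), ("E", n_t + n_t * n_w)]
    if include_d:
        kinds.insert(1, ("D", n_t + n_t * n_w))

    def validate(th: dict) -> bool:
        for s in _sex_suffixes(sex_specific_latent):
            for t in traits:
                tot = th[f"a_lat_{t}{s}"] ** 2
                if include_d:
                    tot += th[f"d_lat_{t}{s}"] ** 2
                if tot > 1.0 + 1e-12:
                    return False
        return True

    def build(th: dict) -> Structure:
        phi: dict[str, dict[str, np.ndarray]] = {}
        lam = {}
        mu = {}
        n_lat = n_t + n_t * n_w
        for sex in SEXES:
            sl = _sfx(sex_specific_latent, sex)
            ss = _sfx(sex_specific_specific, sex)
            sm = _sfx(sex_specific_means, sex)
            phi[sex] = {}
            for kind, r_lab in (("A", "r_a"), ("D", "r_d"), ("E", "r_e")):
                if kind == "D" and not include_d:
                    continue
                r = th[f"{r_lab}{sl}"]
                block = np.eye(n_lat)
                block[0, 1] = block[1, 0] = r
                phi[sex][kind] = block
            # loadings: rows = vars in (trait, wave) order; cols = [lat_t0, lat_t1, specifics...]
            L = {"A": np.zeros((n_t * n_w, n_lat))}
            if include_d:
                L["D"] = np.zeros((n_t * n_w, n_lat))
            L["E"] = np.zeros((n_t * n_w, n_lat))
            mu_vec = np.empty(n_t * n_w)
            for ti, t in enumerate(traits):
                a = th[f"a_lat_{t}{sl}"]
                d = th[f"d_lat_{t}{sl}"] if include_d else 0.0
                e = math.sqrt(max(0.0, 1.0 - a * a - d * d))
                for wi, w in enumerate(waves):
                    row = ti * n_w + wi
                    lam_v = th[f"lam_{t}_{w}{ss}"]
                    L["A"][row, ti] = lam_v * a
                    if include_d:
                        L["D"][row, ti] = lam_v * d
                    L["E"][row, ti] = lam_v * e
                    spec_col = n_t + row
                    L["A"][row, spec_col] = th[f"as_{t}_{w}{ss}"]
                    if include_d:
                        L["D"][row, spec_col] = th[f"ds_{t}_{w}{ss}"]
                    L["E"][row, spec_col] = th[f"es_{t}_{w}{ss}"]
                    mu_vec[row] = th[f"mu_{t}_{w}{sm}"]
            lam[sex] = np.hstack([L[k] for k, _ in kinds])
            mu[sex] = mu_vec
        return Structure(kinds=kinds, phi=phi, lam=lam, mu=mu)

    spec = LatentModelSpec(
        params, var_names, build, validate=validate, name=name, kind="common_pathway_bivariate", parent=parent
    )
    spec.build_args = (
        "common_pathway_spec",
        dict(
            traits=traits,
            waves=waves,
            include_d=include_d,
            sex_specific_latent=sex_specific_latent,
            sex_specific_specific=sex_specific_specific,
            sex_specific_means=sex_specific_means,
            name=name,
            parent=parent,
        ),
    )
    return spec


def common_pathway_ladder(traits=("wellbeing", "resilience"), waves=("t1", "t2")) -> dict[str, LatentModelSpec]:
    """The four-model ladder: I full sex-specific ADE, II equal sexes,
    III equal latent part only, IV as III with D = 0."""
    m1 = common_pathway_spec(traits, waves, include_d=True, sex_specific_latent=True, sex_specific_specific=True, name="I_ADE_full")
    m2 = common_pathway_spec(traits, waves, include_d=True, sex_specific_latent=False, sex_specific_specific=False, name="II_ADE_equal_sex", parent="I_ADE_full")
    m3 = common_pathway_spec(traits, waves, include_d=True, sex_specific_latent=False, sex_specific_specific=True, name="III_ADE_equal_latent", parent="I_ADE_full")
    m4 = common_pathway_spec(traits, waves, include_d=False, sex_specific_latent=False, sex_specific_specific=True, name="IV_AE_equal_latent", parent="III_ADE_equal_latent")
    return {"I": m1, "II": m2, "III": m3, "IV": m4}


# ---------------------------------------------------------------------------
# longitudinal bivariate
# ---------------------------------------------------------------------------


def longitudinal_bivariate_spec(
    var_a: str = "resilience_t1",
    var_b: str = "wellbeing_t2",
    include_d: bool = False,
    sex_specific: bool = False,
    name: str | None = None,
    parent: str | None = None,
) -> LatentModelSpec:
    """Bivariate AE (or ADE) model for one trait at baseline and another at
    follow-up, estimating the cross-trait genetic and environmental
    correlations on the observed scale.

    Fix ``r_a`` or ``r_e`` to zero via ``spec.fix(r_a=0.0)`` for LRTs.
    """
    if name is None:
        name = f"long_{'ADE' if include_d else 'AE'}_{var_a}__{var_b}"
    var_names = [var_a, var_b]
    params: list[Param] = []
    for s in _sex_suffixes(sex_specific):
        for v in ("1", "2"):
            params.append(Param(f"a{v}{s}", 0.6, 0.0, 10.0))
            if include_d:
                params.append(Param(f"d{v}{s}", 0.1, 0.0, 10.0))
            params.append(Param(f"e{v}{s}", 0.6, 1e-6, 10.0))
            params.append(Param(f"mu{v}{s}", 0.0, -np.inf, np.inf))
        params.append(Param(f"r_a{s}", 0.3, -1.0, 1.0))
        if include_d:
            params.append(Param(f"r_d{s}", 0.0, -1.0, 1.0))
        params.append(Param(f"r_e{s}", 0.3, -1.0, 1.0))

    kinds = [("A", 2), ("E", 2)]
    if include_d:
        kinds.insert(1, ("D", 2))

    def build(th: dict) -> Structure:
        phi, lam, mu = {}, {}, {}
        for sex in SEXES:
            s = _sfx(sex_specific, sex)
            blocks = {}
            for kind, r_lab in (("A", "r_a"), ("D", "r_d"), ("E", "r_e")):
                if kind == "D" and not include_d:
                    continue
                b = np.eye(2)
                b[0, 1] = b[1, 0] = th[f"{r_lab}{s}"]
                blocks[kind] = b
            L = []
            for kind, _ in kinds:
                lab = {"A": "a", "D": "d", "E": "e"}[kind]
                L.append(np.diag([th[f"{lab}1{s}"], th[f"{lab}2{s}"]]))
            lam[sex] = np.hstack(L)
            mu[sex] = np.array([th[f"mu1{s}"], th[f"mu2{s}"]])
            phi[sex] = blocks
        return Structure(kinds=kinds, phi=phi, lam=lam, mu=mu)

    spec = LatentModelSpec(params, var_names, build, name=name, kind="longitudinal_bivariate", parent=parent)
    spec.build_args = (
        "longitudinal_bivariate_spec",
        dict(var_a=var_a, var_b=var_b, include_d=include_d, sex_specific=sex_specific, name=name, parent=parent),
    )
    return spec


# ---------------------------------------------------------------------------
# MR-DoC
# ---------------------------------------------------------------------------


def mrdoc_spec(
    r_e_fixed: float = 0.0,
    var_names: tuple[str, str, str] = ("pgs", "exposure", "outcome"),
    name: str | None = None,
    parent: str | None = None,
) -> LatentModelSpec:
    """MR-DoC model spec over (PGS S, exposure X, outcome Y) per twin.

    X = b1*S + a_x*A_x + e_x*E_x
    Y = g1*X + b2*S + a_y*A_y + e_y*E_y

    The PGS behaves like an additive-genetic component: cross-twin sharing
    1 in MZ and 0.5 in DZ pairs, uncorrelated with the residual A factors.
    With a single instrument the environmental correlation r_e must be
    fixed (default 0) for identification.
    """
    if name is None:
        name = f"mrdoc_rE{r_e_fixed:g}"
    params = [
        Param("b1", 0.2, -10.0, 10.0),
        Param("g1", 0.2, -10.0, 10.0),
        Param("b2", 0.0, -10.0, 10.0),
        Param("a_x", 0.6, 0.0, 10.0),
        Param("e_x", 0.6, 1e-6, 10.0),
        Param("a_y", 0.6, 0.0, 10.0),
        Param("e_y", 0.6, 1e-6, 10.0),
        Param("r_a", 0.3, -1.0, 1.0),
        Param("sigma_s", 1.0, 1e-6, 10.0),
        Param("r_e", 0.0, -1.0, 1.0, fixed=float(r_e_fixed)),
        Param("mu_s", 0.0, -np.inf, np.inf),
        Param("mu_x", 0.0, -np.inf, np.inf),
        Param("mu_y", 0.0, -np.inf, np.inf),
    ]
    kinds = [("A", 3), ("E", 2)]

    def build(th: dict) -> Structure:
        phi_a = np.eye(3)
        phi_a[1, 2] = phi_a[2, 1] = th["r_a"]
        phi_e = np.eye(2)
        phi_e[0, 1] = phi_e[1, 0] = th["r_e"]
        s, b1, g1, b2 = th["sigma_s"], th["b1"], th["g1"], th["b2"]
        ax, ex, ay, ey = th["a_x"], th["e_x"], th["a_y"], th["e_y"]
        lam = np.array(
            [
                # A: S, A_x, A_y        E: E_x, E_y
                [s, 0.0, 0.0, 0.0, 0.0],
                [b1 * s, ax, 0.0, ex, 0.0],
                [(g1 * b1 + b2) * s, g1 * ax, ay, g1 * ex, ey],
            ]
        )
        mu = np.array([th["mu_s"], th["mu_x"], th["mu_y"]])
        phi = {"A": phi_a, "E": phi_e}
        return Structure(kinds=kinds, phi={"F": phi, "M": phi}, lam={"F": lam, "M": lam}, mu={"F": mu, "M": mu})

    spec = LatentModelSpec(params, list(var_names), build, name=name, kind="mrdoc", parent=parent)
    spec.build_args = (
        "mrdoc_spec",
        dict(r_e_fixed=r_e_fixed, var_names=tuple(var_names), name=name, parent=parent),
    )
    return spec


# ---------------------------------------------------------------------------
# saturated / correlation models
# ---------------------------------------------------------------------------


def saturated_spec(var_names, name: str = "saturated") -> DirectModelSpec:
    """Saturated Gaussian model for independent individuals.

    One mean and SD per variable plus an unstructured correlation matrix
    (Fisher-z parameterized).  Intended for single-member families; its ML
    solution equals the sample moments on complete data.
    """
    var_names = list(var_names)
    p = len(var_names)
    params = [Param(f"mu_{v}", 0.0, -np.inf, np.inf) for v in var_names]
    params += [Param(f"log_sd_{v}", 0.0, -10.0, 10.0) for v in var_names]
    pair_labels = [f"z_{a}__{b}" for a, b in combinations_with_replacement(var_names, 2) if a != b]
    params += [Param(lab, 0.0, -5.0, 5.0) for lab in pair_labels]

    def build_moments(th, roles, sexes, zygosity):
        if len(roles) != 1:
            raise ValueError("saturated_spec handles single-member families only")
        sd = np.array([math.exp(th[f"log_sd_{v}"]) for v in var_names])
        corr = np.eye(p)
        k = 0
        for i in range(p):
            for j in range(i + 1, p):
                corr[i, j] = corr[j, i] = math.tanh(th[f"z_{var_names[i]}__{var_names[j]}"])
        sigma = corr * np.outer(sd, sd)
        mu = np.array([th[f"mu_{v}"] for v in var_names])
        return mu, sigma

    spec = DirectModelSpec(params, var_names, build_moments, name=name, kind="saturated")
    spec.build_args = ("saturated_spec", dict(var_names=tuple(var_names), name=name))
    return spec


def correlation_spec(
    var_names,
    classes: tuple[str, ...] = ("mz", "dz", "sib"),
    merge_dz_sib: bool = False,
    name: str | None = None,
    parent: str | None = None,
) -> DirectModelSpec:
    """Constrained saturated model for twin/sibling correlation estimation.

    Members are exchangeable: one mean and SD per variable shared by all
    family members, one within-person correlation matrix, and one symmetric
    cross-member correlation matrix per relationship class (``mz`` for MZ
    co-twins, ``dz`` for DZ co-twins, ``sib`` for twin-sibling and
    sibling-sibling pairs).  ``merge_dz_sib`` equates the DZ and sibling
    matrices -- the no-special-twin-environment constraint.
    """
    var_names = list(var_names)
    p = len(var_names)
    if merge_dz_sib:
        classes = tuple(c for c in classes if c not in ("dz", "sib")) + ("dzsib",)
    if name is None:
        name = "corr_" + ("dzsib" if merge_dz_sib else "full")
    params = [Param(f"mu_{v}", 0.0, -np.inf, np.inf) for v in var_names]
    params += [Param(f"log_sd_{v}", 0.0, -10.0, 10.0) for v in var_names]
    for i in range(p):
        for j in range(i + 1, p):
            params.append(Param(f"zw_{var_names[i]}__{var_names[j]}", 0.3, -5.0, 5.0))
    for cls in classes:
        for i in range(p):
            for j in range(i, p):
                params.append(Param(f"zx_{cls}_{var_names[i]}__{var_names[j]}", 0.1, -5.0, 5.0))

    def pair_class(role_i, role_j, zygosity):
        rel = relationship(role_i, role_j, zygosity)
        if rel == "mz":
            return "mz"
        both_twins = role_i in ("twin1", "twin2") and role_j in ("twin1", "twin2")
        cls = "dz" if both_twins else "sib"
        if merge_dz_sib and cls in ("dz", "sib"):
            return "dzsib"
        return cls

    def build_moments(th, roles, sexes, zygosity):
        sd = np.array([math.exp(th[f"log_sd_{v}"]) for v in var_names])
        r_within = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                r_within[i, j] = r_within[j, i] = math.tanh(th[f"zw_{var_names[i]}__{var_names[j]}"])
        r_cross = {}
        for cls in classes:
            m = np.empty((p, p))
            for i in range(p):
                for j in range(i, p):
                    m[i, j] = m[j, i] = math.tanh(th[f"zx_{cls}_{var_names[i]}__{var_names[j]}"])
            r_cross[cls] = m
        n_m = len(roles)
        sigma = np.empty((n_m * p, n_m * p))
        d_outer = np.outer(sd, sd)
        for i in range(n_m):
            si = slice(i * p, (i + 1) * p)
            sigma[si, si] = r_within * d_outer
            for j in range(i + 1, n_m):
                cls = pair_class(roles[i], roles[j], zygosity)
                if cls not in r_cross:
                    raise ValueError(f"relationship class {cls!r} not parameterized")
                sj = slice(j * p, (j + 1) * p)
                block = r_cross[cls] * d_outer
                sigma[si, sj] = block
                sigma[sj, si] = block.T
        mu = np.tile(np.array([th[f"mu_{v}"] for v in var_names]), n_m)
        return mu, sigma

    spec = DirectModelSpec(params, var_names, build_moments, name=name, kind="group_correlation", parent=parent)
    spec.classes = classes  # type: ignore[attr-defined]
    spec.build_args = (
        "correlation_spec",
        dict(
            var_names=tuple(var_names),
            classes=tuple(c for c in classes if c != "dzsib") or ("dz", "sib"),
            merge_dz_sib=merge_dz_sib,
            name=name,
            parent=parent,
        ),
    )
    return spec
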