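"""Twin-sibling family data generator with known ground truth.

The generator mirrors the analysis models: each trait (well-being and the
resilience core) follows a bivariate common-pathway structure over two
waves -- a unit-variance latent factor decomposed into A (+ D) + E loading
on both waves, plus wave-specific A (+ D) + E residuals -- with additive
genetic components correlating 1 between MZ co-twins and 0.5 between DZ
co-twins, twin-sibling and sibling-sibling pairs (0.25 for dominance).
Polygenic scores are standardized A-like variables (sharing 1 / 0.5) with
paths b1 to well-being and b2 (pleiotropy) plus b_res to resilience, and
phenotype-level causal paths can couple the traits.  Anxious-depression is
built from the resilience core and a truncated-Poisson life-event count so
that regressing it on life events recovers the configured slope and the
residual recovers the core.

:func:`implied_moments` assembles the exact model-implied moments by path
tracing and serves as the analytic oracle for both the simulator and the
SEM engine; the simulator itself composes phenotypes from individually
drawn variance components, a deliberately independent code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import GenerativeParams, MRDoCTruth, ZYGOSITY_GROUPS
from .sem.engine import SHARING, Structure, assemble_moments, relationship

__all__ = [
    "simulate_families",
    "simulate_mrdoc_pairs",
    "implied_moments",
    "structure_from_params",
    "CORE_VARS",
]

CORE_VARS = ["wellbeing_t1", "wellbeing_t2", "resilience_t1", "resilience_t2"]
PGS_VARS = ["pgs_wb", "pgs_res"]
TRAITS = ("wellbeing", "resilience")
WAVES = ("t1", "t2")
SEX_INDEX = {"F": 0, "M": 1}
PLATFORMS = ["Axiom", "Affy6", "Omni1M", "Illumina660", "GSA", "Perlegen"]

#: LDpred-style causal-variant fractions and the fidelity of the score
#: computed at each fraction relative to the ideal score (peak at 0.5)
PGS_FRACTIONS = {"1": 0.85, "0.5": 1.0, "0.3": 0.95, "0.2": 0.9, "0.1": 0.8, "0.05": 0.7, "0.01": 0.55}


# ---------------------------------------------------------------------------
# analytic structure / implied moments
# ---------------------------------------------------------------------------


def _causal_transform(params: GenerativeParams) -> np.ndarray:
    """2x2 simultaneous-equation mixing of (well-being, resilience)."""
    g = np.array([[0.0, params.g_res_to_wb], [params.g_wb_to_res, 0.0]])
    det = 1.0 - params.g_wb_to_res * params.g_res_to_wb
    if abs(det) < 1e-10:
        raise ValueError("causal loop g_wb_to_res * g_res_to_wb too close to 1")
    return np.linalg.inv(np.eye(2) - g)


def structure_from_params(params: GenerativeParams, include_pgs: bool = False) -> Structure:
    """Ground-truth Structure over the core phenotypes (+ PGS columns).

    Latent A order: [A_wb, A_res, As x4, S_wb, S_res, S_noise]; D and E
    kinds carry the latent and wave-specific components.  Causal paths are
    folded into the loading rows, so the assembled moments are exact under
    any (non-degenerate) simultaneous causal coupling.
    """
    e_lat = params.e_latent()
    n_spec = 4
    k_a = 2 + n_spec + 3
    k_d = 2 + n_spec
    k_e = 2 + n_spec
    kinds = [("A", k_a), ("D", k_d), ("E", k_e)]
    phi_a = np.eye(k_a)
    phi_a[0, 1] = phi_a[1, 0] = params.r_a
    phi_d = np.eye(k_d)
    phi_d[0, 1] = phi_d[1, 0] = params.r_d
    phi_e = np.eye(k_e)
    phi_e[0, 1] = phi_e[1, 0] = params.r_e
    phi = {"A": phi_a, "D": phi_d, "E": phi_e}

    t_mix = _causal_transform(params)
    sig_s = math.sqrt(params.sigma_s2)
    lam, mu = {}, {}
    for sex, s in SEX_INDEX.items():
        rows_a = np.zeros((4, k_a))
        rows_d = np.zeros((4, k_d))
        rows_e = np.zeros((4, k_e))
        mu_vec = np.zeros(4)
        for ti in range(2):
            for wi in range(2):
                r = ti * 2 + wi
                lv = params.loadings[ti, wi, s]
                rows_a[r, ti] = lv * params.a_latent[ti]
                rows_d[r, ti] = lv * params.d_latent[ti]
                rows_e[r, ti] = lv * e_lat[ti]
                rows_a[r, 2 + r] = params.spec_a[ti, wi, s]
                rows_d[r, 2 + r] = params.spec_d[ti, wi, s]
                rows_e[r, 2 + r] = params.spec_e[ti, wi, s]
                mu_vec[r] = params.means[ti, wi, s]
        # PGS paths (pre-causal structural inputs); b1/b2 multiply the
        # observed score sig_s * S_unit
        rows_a[0, 2 + n_spec] = rows_a[1, 2 + n_spec] = params.b1 * sig_s  # wb waves
        rows_a[2, 2 + n_spec] = rows_a[3, 2 + n_spec] = params.b2 * sig_s  # res waves
        rows_a[2, 3 + n_spec] = rows_a[3, 3 + n_spec] = params.b_res
        # simultaneous causal mixing per wave: rows (wb_w, res_w)
        for wi in range(2):
            idx = [wi, 2 + wi]
            rows_a[idx] = t_mix @ rows_a[idx]
            rows_d[idx] = t_mix @ rows_d[idx]
            rows_e[idx] = t_mix @ rows_e[idx]
            mu_vec[idx] = t_mix @ mu_vec[idx]
        full = np.hstack([rows_a, rows_d, rows_e])
        if include_pgs:
            pgs_rows = np.zeros((2, k_a + k_d + k_e))
            pgs_rows[0, 2 + n_spec] = sig_s
            pgs_rows[1, 3 + n_spec] = 1.0
            full = np.vstack([full, pgs_rows])
            mu_vec = np.concatenate([mu_vec, [0.0, 0.0]])
        lam[sex] = full
        mu[sex] = mu_vec
    return Structure(kinds=kinds, phi={"F": phi, "M": phi}, lam=lam, mu=mu)


def default_sexes(zygosity: str, n_siblings: int = 0, sib_sexes=None) -> tuple[str, ...]:
    if zygosity in ("MZM", "DZM"):
        tw = ("M", "M")
    elif zygosity in ("MZF", "DZF"):
        tw = ("F", "F")
    elif zygosity == "DOS":
        tw = ("M", "F")
    else:
        raise ValueError(f"unknown zygosity label {zygosity!r}")
    if sib_sexes is None:
        sib_sexes = ("F",) * n_siblings
    return tw + tuple(sib_sexes)


def implied_moments(
    params: GenerativeParams,
    zygosity: str,
    n_siblings: int = 0,
    sib_sexes=None,
    include_pgs: bool = False,
):
    """Exact model-implied mean vector and covariance matrix.

    Variables per member are ``CORE_VARS`` (+ ``PGS_VARS`` when
    ``include_pgs``) on the continuous core scale; members are ordered
    twin1, twin2, siblings.  Age effects are conditioned out (age at its
    reference value), so compare against data simulated with
    ``age_quad = 0``.
    """
    sexes = default_sexes(zygosity, n_siblings, sib_sexes)
    roles = ("twin1", "twin2") + ("sibling",) * (len(sexes) - 2)
    st = structure_from_params(params, include_pgs=include_pgs)
    return assemble_moments(st, roles, sexes, zygosity)


# ---------------------------------------------------------------------------
# component-level simulation (independent of the analytic assembly)
# ---------------------------------------------------------------------------


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    """Factor L with L L' = cov for PSD (possibly singular) cov."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _sharing_matrix(kind: str, roles, sexes, zygosity) -> np.ndarray:
    n_m = len(roles)
    c = np.eye(n_m)
    for i in range(n_m):
        for j in range(i + 1, n_m):
            rel = relationship(roles[i], roles[j], zygosity)
            c[i, j] = c[j, i] = SHARING[kind]["mz" if rel == "mz" else "half"]
    return c


def _draw_kind(rng, n_fam, cov_within, kind, roles, sexes, zygosity):
    """Draw latent components of one kind for n_fam families."""
    c = _sharing_matrix(kind, roles, sexes, zygosity)
    joint = np.kron(c, cov_within)
    chol = _psd_cholesky(joint)
    z = rng.standard_normal((n_fam, joint.shape[0]))
    draw = z @ chol.T
    return draw.reshape(n_fam, len(roles), cov_within.shape[0])


def _standardize(x: np.ndarray) -> np.ndarray:
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    return (x - m) / s


def simulate_families(
    params: GenerativeParams,
    seed: int,
    include_truth: bool = False,
) -> pd.DataFrame:
    """Simulate a phenotype table of twin-sibling families.

    Returns one row per individual with columns family_id, zygosity, role,
    sex, ages, life-event counts, anxious-depression and well-being sum
    scores at both waves, polygenic scores (plus causal-fraction variants
    of the well-being PGS), ten genetic PCs, and genotyping platform.
    ``include_truth`` appends the latent-scale core phenotypes
    (``true_wellbeing_t1`` ...), which downstream analyses never see but
    oracle tests compare against :func:`implied_moments`.
    """
    rng = np.random.default_rng(seed)
    e_lat = params.e_latent()
    t_mix = _causal_transform(params)

    # family counts per zygosity group
    weights = np.array([params.zygosity_weights.get(z, 0.0) for z in ZYGOSITY_GROUPS], float)
    weights = weights / weights.sum()
    counts = np.floor(weights * params.n_pairs).astype(int)
    for i in np.argsort(-(weights * params.n_pairs - counts)):
        if counts.sum() >= params.n_pairs:
            break
        counts[i] += 1

    phi_a = np.eye(2)
    phi_a[0, 1] = phi_a[1, 0] = params.r_a
    phi_d = np.eye(2)
    phi_d[0, 1] = phi_d[1, 0] = params.r_d
    phi_e = np.eye(2)
    phi_e[0, 1] = phi_e[1, 0] = params.r_e

    records = []
    fam_counter = 0
    for zyg, n_z in zip(ZYGOSITY_GROUPS, counts):
        if n_z == 0:
            continue
        n_sibs = rng.choice(3, size=n_z, p=np.asarray(params.sibling_probs))
        for n_sib in (0, 1, 2):
            n_g_all = int(np.sum(n_sibs == n_sib))
            if n_g_all == 0:
                continue
            sib_sex_draws = rng.choice(["F", "M"], size=(n_g_all, n_sib)) if n_sib else np.empty((n_g_all, 0), dtype=object)
            # vectorize per distinct sibling-sex configuration
            configs = sorted({tuple(row) for row in sib_sex_draws})
            for cfg in configs:
                sel = np.all(sib_sex_draws == np.array(cfg, dtype=object).reshape(1, -1), axis=1) if n_sib else np.ones(n_g_all, bool)
                n_g = int(sel.sum())
                sexes = default_sexes(zyg, n_sib, cfg)
                roles = ("twin1", "twin2") + ("sibling",) * n_sib
                n_m = len(roles)
                lat_a = _draw_kind(rng, n_g, phi_a, "A", roles, sexes, zyg)
                lat_d = _draw_kind(rng, n_g, phi_d, "D", roles, sexes, zyg)
                lat_e = _draw_kind(rng, n_g, phi_e, "E", roles, sexes, zyg)
                spec_a = _draw_kind(rng, n_g, np.eye(4), "A", roles, sexes, zyg)
                spec_d = _draw_kind(rng, n_g, np.eye(4), "D", roles, sexes, zyg)
                spec_e = rng.standard_normal((n_g, n_m, 4))  # E never shared
                pgs = _draw_kind(rng, n_g, np.diag([params.sigma_s2, 1.0, 1.0]), "A", roles, sexes, zyg)

                # compose phenotype cores member by member
                core = np.empty((n_g, n_m, 2, 2))  # (fam, member, trait, wave)
                for m, sex in enumerate(sexes):
                    s = SEX_INDEX[sex]
                    for ti in range(2):
                        latent = (
                            params.a_latent[ti] * lat_a[:, m, ti]
                            + params.d_latent[ti] * lat_d[:, m, ti]
                            + e_lat[ti] * lat_e[:, m, ti]
                        )
                        for wi in range(2):
                            sp = ti * 2 + wi
                            y = (
                                params.loadings[ti, wi, s] * latent
                                + params.spec_a[ti, wi, s] * spec_a[:, m, sp]
                                + params.spec_d[ti, wi, s] * spec_d[:, m, sp]
                                + params.spec_e[ti, wi, s] * spec_e[:, m, sp]
                                + params.means[ti, wi, s]
                            )
                            core[:, m, ti, wi] = y
                    # structural PGS inputs
                    core[:, m, 0, :] += params.b1 * pgs[:, m, 0][:, None]
                    core[:, m, 1, :] += (params.b2 * pgs[:, m, 0] + params.b_res * pgs[:, m, 1])[:, None]
                    # simultaneous causal coupling per wave
                    for wi in range(2):
                        core[:, m, :, wi] = core[:, m, :, wi] @ t_mix.T

                age_base = rng.normal(params.age_mean, params.age_sd, size=n_g)
                pcs = rng.standard_normal((n_g, 10))
                platforms = rng.choice(PLATFORMS, size=n_g)
                sib_age_off = rng.normal(2.0, 3.0, size=(n_g, n_m))
                fam_ids = np.arange(fam_counter, fam_counter + n_g)
                fam_counter += n_g
                for m, (role, sex) in enumerate(zip(roles, sexes)):
                    age1 = age_base + (sib_age_off[:, m] if role == "sibling" else 0.0)
                    rec = {
                        "family_id": fam_ids,
                        "zygosity": zyg,
                        "role": role,
                        "sex": sex,
                        "age_t1": np.round(age1, 1),
                        "age_t2": np.round(age1 + params.age_gap, 1),
                        "platform": platforms,
                        "pgs_wb_raw": pgs[:, m, 0],
                        "pgs_res": pgs[:, m, 1],
                        "pgs_noise": pgs[:, m, 2],
                    }
                    for wi, w in enumerate(WAVES):
                        rec[f"core_wb_{w}"] = core[:, m, 0, wi]
                        rec[f"core_res_{w}"] = core[:, m, 1, wi]
                    for k in range(10):
                        rec[f"pc{k + 1}"] = pcs[:, k]
                    records.append(pd.DataFrame(rec))

    df = pd.concat(records, ignore_index=True)
    df = df.sort_values(["family_id", "role"], kind="stable").reset_index(drop=True)
    n = len(df)

    # small U-shaped age effect on both cores
    for wi, w in enumerate(WAVES):
        agez = (df[f"age_{w}"].to_numpy() - 40.0) / 10.0
        df[f"core_wb_{w}"] += params.age_quad[0] * agez**2
        df[f"core_res_{w}"] += params.age_quad[1] * agez**2

    # life events and anxious-depression per wave
    male = (df["sex"] == "M").to_numpy()
    for wi, w in enumerate(WAVES):
        le = np.minimum(rng.poisson(params.mu_le[wi], size=n), params.le_max[wi])
        z_le = _standardize(le.astype(float))
        ad_z = params.beta_le[wi] * z_le - df[f"core_res_{w}"].to_numpy() + params.ad_male_shift * male
        df[f"life_events_{w}"] = le.astype(float)
        df[f"anxdep_{w}"] = params.ad_mean[wi] + params.ad_sd[wi] * _standardize(ad_z)
        df[f"wellbeing_{w}"] = params.wb_mean[wi] + params.wb_sd[wi] * _standardize(
            df[f"core_wb_{w}"].to_numpy()
        )

    if params.discretize:
        for wi, w in enumerate(WAVES):
            df[f"anxdep_{w}"] = np.clip(np.round(df[f"anxdep_{w}"]), 0, 30)
            df[f"wellbeing_{w}"] = np.clip(np.round(df[f"wellbeing_{w}"]), 5, 35)

    # PGS variants by causal-variant fraction (peak fidelity at 0.5)
    true_pgs = df.pop("pgs_wb_raw").to_numpy()
    noise = df.pop("pgs_noise").to_numpy()
    for frac, rho in PGS_FRACTIONS.items():
        df[f"pgs_wb_f{frac}"] = rho * true_pgs + math.sqrt(1.0 - rho**2) * noise
    df["pgs_wb"] = df["pgs_wb_f0.5"]

    # completely-at-random whole-wave missingness
    for rate, w in ((params.missing_t1, "t1"), (params.missing_t2, "t2")):
        if rate > 0:
            miss = rng.random(n) < rate
            for col in (f"life_events_{w}", f"anxdep_{w}", f"wellbeing_{w}"):
                df.loc[miss, col] = np.nan

    if include_truth:
        for w in WAVES:
            df[f"true_wellbeing_{w}"] = df[f"core_wb_{w}"]
            df[f"true_resilience_{w}"] = df[f"core_res_{w}"]
    df = df.drop(columns=[f"core_wb_{w}" for w in WAVES] + [f"core_res_{w}" for w in WAVES])

    front = [
        "family_id", "zygosity", "role", "sex", "age_t1", "age_t2",
        "life_events_t1", "life_events_t2", "anxdep_t1", "anxdep_t2",
        "wellbeing_t1", "wellbeing_t2", "pgs_wb", "pgs_res",
    ]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]


def simulate_mrdoc_pairs(
    params: GenerativeParams | MRDoCTruth,
    n_mz: int,
    n_dz: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate (PGS, exposure, outcome) twin-pair data under MR-DoC truth.

    Cross-twin sharing: PGS and A components 1 (MZ) / 0.5 (DZ); E
    components unshared.  Returns one row per individual with columns
    family_id, zygosity (MZ/DZ), role, sex, pgs, exposure, outcome.
    """
    truth = params.mrdoc if isinstance(params, GenerativeParams) else params
    truth.validate()
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for zyg, n_g, c in (("MZ", n_mz, 1.0), ("DZ", n_dz, 0.5)):
        if n_g == 0:
            continue
        share = np.array([[1.0, c], [c, 1.0]])
        s = _psd_cholesky(truth.sigma_s2 * share)
        s_draw = rng.standard_normal((n_g, 2)) @ s.T
        r_a = np.array([[1.0, truth.r_a], [truth.r_a, 1.0]])
        a_joint = _psd_cholesky(np.kron(share, r_a))
        a_draw = (rng.standard_normal((n_g, 4)) @ a_joint.T).reshape(n_g, 2, 2)
        r_e = np.array([[1.0, truth.r_e], [truth.r_e, 1.0]])
        e_chol = _psd_cholesky(r_e)
        e_draw = np.einsum("ntk,jk->ntj", rng.standard_normal((n_g, 2, 2)), e_chol)
        x = truth.b1 * s_draw + truth.a_x * a_draw[:, :, 0] + truth.e_x * e_draw[:, :, 0]
        y = truth.g1 * x + truth.b2 * s_draw + truth.a_y * a_draw[:, :, 1] + truth.e_y * e_draw[:, :, 1]
        for m, role in enumerate(("twin1", "twin2")):
            frames.append(
                pd.DataFrame(
                    {
                        "family_id": np.arange(offset, offset + n_g),
                        "zygosity": zyg,
                        "role": role,
                        "sex": "F",
                        "pgs": s_draw[:, m],
                        "exposure": x[:, m],
                        "outcome": y[:, m],
                    }
                )
            )
        offset += n_g
    if not frames:
        return pd.DataFrame(columns=["family_id", "zygosity", "role", "sex", "pgs", "exposure", "outcome"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["family_id", "role"], kind="stable").reset_index(drop=True)
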