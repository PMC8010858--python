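"""Data contracts, configuration and the three-part analysis pipeline.

Part 1: descriptives, phenotypic and twin/twin-sibling correlations.
Part 2: polygenic-score prediction of both traits at both waves.
Part 3: causality -- change-score regressions, the bivariate
common-pathway twin model (with the sex/D model ladder), longitudinal
bivariate models, MZ intrapair differences, and MR-DoC with the rE
sensitivity grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import GenerativeParams
from .phenotypes import age_effects, resilience_scores, zscore
from .pgs import pgs_regression, select_best_variant
from .screens import (
    change_regression,
    change_scores,
    mz_difference_regression,
    mz_longitudinal_difference_regression,
    mz_pair_differences,
)
from .sem import (
    FamilyData,
    choose_model_family,
    common_pathway_ladder,
    common_pathway_spec,
    decompose_latent,
    fit as sem_fit,
    lrt,
    longitudinal_bivariate_spec,
    twin_group_correlations,
)
from .mrdoc import DEFAULT_RE_GRID, fit_mrdoc, rE_sensitivity

logger = logging.getLogger("twinwell")

__all__ = ["PhenotypeTable", "RunConfig", "read_phenotypes", "write_phenotypes", "run_pipeline"]

MANDATORY_COLUMNS = [
    "family_id", "zygosity", "role", "sex",
    "life_events_t1", "life_events_t2", "anxdep_t1", "anxdep_t2",
    "wellbeing_t1", "wellbeing_t2",
]
KNOWN_COLUMNS = MANDATORY_COLUMNS + [
    "age_t1", "age_t2", "pgs_wb", "pgs_res", "platform",
    *[f"pc{i}" for i in range(1, 11)],
    "resilience_t1", "resilience_t2",
]
ZYGOSITIES = {"MZM", "DZM", "MZF", "DZF", "DOS"}
WAVES = ("t1", "t2")
ALPHA = 0.001


@dataclass
class PhenotypeTable:
    """Validated per-individual phenotype table."""

    frame: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.frame)


def _validate_families(df: pd.DataFrame) -> None:
    g = df.groupby("family_id")
    bad_zyg = g["zygosity"].nunique()
    if (bad_zyg > 1).any():
        fams = bad_zyg[bad_zyg > 1].index.tolist()[:5]
        raise ValueError(f"inconsistent zygosity within family: {fams}")
    unknown = set(df["zygosity"]) - ZYGOSITIES
    if unknown:
        raise ValueError(f"unknown zygosity labels: {sorted(unknown)}")
    twins = df[df["role"].isin(["twin1", "twin2"])]
    counts = twins.groupby("family_id")["role"].nunique()
    dup = twins.groupby(["family_id", "role"]).size()
    if (dup > 1).any():
        raise ValueError("more than one member per twin role in a family")
    for zyg, same in (("MZM", True), ("MZF", True), ("DOS", False)):
        sub = twins[twins["zygosity"] == zyg]
        wide = sub.pivot(index="family_id", columns="role", values="sex")
        if "twin1" in wide and "twin2" in wide:
            both = wide.dropna()
            ok = (both["twin1"] == both["twin2"]) if same else (both["twin1"] != both["twin2"])
            if not ok.all():
                kind = "equal" if same else "opposite"
                raise ValueError(f"{zyg} twin pairs must have {kind} sexes: families {both.index[~ok].tolist()[:5]}")
    for w in WAVES:
        le = df[f"life_events_{w}"]
        if (le.dropna() < 0).any():
            raise ValueError(f"negative life-event counts at {w}")


def read_phenotypes(path) -> PhenotypeTable:
    """Read and validate the standard phenotype CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    warnings_ = []
    extra = [c for c in df.columns if c not in KNOWN_COLUMNS and not c.startswith(("pgs_", "true_"))]
    if extra:
        msg = f"unknown columns preserved: {extra}"
        warnings_.append(msg)
        logger.warning(msg)
    numeric = [c for c in df.columns if c not in ("zygosity", "role", "sex", "platform")]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="raise")
    _validate_families(df)
    n_miss = df[MANDATORY_COLUMNS[4:]].isna().mean().round(3).to_dict()
    logger.info("read %d rows, %d families; missingness %s", len(df), df["family_id"].nunique(), n_miss)
    return PhenotypeTable(frame=df, warnings=warnings_)


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame.to_csv(path, sep=sep, index=False)


@dataclass
class RunConfig:
    """Pipeline configuration; every stochastic step derives from ``seed``."""

    input: str | None = None
    seed: int = 0
    output_dir: str = "twinwell_out"
    run_part1: bool = True
    run_part2: bool = True
    run_part3: bool = True
    fit_sex_ladder: bool = False  # full model ladder is expensive; final model always fitted
    fit_longitudinal: bool = True
    fit_mrdoc_model: bool = True
    re_grid: tuple = DEFAULT_RE_GRID
    n_starts: int = 2
    working: str = "exchangeable"
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def prepare(frame: pd.DataFrame, working: str = "independence") -> pd.DataFrame:
    """Append per-wave resilience scores (missing where inputs are)."""
    df = frame.copy()
    for w in WAVES:
        rs = resilience_scores(df[f"anxdep_{w}"], df[f"life_events_{w}"], df["family_id"], working=working)
        df[f"resilience_{w}"] = rs.scores.to_numpy()
    return df


def _zscore_cols(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = zscore(out[c]).to_numpy()
    return out


def _gee_summary(fit) -> dict:
    return {
        "slope": float(fit.params.iloc[-1]),
        "se": float(fit.se.iloc[-1]),
        "z": float(fit.zvalues.iloc[-1]),
        "p": float(fit.pvalues.iloc[-1]),
        "n": fit.n_obs,
        "n_clusters": fit.n_clusters,
    }


def _part1(df: pd.DataFrame, cfg: RunConfig) -> dict:
    desc = {}
    for col in ("anxdep_t1", "anxdep_t2", "life_events_t1", "life_events_t2", "wellbeing_t1", "wellbeing_t2"):
        s = df[col].dropna()
        desc[col] = {"n": int(len(s)), "mean": float(s.mean()), "sd": float(s.std())}
    for w in WAVES:
        for sex in ("M", "F"):
            s = df.loc[df["sex"] == sex, f"resilience_{w}"].dropna()
            desc[f"resilience_{w}_{sex}"] = {"n": int(len(s)), "mean": float(s.mean()), "sd": float(s.std())}
    pheno = df[["wellbeing_t1", "wellbeing_t2", "resilience_t1", "resilience_t2"]]
    phen_corr = pheno.corr().round(4)
    variables = ["resilience_t1", "wellbeing_t1"]
    tg = twin_group_correlations(df, variables, n_starts=1, seed=cfg.seed)
    r_mz, r_dz = [], []
    for zyg, info in tg.groups.items():
        if not info.get("available"):
            continue
        diag = [info["cross_twin"].loc[v, v] for v in variables]
        (r_mz if zyg.startswith("MZ") else r_dz).extend(diag)
    advice = choose_model_family(r_mz, r_dz) if r_mz and r_dz else None
    age = {}
    if "age_t1" in df.columns:
        for w in WAVES:
            fitres = age_effects(df[f"wellbeing_{w}"], df[f"age_{w}"], df["family_id"], working=cfg.working)
            age[f"wellbeing_{w}"] = {k: float(v) for k, v in fitres.params.items()}
    return {
        "descriptives": desc,
        "phenotypic_correlations": phen_corr.to_dict(),
        "twin_correlations": {
            z: (info["cross_twin"].round(4).to_dict() if info.get("available") else "unavailable")
            for z, info in tg.groups.items()
        },
        "model_family_advice": advice,
        "age_effects": age,
    }


def _part2(df: pd.DataFrame, cfg: RunConfig) -> dict:
    cov_cols = [c for c in ["age_t1", "sex", "platform", *[f"pc{i}" for i in range(1, 11)]] if c in df.columns]
    covs = df[cov_cols].copy() if cov_cols else None
    if covs is not None and "age_t1" in covs:
        covs["age2_t1"] = (covs["age_t1"] - 40.0) ** 2
    out = {}
    for pgs_col in ("pgs_wb", "pgs_res"):
        if pgs_col not in df.columns:
            continue
        for pheno in ("wellbeing", "resilience"):
            for w in WAVES:
                res = pgs_regression(df[f"{pheno}_{w}"], df[pgs_col], covs, df["family_id"])
                out[f"{pgs_col}->{pheno}_{w}"] = {
                    "coefficient": res.coefficient,
                    "se": res.se,
                    "p": res.pvalue,
                    "delta_r2_pct": 100.0 * res.delta_r2,
                    "significant": res.significant,
                }
    variant_cols = [c for c in df.columns if c.startswith("pgs_wb_f")]
    if variant_cols:
        best, table = select_best_variant(df["wellbeing_t2"], df[variant_cols], covs, df["family_id"])
        out["best_wb_variant"] = {"chosen": best, "delta_r2_pct": (100 * table["delta_r2"]).round(3).to_dict()}
    return out


def _part3(df: pd.DataFrame, cfg: RunConfig) -> dict:
    out: dict = {}
    # change scores, both directions
    d_res = change_scores(df["resilience_t1"], df["resilience_t2"])
    d_wb = change_scores(df["wellbeing_t1"], df["wellbeing_t2"])
    out["change_scores"] = {
        "wb_on_res": _gee_summary(change_regression(d_wb, d_res, df["family_id"], working=cfg.working)),
        "res_on_wb": _gee_summary(change_regression(d_res, d_wb, df["family_id"], working=cfg.working)),
    }

    # twin models on standardized scores
    z = _zscore_cols(df, ["wellbeing_t1", "wellbeing_t2", "resilience_t1", "resilience_t2"])
    sem_vars = ["wellbeing_t1", "wellbeing_t2", "resilience_t1", "resilience_t2"]
    data = FamilyData.from_frame(z, sem_vars)
    ladder_out = {}
    if cfg.fit_sex_ladder:
        ladder = common_pathway_ladder()
        fits = {}
        for key, spec in ladder.items():
            fits[key] = sem_fit(spec, data, n_starts=1, seed=cfg.seed, compute_se=False)
        for pair in (("I", "II"), ("I", "III"), ("III", "IV")):
            d, ddf, p = lrt(fits[pair[0]], fits[pair[1]])
            ladder_out[f"{pair[1]}_vs_{pair[0]}"] = {"delta_m2ll": d, "delta_df": ddf, "p": p}
        ladder_out["m2ll"] = {k: f.m2ll for k, f in fits.items()}
        ladder_out["aic"] = {k: f.aic for k, f in fits.items()}
    final_spec = common_pathway_spec(
        include_d=False, sex_specific_latent=False, sex_specific_specific=True, name="final_AE"
    )
    final = sem_fit(final_spec, data, n_starts=cfg.n_starts, seed=cfg.seed, compute_se=False)
    dec = decompose_latent(final)
    out["common_pathway"] = {
        "ladder": ladder_out,
        "m2ll": final.m2ll,
        "aic": final.aic,
        "converged": final.converged,
        "h2_latent": {"wellbeing": dec.h2[0], "resilience": dec.h2[1]},
        "e2_latent": {"wellbeing": dec.e2[0], "resilience": dec.e2[1]},
        "r_g": dec.r_g,
        "r_e": dec.r_e,
        "covariance_decomposition": {
            "genetic_pct": dec.genetic_covariance_pct,
            "environmental_pct": dec.environmental_covariance_pct,
        },
    }

    if cfg.fit_longitudinal:
        long_out = {}
        for var_a, var_b in (("resilience_t1", "wellbeing_t2"), ("wellbeing_t1", "resilience_t2")):
            spec = longitudinal_bivariate_spec(var_a, var_b)
            ldata = FamilyData.from_frame(z, [var_a, var_b])
            full = sem_fit(spec, ldata, n_starts=cfg.n_starts, seed=cfg.seed, compute_se=False)
            res_ra = sem_fit(spec.fix(r_a=0.0), ldata, n_starts=cfg.n_starts, seed=cfg.seed, compute_se=False)
            res_re = sem_fit(spec.fix(r_e=0.0), ldata, n_starts=cfg.n_starts, seed=cfg.seed, compute_se=False)
            long_out[f"{var_a}__{var_b}"] = {
                "r_a": full.estimates["r_a"],
                "r_e": full.estimates["r_e"],
                "p_drop_ra": lrt(full, res_ra)[2],
                "p_drop_re": lrt(full, res_re)[2],
            }
        out["longitudinal"] = long_out

    mz_out = {}
    for w in WAVES:
        dx = mz_pair_differences(df[df["zygosity"].isin(["MZM", "MZF"])], "wellbeing", w)
        dy = mz_pair_differences(df[df["zygosity"].isin(["MZM", "MZF"])], "resilience", w)
        reg = mz_difference_regression(dy, dx)
        mz_out[f"res_on_wb_{w}"] = {"slope": reg.slope, "se": reg.se, "r2": reg.r2, "p": reg.pvalue, "n_pairs": reg.n_pairs}
    mz_long = mz_longitudinal_difference_regression(df[df["zygosity"].isin(["MZM", "MZF"])], "resilience", "wellbeing")
    mz_out["longitudinal_res_on_wb"] = {
        "slope": mz_long.slope, "se": mz_long.se, "r2": mz_long.r2, "p": mz_long.pvalue, "n_pairs": mz_long.n_pairs,
    }
    out["mz_differences"] = mz_out

    if cfg.fit_mrdoc_model and "pgs_wb" in df.columns:
        mr_out = {}
        for w in WAVES:
            pairs = z[z["role"].isin(["twin1", "twin2"])].copy()
            pairs["zygosity"] = np.where(pairs["zygosity"].isin(["MZM", "MZF"]), "MZ", "DZ")
            pairs = pairs.rename(columns={"pgs_wb": "pgs", f"wellbeing_{w}": "exposure", f"resilience_{w}": "outcome"})
            pairs = pairs[["family_id", "zygosity", "role", "sex", "pgs", "exposure", "outcome"]]
            res = fit_mrdoc(pairs, rE_fixed=0.0, n_starts=cfg.n_starts, seed=cfg.seed)
            entry = {
                "g1": res.estimates["g1"],
                "b1": res.estimates["b1"],
                "b2": res.estimates["b2"],
                "explained_variance_pct": res.explained_variance,
                "p_g1": res.lrt_g1[2],
                "weak_instrument": res.weak_instrument,
            }
            if len(cfg.re_grid) > 1:
                grid = rE_sensitivity(pairs, grid=cfg.re_grid, n_starts=1, seed=cfg.seed)
                entry["re_sensitivity"] = grid.drop(columns="error").round(5).to_dict(orient="records")
            mr_out[w] = entry
        out["mrdoc"] = mr_out
    return out


def run_pipeline(config: RunConfig, frame: pd.DataFrame | None = None) -> dict:
    """Execute the configured stages and write the report bundle.

    Stage failures are isolated: a failing part is reported with its
    error and the remaining parts still run (parts needing resilience
    scores are skipped if preparation fails).
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    if frame is None:
        if config.input is None:
            raise ValueError("config.input is required when no frame is passed")
        frame = read_phenotypes(config.input).frame
    report: dict = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    try:
        df = prepare(frame)
        report["prepare"] = {"n_rows": len(df), "n_families": int(df["family_id"].nunique())}
    except Exception as exc:
        report["prepare"] = {"error": str(exc)}
        report["skipped"] = "all stages (preparation failed)"
        return _write_report(report, config)

    for name, runner, enabled in (
        ("part1_phenotypic", _part1, config.run_part1),
        ("part2_pgs", _part2, config.run_part2),
        ("part3_causality", _part3, config.run_part3),
    ):
        if not enabled:
            continue
        try:
            report[name] = runner(df, config)
        except Exception as exc:
            logger.exception("stage %s failed", name)
            report[name] = {"error": str(exc)}
    return _write_report(report, config)


def _render_text(report: dict) -> str:
    lines = [f"twinwell {report['package_version']}  (seed {report['seed']}, config {report['config_digest']})"]
    p3 = report.get("part3_causality", {})
    cp = p3.get("common_pathway") if isinstance(p3, dict) else None
    if cp and "covariance_decomposition" in cp:
        lines.append("")
        lines.append("Bivariate common-pathway model (AE, latent part equal across sexes)")
        lines.append(
            f"  latent h2: well-being {100 * cp['h2_latent']['wellbeing']:.1f}%  "
            f"resilience {100 * cp['h2_latent']['resilience']:.1f}%"
        )
        lines.append(f"  rG = {cp['r_g']:.2f}  rE = {cp['r_e']:.2f}")
        cd = cp["covariance_decomposition"]
        lines.append(
            f"  covariance: {cd['genetic_pct']:.1f}% genetic / {cd['environmental_pct']:.1f}% environmental"
        )
    if isinstance(p3, dict) and "mrdoc" in p3:
        lines.append("")
        lines.append("MR-DoC (rE fixed at 0):")
        for w, entry in p3["mrdoc"].items():
            lines.append(
                f"  {w}: g1 = {entry['g1']:.3f}, explained variance {entry['explained_variance_pct']:.1f}%"
                f" (p[g1=0] = {entry['p_g1']:.2g})"
            )
    return "\n".join(lines) + "\n"


def _write_report(report: dict, config: RunConfig) -> dict:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=default))
    (out / "report.txt").write_text(_render_text(report))
    return report


def simulate_to_files(params: GenerativeParams, seed: int, out_dir) -> Path:
    """Simulate a dataset and write the phenotype CSV + ground-truth JSON."""
    from .simulate import simulate_families

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = simulate_families(params, seed=seed)
    csv_path = out / "phenotypes.csv"
    write_phenotypes(df, csv_path)
    truth = {"seed": seed, "params": params.to_dict()}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))
    return csv_path
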