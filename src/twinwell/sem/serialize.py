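"""JSON round-tripping for model specs and fit reports.

Specs are rebuilt from their builder name and options (closures cannot
be pickled portably), plus any parameters fixed afterwards via
``spec.fix``; fit reports serialize estimates, fit indices and
convergence diagnostics, and a ladder of fits renders as a text table
with the conventional columns (-2LL, df, AIC, delta -2LL, delta df, p).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .engine import FitResult, ModelSpec, lrt

__all__ = ["spec_to_json", "spec_from_json", "fit_to_dict", "ladder_table"]

_BUILDERS: dict[str, callable] = {}


def _register(name):
    def deco(fn):
        _BUILDERS[name] = fn
        return fn

    return deco


def _builders():
    # populated lazily to avoid an import cycle with specs.py
    if not _BUILDERS:
        from . import specs

        _BUILDERS.update(
            common_pathway_spec=specs.common_pathway_spec,
            longitudinal_bivariate_spec=specs.longitudinal_bivariate_spec,
            mrdoc_spec=specs.mrdoc_spec,
            saturated_spec=specs.saturated_spec,
            correlation_spec=specs.correlation_spec,
        )
    return _BUILDERS


def spec_to_json(spec: ModelSpec) -> str:
    if not hasattr(spec, "build_args"):
        raise ValueError(f"spec {spec.name!r} was not made by a registered builder")
    builder, options = spec.build_args
    fixed = {p.label: p.fixed for p in spec.params if p.fixed is not None}
    # builder-level fixed parameters (e.g. mrdoc r_e) are reproduced by the
    # options; re-fixing them is harmless and keeps this simple
    payload = {
        "builder": builder,
        "options": options,
        "fixed": fixed,
        "name": spec.name,
        "parent": spec.parent,
    }
    return json.dumps(payload, indent=2)


def spec_from_json(text: str) -> ModelSpec:
    payload = json.loads(text)
    builder = _builders()[payload["builder"]]
    options = dict(payload["options"])
    # tuple-typed options arrive as lists
    options = {k: tuple(v) if isinstance(v, list) else v for k, v in options.items()}
    spec = builder(**options)
    fixed = {k: v for k, v in payload.get("fixed", {}).items() if spec._by_label[k].fixed is None}
    if fixed:
        spec = spec.fix(**fixed)
    spec.name = payload.get("name", spec.name)
    spec.parent = payload.get("parent", spec.parent)
    return spec


def fit_to_dict(fit: FitResult) -> dict:
    return {
        "model": fit.spec.name,
        "estimates": {k: float(v) for k, v in fit.estimates.items()},
        "se": {k: (None if not np.isfinite(v) else float(v)) for k, v in fit.se.items()},
        "m2ll": float(fit.m2ll),
        "n_free": fit.n_free,
        "aic": float(fit.aic),
        "converged": bool(fit.converged),
        "grad_norm": float(fit.grad_norm),
        "boundary": list(fit.boundary),
        "n_families": fit.n_families,
        "n_obs": fit.n_obs,
    }


def ladder_table(fits: dict[str, FitResult], comparisons: list[tuple[str, str]]) -> pd.DataFrame:
    """Model-comparison table: one row per model with -2LL, df (free
    parameters), AIC, and for each listed (full, nested) comparison the
    delta -2LL, delta df and chi-square p of the nested model."""
    rows = {}
    for label, fit in fits.items():
        rows[label] = {
            "model": label,
            "vs": "",
            "-2LL": fit.m2ll,
            "df": fit.n_free,
            "AIC": fit.aic,
            "d-2LL": np.nan,
            "ddf": np.nan,
            "p": np.nan,
        }
    for full_label, nested_label in comparisons:
        d, ddf, p = lrt(fits[full_label], fits[nested_label], force=True)
        rows[nested_label].update({"vs": full_label, "d-2LL": d, "ddf": ddf, "p": p})
    return pd.DataFrame(rows.values()).set_index("model")
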