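"""FIML structural-equation engine and model zoo for twin-sibling data."""

from .engine import (
    ConvergenceError,
    FamilyData,
    FitResult,
    ModelSpec,
    Param,
    Structure,
    assemble_moments,
    check_identification,
    fit,
    lrt,
    lrt_from_values,
    minus2_loglik,
)
from .specs import (
    common_pathway_ladder,
    common_pathway_spec,
    correlation_spec,
    longitudinal_bivariate_spec,
    mrdoc_spec,
    saturated_spec,
)
from .serialize import fit_to_dict, ladder_table, spec_from_json, spec_to_json
from .analysis import (
    GroupCorrelations,
    VarianceDecomposition,
    choose_model_family,
    covariance_shares,
    decompose_latent,
    solve_rg_from_share,
    twin_group_correlations,
)


def expected_moments(spec, theta, roles=("twin1", "twin2"), sexes=("F", "F"), zygosity="MZF"):
    """Model-implied mean vector and covariance for one family layout.

    ``theta`` may be a free-parameter vector or a full label->value dict.
    """
    import numpy as np

    if not isinstance(theta, dict):
        theta = spec.theta_dict(np.asarray(theta, float))
    return spec.family_moments(theta, tuple(roles), tuple(sexes), zygosity)


__all__ = [
    "ConvergenceError",
    "FamilyData",
    "FitResult",
    "ModelSpec",
    "Param",
    "Structure",
    "assemble_moments",
    "check_identification",
    "fit",
    "lrt",
    "lrt_from_values",
    "minus2_loglik",
    "expected_moments",
    "common_pathway_ladder",
    "common_pathway_spec",
    "correlation_spec",
    "longitudinal_bivariate_spec",
    "mrdoc_spec",
    "saturated_spec",
    "fit_to_dict",
    "ladder_table",
    "spec_from_json",
    "spec_to_json",
    "GroupCorrelations",
    "VarianceDecomposition",
    "choose_model_family",
    "covariance_shares",
    "decompose_latent",
    "solve_rg_from_share",
    "twin_group_correlations",
]
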