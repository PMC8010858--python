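"""Genetically informed causality screens.

Two falsification designs for a causal hypothesis between traits measured
in twins:

* **Within-subject change scores** -- an individual's change from wave 1
  to wave 2 in one trait regressed on the parallel change in the other.
  Stable confounders (including the whole genotype) cancel in the
  difference, so a nonzero slope is consistent with causation while a
  null slope speaks against it.
* **MZ intrapair differences** -- the difference between genetically
  identical co-twins in one trait regressed on their difference in the
  other.  Genetic and shared-environmental confounding cancel within MZ
  pairs; only unique-environment pathways (including a true causal path)
  remain.

Both screens can only falsify, not prove, causation: nonshared
environmental confounders survive the differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import GEEFit, gee_fit

__all__ = [
    "PairDifference",
    "DifferenceRegression",
    "change_scores",
    "change_regression",
    "mz_pair_differences",
    "mz_difference_regression",
    "mz_longitudinal_difference_regression",
]

MZ_LABELS = ("MZM", "MZF", "MZ")


def change_scores(phenotype_t1, phenotype_t2) -> pd.Series:
    """Per-individual change T2 - T1; missing where either wave is missing."""
    t1 = pd.Series(np.asarray(phenotype_t1, float))
    t2 = pd.Series(np.asarray(phenotype_t2, float))
    if len(t1) != len(t2):
        raise ValueError("waves must have equal length")
    return t2 - t1


def change_regression(delta_y, delta_x, clusters, working: str = "exchangeable") -> GEEFit:
    """Cluster-robust regression of one change score on another.

    Clustering is by family: both members of a twin pair contribute
    individual change scores.
    """
    delta_x = np.asarray(delta_x, float)
    x = np.column_stack([np.ones_like(delta_x), delta_x])
    return gee_fit(delta_y, x, clusters, working=working, names=["const", "slope"])


@dataclass
class PairDifference:
    """Intrapair (twin1 - twin2) differences for complete MZ pairs."""

    values: pd.Series  # indexed by family_id
    trait: str
    n_excluded: int  # pairs with an incomplete member

    def __len__(self):
        return len(self.values)


def mz_pair_differences(families: pd.DataFrame, trait: str, wave: str | None = None) -> PairDifference:
    """Twin1 - twin2 differences on ``trait`` (column ``{trait}_{wave}`` if
    a wave is given) for MZ pairs with both members observed.

    Non-MZ families are filtered out with a warning; incomplete pairs are
    excluded and counted.
    """
    col = f"{trait}_{wave}" if wave else trait
    if col not in families.columns:
        raise KeyError(f"no column {col!r}")
    non_mz = ~families["zygosity"].isin(MZ_LABELS)
    if non_mz.any():
        warnings.warn(
            f"{families.loc[non_mz, 'family_id'].nunique()} non-MZ families filtered out",
            stacklevel=2,
        )
    mz = families[~non_mz]
    twins = mz[mz["role"].isin(["twin1", "twin2"])]
    wide = twins.pivot(index="family_id", columns="role", values=col)
    for r in ("twin1", "twin2"):
        if r not in wide:
            wide[r] = np.nan
    complete = wide["twin1"].notna() & wide["twin2"].notna()
    diffs = (wide["twin1"] - wide["twin2"])[complete]
    return PairDifference(values=diffs, trait=col, n_excluded=int((~complete).sum()))


@dataclass
class DifferenceRegression:
    """OLS of one intrapair difference on another (intercept included)."""

    slope: float
    se: float
    tvalue: float
    pvalue: float
    r2: float
    n_pairs: int
    degenerate: bool = False


def mz_difference_regression(delta_y: PairDifference, delta_x: PairDifference) -> DifferenceRegression:
    """Regress one MZ intrapair difference on another.

    Standard OLS with intercept: twin ordering is arbitrary, so the
    intercept's expectation is zero and it simply absorbs finite-sample
    asymmetry.  All reported statistics are invariant to relabeling
    twin1/twin2 within pairs.
    """
    joined = pd.concat({"y": delta_y.values, "x": delta_x.values}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.allclose(joined["x"], 0) or np.allclose(joined["y"], joined["y"].iloc[0]):
        return DifferenceRegression(np.nan, np.nan, np.nan, np.nan, np.nan, len(joined), degenerate=True)
    xmat = sm.add_constant(joined["x"].to_numpy())
    res = sm.OLS(joined["y"].to_numpy(), xmat).fit()
    return DifferenceRegression(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        tvalue=float(res.tvalues[1]),
        pvalue=float(res.pvalues[1]),
        r2=float(res.rsquared),
        n_pairs=len(joined),
    )


def mz_longitudinal_difference_regression(
    families: pd.DataFrame,
    trait_y: str,
    trait_x: str,
    waves: tuple[str, str] = ("t1", "t2"),
) -> DifferenceRegression:
    """MZ intrapair differences of within-individual change scores.

    Computes per-individual changes (wave2 - wave1) for both traits, then
    the twin1 - twin2 difference of those changes in complete MZ pairs,
    then the difference-on-difference OLS.
    """
    fam = families.copy()
    for trait in (trait_y, trait_x):
        fam[f"_change_{trait}"] = change_scores(fam[f"{trait}_{waves[0]}"], fam[f"{trait}_{waves[1]}"])
    dy = mz_pair_differences(fam, f"_change_{trait_y}")
    dx = mz_pair_differences(fam, f"_change_{trait_x}")
    return mz_difference_regression(dy, dx)
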