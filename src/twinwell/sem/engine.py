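"""Full-information maximum-likelihood engine for multivariate-normal family data.

The engine evaluates Gaussian likelihoods on families whose members are
related through latent variance components.  Each latent component has a
*kind* (A: additive genetic, D: dominance, C: shared environment, E: unique
environment) and the kind determines how the component correlates between
two family members:

====  ==========  =====================================
kind  MZ co-twin  DZ co-twin / twin-sibling / siblings
====  ==========  =====================================
A     1.0         0.5
D     1.0         0.25
C     1.0         1.0
E     0.0         0.0
====  ==========  =====================================

A :class:`ModelSpec` maps a free-parameter vector to model-implied moments
for an arbitrary family (any member count, any mix of sexes).  Missing
entries are handled by row/column deletion of the implied moments (FIML).
Families sharing the same zygosity, member layout, sex configuration and
missingness pattern are grouped so each likelihood evaluation costs one
small Cholesky factorization per distinct pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import chi2

__all__ = [
    "SHARING",
    "Structure",
    "assemble_moments",
    "relationship",
    "Param",
    "ModelSpec",
    "LatentModelSpec",
    "DirectModelSpec",
    "FamilyData",
    "FitResult",
    "minus2_loglik",
    "fit",
    "lrt",
    "lrt_from_values",
    "check_identification",
]

#: cross-member correlation scaling per latent kind and relationship class
SHARING = {
    "A": {"mz": 1.0, "half": 0.5},
    "D": {"mz": 1.0, "half": 0.25},
    "C": {"mz": 1.0, "half": 1.0},
    "E": {"mz": 0.0, "half": 0.0},
}

MZ_ZYGOSITIES = frozenset({"MZM", "MZF", "MZ"})
TWIN_ROLES = frozenset({"twin1", "twin2"})

_LOG_2PI = math.log(2.0 * math.pi)


def relationship(role_i: str, role_j: str, zygosity: str) -> str:
    """Relationship class of two distinct family members.

    MZ co-twins are genetically identical; every other within-family pair
    (DZ co-twins, twin-sibling, sibling-sibling) shares on average half of
    the segregating genes.
    """
    if zygosity in MZ_ZYGOSITIES and role_i in TWIN_ROLES and role_j in TWIN_ROLES:
        return "mz"
    return "half"


@dataclass
class Param:
    """One named model parameter."""

    label: str
    start: float
    lower: float = -np.inf
    upper: float = np.inf
    fixed: float | None = None  # when set, the parameter is not optimized

    @property
    def is_free(self) -> bool:
        return self.fixed is None


@dataclass
class Structure:
    """Implied-moment ingredients produced by a LatentModelSpec at one theta.

    ``phi`` maps sex -> latent kind -> within-person covariance among the
    latents of that kind (unit diagonal for correlation-parameterized
    blocks).  ``lam`` and ``mu`` map sex ('M'/'F') -> loading matrix
    (p x K) and mean vector (p,), with latent columns ordered by
    ``kinds``.  For a cross-sex pair (DOS twins, brother-sister) the
    engine uses the average of the female and male phi blocks; when the
    latent structure is not sex-specific the blocks coincide and the
    average is a no-op.
    """

    kinds: list[tuple[str, int]]
    phi: dict[str, dict[str, np.ndarray]]
    lam: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]


def assemble_moments(
    st: "Structure",
    roles: tuple[str, ...],
    sexes: tuple[str, ...],
    zygosity: str,
    block_cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble full-family implied moments by path tracing.

    Cross-member blocks scale each latent kind's covariance by the
    relationship sharing coefficient; cross-sex pairs average the
    female/male phi blocks (a no-op unless the latent structure is
    sex-specific).  ``block_cache`` memoizes the loading products within
    one parameter evaluation: distinct family layouts reuse the same
    (sex_i, sex_j, relationship) blocks.
    """
    n_m = len(roles)
    lams = [st.lam[s] for s in sexes]
    p = lams[0].shape[0]
    mu = np.concatenate([st.mu[s] for s in sexes])
    sigma = np.empty((n_m * p, n_m * p))
    if block_cache is None:
        block_cache = {}

    def pair_phi(sex_i, sex_j):
        if sex_i == sex_j:
            return st.phi[sex_i]
        return {k: 0.5 * (st.phi[sex_i][k] + st.phi[sex_j][k]) for k, _ in st.kinds}

    def within_block(s):
        key = ("W", s)
        if key not in block_cache:
            phi_within = linalg.block_diag(*[st.phi[s][k] for k, _ in st.kinds])
            block_cache[key] = st.lam[s] @ phi_within @ st.lam[s].T
        return block_cache[key]

    def cross_block(s_i, s_j, rel):
        key = ("X", s_i, s_j, rel)
        if key not in block_cache:
            phi_ij = pair_phi(s_i, s_j)
            blocks = [SHARING[k]["mz" if rel == "mz" else "half"] * phi_ij[k] for k, _ in st.kinds]
            phi_cross = linalg.block_diag(*blocks)
            block_cache[key] = st.lam[s_i] @ phi_cross @ st.lam[s_j].T
        return block_cache[key]

    for i in range(n_m):
        si = slice(i * p, (i + 1) * p)
        sigma[si, si] = within_block(sexes[i])
        for j in range(i + 1, n_m):
            rel = relationship(roles[i], roles[j], zygosity)
            sj = slice(j * p, (j + 1) * p)
            block = cross_block(sexes[i], sexes[j], rel)
            sigma[si, sj] = block
            sigma[sj, si] = block.T
    return mu, sigma


class ModelSpec:
    """Base class: a named, parameterized family model.

    Subclasses implement :meth:`family_moments` returning the implied mean
    vector and covariance matrix for a full family (all members x all
    per-person variables, stacked member-major).
    """

    name: str = "model"
    kind: str = "generic"
    parent: str | None = None  # lineage for nested-model checks

    def __init__(self, params: Sequence[Param], var_names: Sequence[str]):
        self.params = list(params)
        self.var_names = list(var_names)
        self._by_label = {p.label: p for p in self.params}
        if len(self._by_label) != len(self.params):
            raise ValueError("duplicate parameter labels in model spec")

    # -- parameter bookkeeping -------------------------------------------
    @property
    def free_params(self) -> list[Param]:
        return [p for p in self.params if p.is_free]

    @property
    def free_labels(self) -> list[str]:
        return [p.label for p in self.free_params]

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def start_vector(self) -> np.ndarray:
        return np.array([p.start for p in self.free_params], float)

    def bounds(self) -> list[tuple[float, float]]:
        return [(p.lower, p.upper) for p in self.free_params]

    def theta_dict(self, x: np.ndarray) -> dict[str, float]:
        th = {p.label: p.fixed for p in self.params if not p.is_free}
        th.update(zip(self.free_labels, np.asarray(x, float)))
        return th

    def fix(self, **values: float) -> "ModelSpec":
        """Return a copy with the named parameters fixed (nested submodel)."""
        import copy

        new = copy.deepcopy(self)
        for label, value in values.items():
            if label not in new._by_label:
                raise KeyError(f"unknown parameter {label!r}")
            new._by_label[label].fixed = float(value)
        new.parent = self.name
        new.name = f"{self.name}|" + ",".join(f"{k}={v:g}" for k, v in values.items())
        return new

    # -- moments ----------------------------------------------------------
    def validate_theta(self, theta: dict[str, float]) -> bool:
        """Return False when theta lies outside the admissible region."""
        return True

    def family_moments(
        self,
        theta: dict[str, float],
        roles: tuple[str, ...],
        sexes: tuple[str, ...],
        zygosity: str,
        cache: dict | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def lineage(self) -> list[str]:
        return [self.name]


class LatentModelSpec(ModelSpec):
    """Model built from latent kinds with path-rule moment assembly.

    ``build`` maps a theta dict to a :class:`Structure`; ``validate`` may
    reject inadmissible thetas (e.g. latent variance shares exceeding 1).
    """

    def __init__(
        self,
        params: Sequence[Param],
        var_names: Sequence[str],
        build: Callable[[dict[str, float]], Structure],
        validate: Callable[[dict[str, float]], bool] | None = None,
        name: str = "latent_model",
        kind: str = "latent",
        parent: str | None = None,
    ):
        super().__init__(params, var_names)
        self.build = build
        self._validate = validate
        self.name = name
        self.kind = kind
        self.parent = parent

    def validate_theta(self, theta):
        return True if self._validate is None else bool(self._validate(theta))

    def family_moments(self, theta, roles, sexes, zygosity, cache=None):
        if cache is not None and "structure" in cache:
            st = cache["structure"]
        else:
            st = self.build(theta)
            if cache is not None:
                cache["structure"] = st
                cache.setdefault("blocks", {})
        blocks = cache.get("blocks") if cache is not None else None
        return assemble_moments(st, roles, sexes, zygosity, block_cache=blocks)


class DirectModelSpec(ModelSpec):
    """Model whose implied family moments are assembled directly.

    Used for saturated/correlation models where the covariance matrix is
    parameterized as means + SDs + correlations with exchangeability and
    relationship-class constraints rather than through latent paths.
    ``build_moments(theta, roles, sexes, zygosity)`` returns (mu, sigma).
    """

    def __init__(
        self,
        params: Sequence[Param],
        var_names: Sequence[str],
        build_moments: Callable,
        validate: Callable | None = None,
        name: str = "direct_model",
        kind: str = "direct",
        parent: str | None = None,
    ):
        super().__init__(params, var_names)
        self.build_moments = build_moments
        self._validate = validate
        self.name = name
        self.kind = kind
        self.parent = parent

    def validate_theta(self, theta):
        return True if self._validate is None else bool(self._validate(theta))

    def family_moments(self, theta, roles, sexes, zygosity, cache=None):
        return self.build_moments(theta, roles, sexes, zygosity)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

ROLE_ORDER = {"twin1": 0, "twin2": 1, "sibling": 2}


@dataclass
class PatternGroup:
    """Families sharing zygosity, member layout, sexes and missingness."""

    zygosity: str
    roles: tuple[str, ...]
    sexes: tuple[str, ...]
    mask: np.ndarray  # boolean, length n_members * p
    data: np.ndarray  # (n_families, mask.sum()) observed values

    def __post_init__(self):
        self.obs_idx = np.flatnonzero(self.mask)


@dataclass
class FamilyData:
    """Pattern-grouped family observations for one variable layout."""

    var_names: list[str]
    groups: list[PatternGroup]
    n_families: int
    n_dropped: int  # families with no observed variable at all

    @property
    def n_obs(self) -> int:
        """Total number of observed data points."""
        return sum(g.data.size for g in self.groups)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        var_names: Sequence[str],
        family_col: str = "family_id",
        zygosity_col: str = "zygosity",
        role_col: str = "role",
        sex_col: str = "sex",
    ) -> "FamilyData":
        var_names = list(var_names)
        missing_cols = [c for c in [family_col, zygosity_col, role_col, sex_col, *var_names] if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"missing columns: {missing_cols}")
        if not set(frame[role_col]).issubset(ROLE_ORDER):
            bad = sorted(set(frame[role_col]) - set(ROLE_ORDER))
            raise ValueError(f"unknown member role(s) {bad}")
        p = len(var_names)
        buckets: dict[tuple, list[np.ndarray]] = {}
        n_fam = 0
        n_dropped = 0

        dup = frame.duplicated([family_col, role_col], keep=False)
        slow_families = set(frame.loc[dup, family_col])
        fast = frame[~frame[family_col].isin(slow_families)]

        if len(fast):
            # Vectorized path: at most one row per role.  An absent member is
            # treated as fully missing, which FIML marginalizes exactly; its
            # placeholder sex never enters any retained moment.
            roles_all = [r for r in ("twin1", "twin2", "sibling") if r in set(fast[role_col])]
            piv_val = fast.pivot(index=family_col, columns=role_col, values=var_names)
            piv_sex = fast.pivot(index=family_col, columns=role_col, values=sex_col)
            zyg_by_fam = fast.groupby(family_col)[zygosity_col].first()
            n = len(piv_val)
            n_fam += n
            x = np.empty((n, len(roles_all) * p))
            sex_mat = np.empty((n, len(roles_all)), dtype=object)
            for mi, role in enumerate(roles_all):
                for vi, v in enumerate(var_names):
                    col = (v, role)
                    x[:, mi * p + vi] = piv_val[col].to_numpy(float) if col in piv_val else np.nan
                sex_mat[:, mi] = (
                    piv_sex[role].fillna("F").to_numpy() if role in piv_sex else np.array(["F"] * n, dtype=object)
                )
            mask_mat = ~np.isnan(x)
            zygs = zyg_by_fam.loc[piv_val.index].to_numpy()
            any_obs = mask_mat.any(axis=1)
            n_dropped += int((~any_obs).sum())
            keys = pd.DataFrame(
                {
                    "zyg": zygs[any_obs],
                    **{f"s{m}": sex_mat[any_obs, m] for m in range(len(roles_all))},
                    "mask": [mk.tobytes() for mk in mask_mat[any_obs]],
                }
            )
            x_obs = x[any_obs]
            for key, idx in keys.groupby(list(keys.columns), sort=False).indices.items():
                zyg = key[0]
                sexes = tuple(key[1:-1])
                mask = np.frombuffer(key[-1], dtype=bool)
                buckets[(zyg, tuple(roles_all), sexes, key[-1])] = [x_obs[np.asarray(idx)][:, mask]]

        if slow_families:
            cols = [zygosity_col, role_col, sex_col, *var_names]
            slow = frame[frame[family_col].isin(slow_families)]
            for _, fam in slow[[family_col, *cols]].groupby(family_col, sort=False):
                n_fam += 1
                order = fam[role_col].map(ROLE_ORDER)
                fam = fam.iloc[np.argsort(order.to_numpy(), kind="stable")]
                zyg = fam[zygosity_col].iloc[0]
                values = fam[var_names].to_numpy(float).ravel()
                mask = ~np.isnan(values)
                if not mask.any():
                    n_dropped += 1
                    continue
                key = (zyg, tuple(fam[role_col]), tuple(fam[sex_col]), mask.tobytes())
                buckets.setdefault(key, []).append(values[mask].reshape(1, -1))

        groups = [
            PatternGroup(
                zygosity=key[0],
                roles=key[1],
                sexes=key[2],
                mask=np.frombuffer(key[3], dtype=bool).copy(),
                data=np.vstack(rows),
            )
            for key, rows in buckets.items()
        ]
        return cls(var_names=var_names, groups=groups, n_families=n_fam, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


#: optimizer-safe stand-in for +inf (finite, so numeric gradients stay NaN-free)
PENALIZED = 1e100


def minus2_loglik(spec: ModelSpec, x: np.ndarray, data: FamilyData) -> float:
    """-2 log multivariate-normal likelihood summed over families (FIML).

    Missing entries of a family's observation vector are marginalized by
    deleting the corresponding rows/columns of the implied moments.  An
    inadmissible theta or non-positive-definite implied covariance yields
    a large finite penalty so optimizers can step back.
    """
    theta = spec.theta_dict(x)
    if not spec.validate_theta(theta):
        return PENALIZED
    cache: dict = {}
    moment_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    total = 0.0
    for g in data.groups:
        mkey = (g.zygosity, g.roles, g.sexes)
        if mkey in moment_cache:
            mu, sigma = moment_cache[mkey]
        else:
            mu, sigma = spec.family_moments(theta, g.roles, g.sexes, g.zygosity, cache=cache)
            moment_cache[mkey] = (mu, sigma)
        idx = g.obs_idx
        mu_s = mu[idx]
        sig_s = sigma[np.ix_(idx, idx)]
        try:
            chol = np.linalg.cholesky(sig_s)
        except np.linalg.LinAlgError:
            return PENALIZED
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        resid = g.data - mu_s
        z = linalg.solve_triangular(chol, resid.T, lower=True, check_finite=False)
        n_g, q = g.data.shape
        total += n_g * (q * _LOG_2PI + logdet) + float(np.sum(z * z))
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum-likelihood fit of a ModelSpec to family data."""

    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    m2ll: float
    n_free: int
    aic: float
    grad_norm: float
    converged: bool
    n_families: int
    n_obs: int
    n_starts: int
    boundary: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def free_labels(self) -> list[str]:
        return self.spec.free_labels

    def estimate_vector(self) -> np.ndarray:
        return np.array([self.estimates[l] for l in self.free_labels])

    def summary(self) -> pd.DataFrame:
        rows = []
        for lab in self.free_labels:
            rows.append({"parameter": lab, "estimate": self.estimates[lab], "se": self.se.get(lab, np.nan)})
        return pd.DataFrame(rows)


def _numeric_gradient(f, x, step=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        h = step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fp, fm = f(xp), f(xm)
        g[i] = (fp - fm) / (2 * h) if np.isfinite(fp) and np.isfinite(fm) else np.nan
    return g


def _numeric_hessian(f, x, step=1e-4):
    n = x.size
    h = step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        hess[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
        for j in range(i + 1, n):
            xpp, xpm, xmp, xmm = (x.copy() for _ in range(4))
            xpp[i] += h[i]
            xpp[j] += h[j]
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm[i] -= h[i]
            xmm[j] -= h[j]
            val = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    if not np.all(np.isfinite(hess)):
        hess = np.where(np.isfinite(hess), hess, 0.0)
    return hess, f0


class ConvergenceError(RuntimeError):
    pass


def fit(
    spec: ModelSpec,
    data: FamilyData | pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
    check_ident: bool = False,
    grad_tol: float | None = None,
    maxiter: int = 2000,
) -> FitResult:
    """Fit a model by FIML with multiple random restarts.

    The first start uses the spec's start values; the remaining
    ``n_starts - 1`` perturb them uniformly within the bounds.  Standard
    errors come from the numerical Hessian of -2LL (cov = 2 H^{-1}).
    Estimates within 1e-6 of a bound are flagged as boundary solutions,
    which for variance paths means the component is effectively zero.
    """
    if isinstance(data, pd.DataFrame):
        data = FamilyData.from_frame(data, spec.var_names)
    if data.n_families - data.n_dropped < 1:
        raise ValueError("no families with observed data")
    if check_ident:
        ok, rank, n_free = check_identification(spec, data)
        if not ok:
            raise ValueError(
                f"model not locally identified at start values: moment Jacobian rank {rank} < {n_free} free parameters"
            )

    rng = np.random.default_rng(seed)
    x0 = spec.start_vector()
    bounds = spec.bounds()
    f = lambda x: minus2_loglik(spec, x, data)

    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        pert = np.array(
            [
                np.clip(v + rng.uniform(-0.3, 0.3) * (1.0 + abs(v)), lo + 1e-6 if np.isfinite(lo) else -np.inf, hi - 1e-6 if np.isfinite(hi) else np.inf)
                for v, (lo, hi) in zip(x0, bounds)
            ]
        )
        starts.append(pert)

    best = None
    messages = []
    for s in starts:
        if f(s) >= PENALIZED:
            messages.append("start rejected (penalized -2LL)")
            continue
        res = optimize.minimize(
            f,
            s,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7, "maxfun": 10 * maxiter},
        )
        messages.append(res.message if isinstance(res.message, str) else str(res.message))
        if res.fun < PENALIZED and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError("all starts failed: " + "; ".join(messages))

    x_hat = best.x
    m2ll = float(best.fun)

    # projected gradient: components pressing against an active bound are zeroed
    grad = _numeric_gradient(f, x_hat)
    proj = grad.copy()
    for i, (lo, hi) in enumerate(bounds):
        if np.isfinite(lo) and x_hat[i] - lo < 1e-8 and grad[i] > 0:
            proj[i] = 0.0
        if np.isfinite(hi) and hi - x_hat[i] < 1e-8 and grad[i] < 0:
            proj[i] = 0.0
    grad_norm = float(np.nanmax(np.abs(proj))) if proj.size else 0.0
    if grad_tol is None:
        # numeric-gradient noise scales with the magnitude of -2LL
        grad_tol = 1e-4 * max(1.0, abs(m2ll) * 1e-2)
    converged = bool(np.isfinite(m2ll)) and grad_norm <= grad_tol

    boundary = []
    for i, (lo, hi) in enumerate(bounds):
        if (np.isfinite(lo) and abs(x_hat[i] - lo) < 1e-6) or (np.isfinite(hi) and abs(x_hat[i] - hi) < 1e-6):
            boundary.append(spec.free_labels[i])

    se = {}
    if compute_se:
        hess, _ = _numeric_hessian(f, x_hat)
        try:
            cov = 2.0 * linalg.pinvh(hess)
            d = np.diag(cov)
            se = {
                lab: (math.sqrt(v) if v > 0 else np.nan)
                for lab, v in zip(spec.free_labels, d)
            }
        except linalg.LinAlgError:
            se = {lab: np.nan for lab in spec.free_labels}

    n_free = spec.n_free
    return FitResult(
        spec=spec,
        estimates=dict(zip(spec.free_labels, x_hat)),
        se=se,
        m2ll=m2ll,
        n_free=n_free,
        aic=m2ll + 2 * n_free,
        grad_norm=grad_norm,
        converged=converged,
        n_families=data.n_families,
        n_obs=data.n_obs,
        n_starts=len(starts),
        boundary=boundary,
        message="; ".join(messages[-1:]),
    )


# ---------------------------------------------------------------------------
# nested-model testing
# ---------------------------------------------------------------------------


def lrt_from_values(delta_m2ll: float, delta_df: int) -> float:
    """Upper-tail chi-square p-value for a likelihood-ratio statistic."""
    if delta_df < 0:
        raise ValueError("delta_df must be >= 0")
    if delta_df == 0:
        return 1.0
    return float(chi2.sf(max(delta_m2ll, 0.0), delta_df))


def _is_nested(full: ModelSpec, nested: ModelSpec) -> bool:
    if set(nested.free_labels) <= set(full.free_labels):
        return True
    # constrained specs built by .fix() or by the ladder builders record lineage
    seen = set()
    node: str | None = nested.name
    chain = [nested.name]
    spec = nested
    while spec is not None and spec.parent and spec.parent not in seen:
        seen.add(spec.parent)
        chain.append(spec.parent)
        spec = None  # only one hop is stored on the object itself
    return full.name in chain or (nested.parent is not None and full.name == nested.parent)


def lrt(full: FitResult, nested: FitResult, tol: float = 1e-4, force: bool = False):
    """Likelihood-ratio test of a nested model against its parent.

    Returns ``(delta_m2ll, delta_df, p)``.  Raises when the pair is not
    recognizably nested (free-parameter subset or recorded lineage) unless
    ``force=True``.
    """
    if not force and not _is_nested(full.spec, nested.spec):
        raise ValueError(
            f"models {full.spec.name!r} and {nested.spec.name!r} are not nested "
            "(no free-parameter subset and no recorded lineage)"
        )
    delta_df = full.n_free - nested.n_free
    if delta_df < 0:
        raise ValueError("nested model has more free parameters than the full model")
    delta = nested.m2ll - full.m2ll
    if delta < -tol * max(1.0, abs(full.m2ll)):
        raise ValueError(
            f"nested model fits better than the full model (delta -2LL = {delta:.6g}); "
            "refit with more starts"
        )
    return max(delta, 0.0), delta_df, lrt_from_values(delta, delta_df)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------


def check_identification(spec: ModelSpec, data: FamilyData, step: float = 1e-5):
    """Local identifiability via the rank of the moment Jacobian at start.

    Stacks the implied means and lower-triangular covariances over the
    distinct family configurations present in the data and differentiates
    numerically with respect to the free parameters.
    """
    configs = sorted({(g.zygosity, g.roles, g.sexes) for g in data.groups})
    x0 = spec.start_vector()

    def stacked(x):
        theta = spec.theta_dict(x)
        out = []
        for zyg, roles, sexes in configs:
            mu, sig = spec.family_moments(theta, roles, sexes, zyg)
            out.append(mu)
            out.append(sig[np.tril_indices_from(sig)])
        return np.concatenate(out)

    base = stacked(x0)
    jac = np.empty((base.size, x0.size))
    for i in range(x0.size):
        h = step * (1.0 + abs(x0[i]))
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        jac[:, i] = (stacked(xp) - stacked(xm)) / (2 * h)
    rank = int(np.linalg.matrix_rank(jac, tol=1e-8 * max(1.0, float(np.abs(jac).max()))))
    return rank >= spec.n_free, rank, spec.n_free
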