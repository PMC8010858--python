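"""Ground-truth parameters for the twin-family data generator.

:class:`GenerativeParams` collects every path coefficient, correlation and
design setting that drives the simulator: the bivariate common-pathway
structure of the two traits (well-being and the resilience core) over two
waves, the life-event process that turns the resilience core into an
anxious-depression score, polygenic-score effects, causal cross-trait
paths, family composition across the five zygosity groups plus non-twin
siblings, and missingness.

Conventions
-----------
* Latent trait factors have unit variance: ``a_latent``/``d_latent`` are
  paths on the SD scale and the latent E path is ``sqrt(1 - a^2 - d^2)``,
  so ``a_latent[t]**2`` is the latent heritability of trait ``t``.
* Arrays indexed ``[trait][wave][sex]`` use trait order
  (well-being, resilience), wave order (t1, t2), sex order (F, M).
* The per-wave phenotype "core" scale is the scale on which
  :func:`twinwell.simulate.implied_moments` is expressed; raw
  questionnaire scores are affine rescalings of the standardized cores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["GenerativeParams", "MRDoCTruth", "ZYGOSITY_GROUPS"]

ZYGOSITY_GROUPS = ("MZM", "DZM", "MZF", "DZF", "DOS")

#: share of twin pairs per zygosity group, mirroring the study sample
#: (1577 MZM / 967 DZM / 3859 MZF / 2112 DZF / 2789 DOS individuals)
DEFAULT_ZYGOSITY_WEIGHTS = {
    "MZM": 0.139,
    "DZM": 0.086,
    "MZF": 0.341,
    "DZF": 0.187,
    "DOS": 0.247,
}


def _twsa(value) -> np.ndarray:
    """Broadcast a scalar/nested sequence to a (trait, wave, sex) array."""
    arr = np.asarray(value, float)
    return np.broadcast_to(arr, (2, 2, 2)).copy()


@dataclass
class MRDoCTruth:
    """Generating values for MR-DoC pair data: S -> X -> Y with pleiotropy.

    X = b1*S + a_x*A_x + e_x*E_x;  Y = g1*X + b2*S + a_y*A_y + e_y*E_y.
    """

    b1: float = 0.3
    g1: float = 0.4
    b2: float = 0.1
    a_x: float = 0.7
    e_x: float = 0.65
    a_y: float = 0.7
    e_y: float = 0.65
    r_a: float = 0.3
    r_e: float = 0.0
    sigma_s2: float = 1.0

    def validate(self) -> None:
        if self.sigma_s2 <= 0:
            raise ValueError("sigma_s2 must be > 0")
        for lab in ("a_x", "e_x", "a_y", "e_y"):
            if getattr(self, lab) < 0:
                raise ValueError(f"variance path {lab} must be >= 0")
        for lab in ("r_a", "r_e"):
            if abs(getattr(self, lab)) > 1:
                raise ValueError(f"|{lab}| must be <= 1")


@dataclass
class GenerativeParams:
    """All ground truth driving :func:`twinwell.simulate.simulate_families`."""

    # latent bivariate structure (trait order: well-being, resilience)
    a_latent: tuple[float, float] = (math.sqrt(0.548), math.sqrt(0.609))
    d_latent: tuple[float, float] = (0.0, 0.0)
    r_a: float = 0.71
    r_d: float = 0.0
    r_e: float = 0.93

    # measurement part, indexed [trait][wave][sex]
    loadings: np.ndarray = field(default_factory=lambda: _twsa(0.8))
    spec_a: np.ndarray = field(default_factory=lambda: _twsa(0.0))  # set in __post_init__
    spec_d: np.ndarray = field(default_factory=lambda: _twsa(0.0))
    spec_e: np.ndarray = field(default_factory=lambda: _twsa(0.0))
    means: np.ndarray = field(default_factory=lambda: _twsa(0.0))

    # causal phenotype-level paths, applied simultaneously per wave
    g_wb_to_res: float = 0.0
    g_res_to_wb: float = 0.0

    # polygenic scores (standardized; A-type familial sharing)
    sigma_s2: float = 1.0
    b1: float = 0.0  # well-being PGS -> well-being
    b2: float = 0.0  # well-being PGS -> resilience (pleiotropy)
    b_res: float = 0.0  # resilience PGS -> resilience

    # life events and anxious-depression (per wave)
    mu_le: tuple[float, float] = (1.53, 2.19)
    le_max: tuple[int, int] = (16, 19)
    beta_le: tuple[float, float] = (0.11, 0.27)
    ad_mean: tuple[float, float] = (6.16, 4.99)
    ad_sd: tuple[float, float] = (5.37, 5.05)
    ad_male_shift: float = -0.05  # males report fewer symptoms (z-scale)
    wb_mean: tuple[float, float] = (26.5, 27.3)
    wb_sd: tuple[float, float] = (6.0, 6.0)

    # age structure and small U-shaped age effect on both traits
    age_mean: float = 33.0
    age_sd: float = 11.4
    age_gap: float = 7.0  # wave 2 occurs ~7 years after wave 1
    age_quad: tuple[float, float] = (0.01, 0.01)  # per ((age-40)/10)^2

    # family composition
    n_pairs: int = 2000
    zygosity_weights: dict = field(default_factory=lambda: dict(DEFAULT_ZYGOSITY_WEIGHTS))
    sibling_probs: tuple[float, float, float] = (0.62, 0.31, 0.07)

    # completely-at-random missingness per wave (whole-wave block)
    missing_t1: float = 0.58
    missing_t2: float = 0.17

    # MR-DoC generating values (for simulate_mrdoc_pairs)
    mrdoc: MRDoCTruth = field(default_factory=MRDoCTruth)

    discretize: bool = False

    def __post_init__(self):
        self.loadings = _twsa(self.loadings)
        self.spec_a = _twsa(self.spec_a)
        self.spec_d = _twsa(self.spec_d)
        self.spec_e = _twsa(self.spec_e)
        self.means = _twsa(self.means)
        if not np.any(self.spec_a) and not np.any(self.spec_e):
            self._default_specifics()
        self.validate()

    def _default_specifics(self):
        """Time-specific paths mirroring the reported wave-level structure.

        Wave variance is lam^2 (latent) + spec variance 0.66; the genetic
        share of the time-specific variance follows the reported
        time-specific heritabilities: well-being 32%/37% (F), 32%/35% (M);
        resilience 45%/43% (F), 39%/36% (M).
        """
        spec_var = 0.66
        shares = np.array(
            [  # [trait][wave][sex]
                [[0.32, 0.32], [0.37, 0.35]],
                [[0.45, 0.39], [0.43, 0.36]],
            ]
        )
        self.spec_a = np.sqrt(shares * spec_var)
        self.spec_e = np.sqrt((1.0 - shares) * spec_var)

    # ------------------------------------------------------------------
    def e_latent(self) -> tuple[float, float]:
        out = []
        for t in range(2):
            rem = 1.0 - self.a_latent[t] ** 2 - self.d_latent[t] ** 2
            if rem < -1e-12:
                raise ValueError(
                    f"latent variance shares of trait {t} exceed 1 (a^2 + d^2 = {1 - rem:.4f})"
                )
            out.append(math.sqrt(max(rem, 0.0)))
        return tuple(out)

    def validate(self) -> None:
        for lab in ("r_a", "r_d", "r_e"):
            if abs(getattr(self, lab)) > 1:
                raise ValueError(f"|{lab}| must be <= 1")
        for name in ("loadings", "spec_a", "spec_d", "spec_e"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative variance path in {name}")
        self.e_latent()  # raises when a^2 + d^2 > 1
        if not (0 <= self.missing_t1 < 1 and 0 <= self.missing_t2 < 1):
            raise ValueError("missingness rates must lie in [0, 1)")
        if abs(sum(self.sibling_probs) - 1.0) > 1e-9:
            raise ValueError("sibling_probs must sum to 1")
        w = sum(self.zygosity_weights.get(z, 0.0) for z in ZYGOSITY_GROUPS)
        if w <= 0:
            raise ValueError("zygosity weights must have positive mass")
        if any(self.zygosity_weights.get(z, 0.0) < 0 for z in ZYGOSITY_GROUPS):
            raise ValueError("zygosity weights must be non-negative")
        self.mrdoc.validate()
        from .simulate import implied_moments  # deferred: avoids cycle at import

        for zyg in ZYGOSITY_GROUPS:
            _, sigma = implied_moments(self, zyg, n_siblings=0)
            ev = np.linalg.eigvalsh(sigma)
            if ev.min() < -1e-8:
                raise ValueError(
                    f"implied covariance for zygosity group {zyg} is not positive "
                    f"semi-definite (min eigenvalue {ev.min():.3g})"
                )

    # ------------------------------------------------------------------
    # presets
    # ------------------------------------------------------------------
    @classmethod
    def study_mirror(cls, n_pairs: int = 2000, **overrides) -> "GenerativeParams":
        """Defaults emulating the study conditions (the final AE model with
        sex-specific time-specific parts, study-like composition,
        wave-level missingness and a predictive well-being PGS)."""
        base = dict(
            b1=math.sqrt(0.0085 * 1.3),  # PGS explains ~0.85% of well-being
            b2=math.sqrt(0.016 * 1.3),  # and ~1.6% of resilience (pleiotropy)
            b_res=math.sqrt(0.001 * 1.3),
            n_pairs=n_pairs,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def recovery_benchmark(cls, n_pairs: int = 10000, **overrides) -> "GenerativeParams":
        """Parameter-recovery conditions: the final-model latent values
        (h2 0.548 / 0.609, rA 0.71, rE 0.93), wave loadings 0.8, the
        time-specific AE variance split evenly, no sex differences, no
        missingness, twin pairs only, equal zygosity-sex cells."""
        base = dict(
            loadings=_twsa(0.8),
            spec_a=_twsa(math.sqrt(0.18)),
            spec_e=_twsa(math.sqrt(0.18)),
            ad_male_shift=0.0,
            age_quad=(0.0, 0.0),
            missing_t1=0.0,
            missing_t2=0.0,
            sibling_probs=(1.0, 0.0, 0.0),
            zygosity_weights={"MZM": 0.25, "MZF": 0.25, "DZM": 0.25, "DZF": 0.25, "DOS": 0.0},
            n_pairs=n_pairs,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null_world(cls, n_pairs: int = 2000, **overrides) -> "GenerativeParams":
        """No cross-trait correlation, no causal paths, no PGS effects."""
        base = dict(
            r_a=0.0,
            r_e=0.0,
            ad_male_shift=0.0,
            age_quad=(0.0, 0.0),
            n_pairs=n_pairs,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d
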