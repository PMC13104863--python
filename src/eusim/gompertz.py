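"""Gompertz–Makeham mortality and the vitality/longevity allele parameterization.

The hazard at age ``n`` is ``h(n) = alpha * exp(beta * n) + gamma``: ``alpha``
is the baseline (age-0) senescent hazard, ``beta`` the exponential rate at
which hazard grows with age, and ``gamma`` an age-independent (Makeham)
component.  Alleles are described by two phenomenological scores — Vitality
``V`` (inversely related to ``alpha``) and Longevity ``L`` (inversely related
to ``beta``; interpreted as the mortality-doubling half-life in time units) —
and mapped onto Gompertz parameters by a pluggable :class:`MappingConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GompertzParams",
    "Allele",
    "TradeoffPoint",
    "MappingConfig",
    "hazard",
    "death_probability",
    "survivorship",
    "allele_to_gompertz",
    "apply_tradeoff",
]


@dataclass(frozen=True)
class GompertzParams:
    """The (alpha, beta, gamma) triple of the Gompertz–Makeham hazard.

    Units: hazards are per time unit; ages are in the same time unit.
    """

    alpha: float
    beta: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")

    def with_gamma(self, gamma: float) -> "GompertzParams":
        return replace(self, gamma=gamma)


@dataclass(frozen=True)
class Allele:
    """A heritable unit carrying a Vitality/Longevity score pair.

    ``V`` is dimensionless robustness at young ages (inverse of alpha);
    ``L`` is the mortality-doubling half-life in time units (inverse of beta).
    ``dominant`` marks the allele that masks its partner in heterozygotes
    under the dominant/recessive phenotype rule.
    """

    label: str
    V: float
    L: float
    dominant: bool = False

    def __post_init__(self) -> None:
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")


@dataclass(frozen=True)
class TradeoffPoint:
    """Fractional changes (x, y) applied to (alpha, beta) of a reference allele.

    The transformed hazard is ``(1-x) * alpha * exp((1-y) * beta * n) + gamma``.
    A genuine vitality/longevity tradeoff requires x and y of opposite signs;
    axis points (one coordinate zero) are allowed for sweeps.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x != 0.0 and self.y != 0.0 and (self.x > 0) == (self.y > 0):
            raise ValueError(
                f"tradeoff requires x and y of opposite signs, got ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class MappingConfig:
    """Reference constants mapping (V, L) scores to Gompertz parameters.

    Default rule: ``beta = ln(2) / L`` (L is the hazard-doubling half-life)
    and ``alpha = alpha_ref * V_ref / V`` (vitality inversely proportional to
    baseline hazard, anchored so V = V_ref maps to alpha = alpha_ref).
    """

    alpha_ref: float = 0.002
    V_ref: float = 1000.0
    gamma: float = 0.0
    rule: str = "inverse"

    def __post_init__(self) -> None:
        if not self.alpha_ref > 0 or not self.V_ref > 0:
            raise ValueError("alpha_ref and V_ref must be positive")
        if self.rule != "inverse":
            raise ValueError(f"unknown mapping rule {self.rule!r}")


def hazard(params: GompertzParams, n):
    """Gompertz–Makeham hazard ``alpha * exp(beta*n) + gamma`` at age(s) ``n``."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("age must be nonnegative")
    out = params.alpha * np.exp(params.beta * n) + params.gamma
    return float(out) if out.ndim == 0 else out


def cumulative_hazard(params: GompertzParams, n):
    """Integral of the hazard from age 0 to age ``n`` (closed form)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("age must be nonnegative")
    if params.beta > 1e-200:  # same cutoff as death_probability
        out = (params.alpha / params.beta) * np.expm1(params.beta * n) + params.gamma * n
    else:
        out = (params.alpha + params.gamma) * n
    return float(out) if out.ndim == 0 else out


def survivorship(params: GompertzParams, n):
    """Probability of surviving from age 0 to age ``n``: ``exp(-∫₀ⁿ h)``."""
    return np.exp(-np.asarray(cumulative_hazard(params, n)))


def death_probability(params: GompertzParams, n, dt: float = 1.0):
    """Probability that an individual of age ``n`` dies within the next ``dt``.

    Integrating the hazard over [n, n+dt] gives
    ``D_n = 1 - exp(-(alpha/beta) e^{beta n} (e^{beta dt} - 1) - gamma dt)``;
    at beta = 0 the closed form reduces to ``1 - exp(-(alpha+gamma) dt)``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("age must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    # below ~1e-200 the alpha/beta ratio overflows; the beta->0 limit is exact
    if params.beta > 1e-200:
        expo = (
            (params.alpha / params.beta)
            * np.exp(params.beta * n)
            * np.expm1(params.beta * dt)
            + params.gamma * dt
        )
    else:
        expo = (params.alpha + params.gamma) * dt * np.ones_like(n)
    out = -np.expm1(-expo)
    return float(out) if out.ndim == 0 else out


def allele_to_gompertz(
    allele: Allele, mapping: MappingConfig | None = None, gamma: float | None = None
) -> GompertzParams:
    """Map an allele's (V, L) scores to Gompertz parameters.

    ``gamma`` overrides the mapping's Makeham term when given.
    """
    mapping = mapping or MappingConfig()
    beta = math.log(2.0) / allele.L
    alpha = mapping.alpha_ref * mapping.V_ref / allele.V
    g = mapping.gamma if gamma is None else gamma
    return GompertzParams(alpha=alpha, beta=beta, gamma=g)


def apply_tradeoff(base: GompertzParams, pt: TradeoffPoint) -> GompertzParams:
    """Hazard of the competitor at tradeoff point (x, y): ((1-x)α, (1-y)β, γ)."""
    alpha = (1.0 - pt.x) * base.alpha
    beta = (1.0 - pt.y) * base.beta
    if alpha <= 0 or beta < 0:
        raise ValueError(f"tradeoff ({pt.x}, {pt.y}) yields nonpositive parameters")
    return GompertzParams(alpha=alpha, beta=beta, gamma=base.gamma)
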