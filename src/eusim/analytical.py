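"""Deterministic age-structured two-allele competition.

Two alleles A and B, with Gompertz–Makeham death probabilities ``D_n`` and
``d_n`` per timestep, compete in a population updated in discrete time:
survivors shift up one age class each step and newborns enter at age 0
according to a growth law.  Under a *linear* (eusocial, single-queen) law the
total birth count is a constant ``g`` split by allele frequency; under an
*exponential* law every female reproduces and births saturate with total
population size through ``S(x) = Ns*x / (Ns + x - 2)``.

For any growth law of the shared-form ``X_i = p_i * H(A, B)`` only the two
competitive-exclusion steady states are stable, and the winner is decided by
the sign of the fitness difference

    dF = sum_{n>=1} prod_{k<n} (1 - D_k)  -  sum_{n>=1} prod_{k<n} (1 - d_k),

the difference of the alleles' expected-lifetime (summed survivorship)
series.  dF > 0 means allele A excludes B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .gompertz import (
    GompertzParams,
    TradeoffPoint,
    apply_tradeoff,
    cumulative_hazard,
    death_probability,
)

__all__ = [
    "AgeStructuredState",
    "GrowthLaw",
    "survivorship_sum",
    "delta_F",
    "births_linear",
    "saturation",
    "births_exponential",
    "step",
    "steady_state",
    "steady_state_total",
    "mean_age",
    "match_gamma",
    "nullcline",
    "nullcline_slope_at_origin",
]

#: survivorship below which the series tail is discarded; the tail is bounded
#: by a geometric series with ratio (1 - D_nmax) and is < 1e-11 at this cut.
TAIL_TOL = 1e-12


@dataclass
class AgeStructuredState:
    """Abundance-by-age vectors for the two competing alleles at time t."""

    abundA: np.ndarray
    abundB: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.abundA = np.asarray(self.abundA, dtype=float)
        self.abundB = np.asarray(self.abundB, dtype=float)
        if np.any(self.abundA < 0) or np.any(self.abundB < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def totalA(self) -> float:
        return float(self.abundA.sum())

    @property
    def totalB(self) -> float:
        return float(self.abundB.sum())

    @property
    def total(self) -> float:
        return self.totalA + self.totalB


@dataclass(frozen=True)
class GrowthLaw:
    """Birth law: ``linear`` (total births = g) or ``exponential`` (saturating)."""

    mode: Literal["linear", "exponential"]
    g: float = 2.0
    Ns: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "exponential"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if not self.g > 0:
            raise ValueError("fecundity g must be positive")
        if self.mode == "exponential" and not self.Ns > 2:
            raise ValueError("saturation size Ns must exceed 2")


def _survivorships(params: GompertzParams, dt: float, tail_tol: float) -> np.ndarray:
    """S(n) = prod_{k<n} (1 - D_k) for n = 0, 1, ..., truncated at S < tail_tol.

    Because D_k integrates the hazard over [k*dt, (k+1)*dt], the product
    telescopes to the closed-form exp(-cumulative hazard), evaluated in blocks.
    """
    out = [np.array([1.0])]
    n0, block = 0, 64
    while True:
        n = np.arange(n0 + 1, n0 + block + 1, dtype=float)
        s = np.exp(-np.asarray(cumulative_hazard(params, n * dt)))
        keep = s >= tail_tol
        out.append(s[keep])
        if not keep.all():
            break
        if params.alpha + params.gamma <= 0:  # pragma: no cover - guarded by type
            raise RuntimeError("non-decaying survivorship")
        n0 += block
        if n0 > 10_000_000:
            raise RuntimeError("survivorship series failed to decay below tolerance")
    return np.concatenate(out)


def survivorship_sum(
    params: GompertzParams, dt: float = 1.0, tail_tol: float = TAIL_TOL
) -> float:
    """F = sum_{n>=1} S(n): the allele's expected-lifetime fitness series."""
    s = _survivorships(params, dt, tail_tol)
    return float(s[1:].sum())


def delta_F(
    paramsA: GompertzParams,
    paramsB: GompertzParams,
    dt: float = 1.0,
    tail_tol: float = TAIL_TOL,
) -> float:
    """Fitness difference between alleles A and B; positive means A wins."""
    return survivorship_sum(paramsA, dt, tail_tol) - survivorship_sum(paramsB, dt, tail_tol)


def births_linear(Atot: float, Btot: float, g: float) -> tuple[float, float]:
    """Single-queen births: a fixed total g split by current allele frequency."""
    tot = Atot + Btot
    if tot <= 0:
        return 0.0, 0.0  # extinct: no queen, no births
    return g * Atot / tot, g * Btot / tot


def saturation(x: float, Ns: float) -> float:
    """Effective female count S(x) = Ns*x / (Ns + x - 2); S(2) = 2, S(inf) = Ns."""
    denom = Ns + x - 2.0
    if denom <= 0:
        raise ValueError(f"saturation denominator Ns + x - 2 = {denom} must be positive")
    return Ns * x / denom


def births_exponential(
    Atot: float, Btot: float, g: float, Ns: float
) -> tuple[float, float]:
    """Saturating whole-population births: X_i = g * Ns * i_tot / (2 (Ns + N - 2))."""
    tot = Atot + Btot
    if tot <= 0:
        return 0.0, 0.0
    h = g * saturation(tot, Ns) / (2.0 * tot)
    return h * Atot, h * Btot


def step(
    state: AgeStructuredState,
    growth: GrowthLaw,
    paramsA: GompertzParams,
    paramsB: GompertzParams,
    dt: float = 1.0,
) -> AgeStructuredState:
    """One discrete-time update: survival shifts ages up, then births fill age 0.

    Births are computed from the abundances at time t (before survival), so
    the age-0 class at t+dt reflects the population that did the mating at t.
    The age axis is capped where cumulative survivorship drops below TAIL_TOL.
    """
    Atot, Btot = state.totalA, state.totalB
    if growth.mode == "linear":
        A0, B0 = births_linear(Atot, Btot, growth.g)
    else:
        A0, B0 = births_exponential(Atot, Btot, growth.g, growth.Ns)

    def shift(abund: np.ndarray, params: GompertzParams, x0: float) -> np.ndarray:
        ages = np.arange(len(abund), dtype=float) * dt
        surv = 1.0 - np.asarray(death_probability(params, ages, dt))
        new = np.concatenate([[x0], abund * surv])
        # drop trailing classes once cumulative survivorship is negligible
        while len(new) > 1 and cumulative_hazard(
            params, (len(new) - 1) * dt
        ) > -np.log(TAIL_TOL):
            new = new[:-1]
        return new

    return AgeStructuredState(
        abundA=shift(state.abundA, paramsA, A0),
        abundB=shift(state.abundB, paramsB, B0),
        t=state.t + dt,
    )


def steady_state(
    growth: GrowthLaw,
    paramsA: GompertzParams,
    paramsB: GompertzParams,
    init: AgeStructuredState | None = None,
    dt: float = 1.0,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> AgeStructuredState:
    """Iterate :func:`step` to a fixed point (max abundance change < tol)."""
    if init is None:
        init = AgeStructuredState(abundA=np.array([1.0]), abundB=np.array([1.0]))
    state = init
    for _ in range(max_iter):
        new = step(state, growth, paramsA, paramsB, dt)
        if (
            len(new.abundA) == len(state.abundA)
            and len(new.abundB) == len(state.abundB)
            and max(
                np.max(np.abs(new.abundA - state.abundA), initial=0.0),
                np.max(np.abs(new.abundB - state.abundB), initial=0.0),
            )
            < tol
        ):
            return new
        state = new
    raise RuntimeError(
        f"steady_state did not converge in {max_iter} iterations "
        f"(totals A={state.totalA:.3g}, B={state.totalB:.3g})"
    )


def steady_state_total(
    growth: GrowthLaw, params: GompertzParams, dt: float = 1.0
) -> float:
    """Closed-form single-allele steady-state total population size.

    At the fixed point every age class holds X * S(n) with X the per-step
    birth count, so the total is T = X * (1 + F) where F is the survivorship
    sum.  Linear: X = g.  Exponential: X = g*S(T)/2 solves to
    T = g*Ns*(1+F)/2 - Ns + 2.
    """
    F = survivorship_sum(params, dt)
    if growth.mode == "linear":
        return growth.g * (1.0 + F)
    T = growth.g * growth.Ns * (1.0 + F) / 2.0 - growth.Ns + 2.0
    if T <= 0:
        raise ValueError("exponential population not viable at these parameters")
    return T


def mean_age(params: GompertzParams, dt: float = 1.0) -> float:
    """Mean age of the stationary age distribution X*S(n)."""
    s = _survivorships(params, dt, TAIL_TOL)
    n = np.arange(len(s), dtype=float) * dt
    return float((n * s).sum() / s.sum())


def match_gamma(
    linear: GrowthLaw,
    exponential: GrowthLaw,
    params: GompertzParams,
    dt: float = 1.0,
    tol: float = 1e-8,
    gamma_hi: float = 50.0,
) -> float:
    """Find gamma' >= gamma equalizing exponential and linear carrying capacities.

    Only the age-independent Makeham term is adjusted, leaving the
    age-dependent (alpha, beta) component untouched.  Raises if the
    exponential population at the baseline gamma is already at or below the
    linear target (no gamma' >= gamma exists) or if the bracket cannot span
    the target.
    """
    target = steady_state_total(linear, params, dt)

    def gap(gamma: float) -> float:
        return steady_state_total(exponential, params.with_gamma(gamma), dt) - target

    g0 = gap(params.gamma)
    if abs(g0) < tol:
        return params.gamma
    if g0 < 0:
        raise ValueError(
            "exponential steady state at baseline gamma is below the linear "
            "target; no gamma' >= gamma can match the carrying capacities"
        )
    hi = max(params.gamma + 1.0, 1.0)
    while gap(hi) > 0:
        hi *= 2.0
        if hi > gamma_hi:
            raise ValueError(
                f"no gamma' <= {gamma_hi} matches the carrying capacities "
                "(exponential population too fecund even at maximal hazard)"
            )
    return float(brentq(gap, params.gamma, hi, xtol=tol))


def _delta_F_at(base: GompertzParams, x: float, y: float, dt: float) -> float:
    comp = apply_tradeoff(base, TradeoffPoint(x=x, y=y))
    return delta_F(base, comp, dt)


def nullcline(
    base: GompertzParams,
    x_grid,
    dt: float = 1.0,
    y_limit: float = 0.999,
    tol: float = 1e-12,
) -> list[tuple[float, float | None]]:
    """Solve, for each x, the y with dF(base, tradeoff(base, (x, y))) = 0.

    dF is monotone decreasing in y (lower competitor beta only helps the
    competitor), so each root is bracketed by a sign change before Brent
    refinement.  x and y on the curve have opposite signs; an x for which no
    sign change exists within |y| < y_limit yields ``(x, None)`` rather than
    a fabricated point.
    """
    pts: list[tuple[float, float | None]] = []
    for x in np.asarray(x_grid, dtype=float):
        if x == 0.0:
            pts.append((0.0, 0.0))
            continue
        # competitor with higher vitality (x>0) must pay in longevity (y<0)
        lo, hi = (-y_limit, 0.0) if x > 0 else (0.0, y_limit)
        f_lo = _delta_F_at(base, x, lo, dt)
        f_hi = _delta_F_at(base, x, hi, dt)
        if f_lo * f_hi > 0:
            pts.append((float(x), None))
            continue
        y = brentq(lambda yy: _delta_F_at(base, x, yy, dt), lo, hi, xtol=tol)
        pts.append((float(x), float(y)))
    return pts


def nullcline_slope_at_origin(
    base: GompertzParams, dt: float = 1.0, h: float = 1e-4
) -> float:
    """dy/dx of the nullcline at (0, 0) by central differences of dF."""
    dFdx = (_delta_F_at(base, h, 0.0, dt) - _delta_F_at(base, -h, 0.0, dt)) / (2 * h)
    dFdy = (_delta_F_at(base, 0.0, h, dt) - _delta_F_at(base, 0.0, -h, dt)) / (2 * h)
    return -dFdx / dFdy
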