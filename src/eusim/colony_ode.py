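"""Colony-site competition dynamics.

A landscape holds M colony sites.  Colonies of allele types A and B seed new
colonies into the r = M - A - B available sites, each colony seeding at rate
kA*r (proportional to available sites) and collapsing at a constant
per-colony rate DA:

    dA/dt = A * (kA * r - DA),      dB/dt = B * (kB * r - DB)

Besides the empty landscape the
only steady states are the two competitive-exclusion states
``r* = D/k, winner = M - r*, loser = 0``; the stable one is the exclusion
state with the lowest r* (higher-r* states are invadable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["ColonyCompetitionParams", "ColonySteadyState", "colony_steady_states",
           "integrate_colony_ode"]


@dataclass(frozen=True)
class ColonyCompetitionParams:
    M: float  # total colony sites
    kA: float  # per-colony seeding rate constant, allele A
    kB: float
    DA: float  # per-colony collapse rate, allele A
    DB: float

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError("M must be positive")
        for name in ("kA", "kB", "DA", "DB"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ColonySteadyState:
    label: Literal["trivial", "A_excludes_B", "B_excludes_A"]
    r: float
    A: float
    B: float
    stable: bool
    viable: bool  # r* < M, i.e. the winning allele can persist at all
    tie: bool = False


def colony_steady_states(p: ColonyCompetitionParams) -> list[ColonySteadyState]:
    """The three fixed points, with the lowest-r exclusion state marked stable.

    An exclusion state with r* >= M would need a nonpositive colony count and
    is flagged non-viable.  rA == rB is reported as a neutral tie with
    neither exclusion state marked stable.
    """
    rA = p.DA / p.kA
    rB = p.DB / p.kB
    tie = np.isclose(rA, rB, rtol=1e-12, atol=0.0)
    viableA, viableB = rA < p.M, rB < p.M
    a_stable = viableA and not tie and (rA < rB or not viableB)
    b_stable = viableB and not tie and (rB < rA or not viableA)
    return [
        ColonySteadyState("trivial", p.M, 0.0, 0.0,
                          stable=not (viableA or viableB), viable=True),
        ColonySteadyState("A_excludes_B", rA, max(p.M - rA, 0.0), 0.0,
                          stable=a_stable, viable=viableA, tie=bool(tie)),
        ColonySteadyState("B_excludes_A", rB, 0.0, max(p.M - rB, 0.0),
                          stable=b_stable, viable=viableB, tie=bool(tie)),
    ]


def integrate_colony_ode(
    p: ColonyCompetitionParams,
    A0: float,
    B0: float,
    t_end: float,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Explicit time-stepped trajectory of (A, B), halving dt on negativity.

    r(t) is computed as M - A - B at every step, so site conservation holds
    identically.  Returns a DataFrame with columns t, A, B, r.
    """
    if A0 < 0 or B0 < 0 or A0 + B0 > p.M:
        raise ValueError("need A0, B0 >= 0 and A0 + B0 <= M")
    ts, As, Bs = [0.0], [float(A0)], [float(B0)]
    t, A, B = 0.0, float(A0), float(B0)
    while t < t_end - 1e-12:
        h = min(dt, t_end - t)
        while True:
            r = p.M - A - B
            A1 = A + h * A * (p.kA * r - p.DA)
            B1 = B + h * B * (p.kB * r - p.DB)
            if A1 >= 0 and B1 >= 0 and A1 + B1 <= p.M:
                break
            h /= 2.0
            if h < 1e-12:
                raise RuntimeError("step size underflow in colony ODE integration")
        A, B, t = A1, B1, t + h
        ts.append(t), As.append(A), Bs.append(B)
    df = pd.DataFrame({"t": ts, "A": As, "B": Bs})
    df["r"] = p.M - df["A"] - df["B"]
    return df
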