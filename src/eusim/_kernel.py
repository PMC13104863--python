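"""Numba inner loop for the agent-based simulator.

State is a structure-of-arrays population with a fixed capacity: ``alive``
(uint8), ``sex`` (uint8, 1 = female), ``age`` (int64, ticks) and ``gcode``
(uint8, the number of B-allele copies: 0 = AA, 1 = AB, 2 = BB).  Dead slots
are compacted to the front of the arrays at the start of every tick.

Per tick, in order: deaths (Gompertz-by-genotype combined with logistic
density mortality), queen replacement (linear mode), births, aging of the
pre-existing survivors (newborns stay at age 0 and neither die nor reproduce
in their birth tick).

Randomness uses numba's global np.random state; pass ``seed >= 0`` to reseed
at entry (one run = one seed) or ``seed = -1`` to continue an already-seeded
stream (used by the colony metapopulation, which seeds once per run).
"""

import numpy as np
from numba import njit

MODE_EXPONENTIAL = 0
MODE_LINEAR = 1

OUTCOME_UNDECIDED = 0
OUTCOME_FIXED_A = 1
OUTCOME_FIXED_B = 2
OUTCOME_EXTINCT = 3


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _compact(alive, sex, age, gcode, used, queen):
    j = 0
    newq = -1
    for i in range(used):
        if alive[i] == 1:
            if j != i:
                alive[j] = 1
                sex[j] = sex[i]
                age[j] = age[i]
                gcode[j] = gcode[i]
            if i == queen:
                newq = j
            j += 1
    for i in range(j, used):
        alive[i] = 0
    return j, newq


@njit(cache=True)
def _spawn(alive, sex, age, gcode, used, cap, litter, mg, fg):
    """Append a litter from mother genotype mg and father genotype fg."""
    for _ in range(litter):
        if used >= cap:
            break
        g = 0
        if mg == 2 or (mg == 1 and np.random.random() < 0.5):
            g += 1
        if fg == 2 or (fg == 1 and np.random.random() < 0.5):
            g += 1
        alive[used] = 1
        sex[used] = 1 if np.random.random() < 0.5 else 0
        age[used] = 0
        gcode[used] = g
        used += 1
    return used


@njit(cache=True)
def run_ticks(
    alive,
    sex,
    age,
    gcode,
    used,
    queen,
    queenless,
    mode,
    maturity,
    p_repro,
    litter,
    K,
    w,
    mort,
    queen_delay,
    sperm_code,
    n_ticks,
    stop_on_fix,
    freq_out,
    n_out,
    meanage_out,
    seed,
):
    """Advance the population up to ``n_ticks`` ticks.

    ``queen_delay``: ticks a linear-mode population stays queenless before a
    replacement is drawn (0 = immediate, -1 = never replace).
    ``sperm_code``: fixed father genotype for queen matings (ant-mode stored
    sperm); -1 draws a random living mature male per reproduction event.

    Returns (outcome, ticks_done, used, queen, queenless); per-tick allele-B
    frequency, population size and mean age are written into the out arrays.
    """
    if seed >= 0:
        np.random.seed(seed)
    cap = alive.shape[0]
    amax = mort.shape[1]
    males = np.empty(cap, np.int64)
    females = np.empty(cap, np.int64)
    outcome = OUTCOME_UNDECIDED
    t_done = 0
    for t in range(n_ticks):
        used, queen = _compact(alive, sex, age, gcode, used, queen)
        N = used
        if N == 0:
            freq_out[t] = np.nan
            n_out[t] = 0
            meanage_out[t] = np.nan
            t_done = t + 1
            outcome = OUTCOME_EXTINCT
            break

        z = (N - K) / w
        if z > 35.0:
            dens = 1.0
        elif z < -35.0:
            dens = 0.0
        else:
            dens = 1.0 / (1.0 + np.exp(-z))

        for i in range(N):
            a = age[i]
            if a >= amax:
                a = amax - 1
            d_age = mort[gcode[i], a]
            p = 1.0 - (1.0 - d_age) * (1.0 - dens)
            if np.random.random() < p:
                alive[i] = 0

        if mode == MODE_LINEAR:
            if queen >= 0 and alive[queen] == 0:
                queen = -1
            if queen < 0 and queen_delay >= 0:
                if queenless >= queen_delay:
                    nf = 0
                    for i in range(N):
                        if alive[i] == 1 and sex[i] == 1 and age[i] >= maturity:
                            females[nf] = i
                            nf += 1
                    if nf > 0:
                        queen = females[np.random.randint(nf)]
                        queenless = 0
                    else:
                        queenless += 1
                else:
                    queenless += 1

        nm = 0
        for i in range(N):
            if alive[i] == 1 and sex[i] == 0 and age[i] >= maturity:
                males[nm] = i
                nm += 1

        pre = used
        if mode == MODE_EXPONENTIAL:
            for i in range(pre):
                if alive[i] == 1 and sex[i] == 1 and age[i] >= maturity:
                    if np.random.random() < p_repro and nm > 0:
                        fg = gcode[males[np.random.randint(nm)]]
                        used = _spawn(
                            alive, sex, age, gcode, used, cap, litter, gcode[i], fg
                        )
        else:
            if queen >= 0 and alive[queen] == 1 and age[queen] >= maturity:
                if np.random.random() < p_repro:
                    fg = -1
                    if sperm_code >= 0:
                        fg = sperm_code
                    elif nm > 0:
                        fg = gcode[males[np.random.randint(nm)]]
                    if fg >= 0:
                        used = _spawn(
                            alive, sex, age, gcode, used, cap, litter, gcode[queen], fg
                        )

        for i in range(pre):
            if alive[i] == 1:
                age[i] += 1

        N2 = 0
        B2 = 0
        asum = 0
        for i in range(used):
            if alive[i] == 1:
                N2 += 1
                B2 += gcode[i]
                asum += age[i]
        n_out[t] = N2
        if N2 > 0:
            freq_out[t] = B2 / (2.0 * N2)
            meanage_out[t] = asum / N2
        else:
            freq_out[t] = np.nan
            meanage_out[t] = np.nan
        t_done = t + 1
        if N2 == 0:
            outcome = OUTCOME_EXTINCT
            break
        if stop_on_fix == 1:
            if B2 == 0:
                outcome = OUTCOME_FIXED_A
                break
            if B2 == 2 * N2:
                outcome = OUTCOME_FIXED_B
                break
    return outcome, t_done, used, queen, queenless
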