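"""Colony metapopulation: exponential colony reproduction over linear colonies.

Within each colony, individuals follow the linear (single-queen) rules of
:mod:`eusim.abm`.  Colonies themselves reproduce exponentially, limited by a
logistic founding probability ``1 / (1 + exp((C - C_cap)/w_c))`` in the
current colony count ``C``.  Two eusocial lifestyles are modeled:

*Ant mode* — new colonies are founded by a single new queen carrying an
inexhaustible sperm supply from a mating flight (a male genotype drawn from
reproductive males across dispersing colonies that tick); queens never remate
and a colony dies with its queen.

*Mole-rat mode* — queens mate within the colony and are replaced (after a
delay) from colony females when they die; colonies at threshold size send
out groups of pioneers to found new colonies, and every colony faces a small
per-tick probability of a disaster that kills most members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _kernel
from .abm import Population, PopulationConfig
from .gompertz import Allele
from .reporting import ExperimentSummary, replicate_seed, summarize_experiment

__all__ = [
    "MetapopConfig",
    "Colony",
    "MetapopResult",
    "founding_probability",
    "ant_found_colony",
    "molerat_seed",
    "disaster_check",
    "metapop_run",
    "colony_fixation_experiment",
]


def _default_colony_cfg() -> PopulationConfig:
    # within-colony life history: same individual rules, but a per-colony
    # resource cap high enough that crowding rarely dominates senescent death
    return PopulationConfig(mode="linear", K=144.0, w=14.0, init_size=12)


@dataclass(frozen=True)
class MetapopConfig:
    """Metapopulation parameters superimposed on a within-colony config."""

    mode: Literal["ant", "molerat"] = "molerat"
    colony: PopulationConfig = field(default_factory=_default_colony_cfg)
    threshold_colony_size: int = 24
    C_cap: float = 18.0  # colony-count scale of the founding logistic
    w_c: float = 2.0
    p_disaster: float = 0.045  # per-colony per-tick (mole-rat mode)
    p_disaster_kill: float = 0.9
    ticks_to_queen_replacement: int = 6
    pioneers_per_event: int = 10
    n_colonies_init: int = 6
    max_ticks: int = 20_000

    def __post_init__(self) -> None:
        if self.mode not in ("ant", "molerat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for p in (self.p_disaster, self.p_disaster_kill):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.threshold_colony_size < 2:
            raise ValueError("threshold_colony_size must be >= 2")
        if self.pioneers_per_event < 1 or self.C_cap <= 0 or self.w_c <= 0:
            raise ValueError("invalid founding parameters")

    def colony_cfg(self) -> PopulationConfig:
        """Within-colony config with the mode's queen-replacement rule."""
        delay = -1 if self.mode == "ant" else self.ticks_to_queen_replacement
        return self.colony.with_(mode="linear", queen_delay=delay)


class Colony:
    """One colony: a linear-mode population plus colony-level state."""

    _next_id = 0

    def __init__(
        self,
        pop: Population,
        founded_at: int = 0,
        sperm_code: int = -1,
    ):
        self.id = Colony._next_id
        Colony._next_id += 1
        self.pop = pop
        self.founded_at = founded_at
        self.sperm_code = sperm_code  # ant mode: stored mating-flight sperm

    @property
    def size(self) -> int:
        return self.pop.size

    @property
    def queenless(self) -> bool:
        q = self.pop.queen
        return q < 0 or self.pop.alive[q] == 0

    def monomorphic(self) -> bool:
        m = self.pop.alive[: self.pop.used] == 1
        g = self.pop.gcode[: self.pop.used][m]
        return g.size > 0 and (np.all(g == 0) or np.all(g == 2))

    def mature_male_codes(self) -> np.ndarray:
        p = self.pop
        m = (
            (p.alive[: p.used] == 1)
            & (p.sex[: p.used] == 0)
            & (p.age[: p.used] >= p.cfg.maturity_age)
        )
        return p.gcode[: p.used][m]

    def kill_fraction(self, p_kill: float, rng: np.random.Generator) -> None:
        p = self.pop
        m = np.flatnonzero(p.alive[: p.used] == 1)
        dead = m[rng.random(m.size) < p_kill]
        p.alive[dead] = 0
        if p.queen >= 0 and p.alive[p.queen] == 0:
            p.queen = -1


def founding_probability(n_colonies: int, C_cap: float, w_c: float) -> float:
    """Logistic limit on colony founding in the current colony count."""
    z = (n_colonies - C_cap) / w_c
    if z > 35.0:
        return 0.0
    if z < -35.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(z))


def _empty_colony(mcfg: MetapopConfig, pop_template: Population, tick: int,
                  sperm_code: int = -1) -> Colony:
    cfg = mcfg.colony_cfg()
    pop = Population(
        cfg,
        pop_template.alleleA,
        pop_template.alleleB,
        capacity=int((cfg.K + 8 * cfg.w + 32) * (cfg.litter_size + 1)),
        mort=pop_template.mort,
    )
    return Colony(pop, founded_at=tick, sperm_code=sperm_code)


def ant_found_colony(
    source: Colony,
    mcfg: MetapopConfig,
    n_colonies: int,
    male_pool: np.ndarray,
    rng: np.random.Generator,
    tick: int,
) -> Colony | None:
    """Attempt an ant-mode founding from a threshold-size source colony.

    A new queen (an offspring genotype of the source queen and its stored
    sperm) mates in flight with a male genotype drawn from the pool of
    reproductive males across dispersing colonies, then founds a one-queen
    colony with that sperm stored for life.  Returns None on failure.
    """
    if source.size < mcfg.threshold_colony_size or source.queenless:
        return None
    if male_pool.size == 0:
        return None
    if rng.random() >= founding_probability(n_colonies, mcfg.C_cap, mcfg.w_c):
        return None
    pop = source.pop
    qg = int(pop.gcode[pop.queen])
    sg = source.sperm_code if source.sperm_code >= 0 else -1
    if sg < 0:  # source founded before sperm tracking (initial colonies)
        males = source.mature_male_codes()
        if males.size == 0:
            return None
        sg = int(rng.choice(males))
    queen_g = _gamete(qg, rng) + _gamete(sg, rng)
    new_sperm = int(rng.choice(male_pool))
    col = _empty_colony(mcfg, pop, tick, sperm_code=new_sperm)
    p = col.pop
    p.alive[0], p.sex[0], p.gcode[0] = 1, 1, queen_g
    p.age[0] = p.cfg.maturity_age  # founding reproductives disperse as adults
    p.used, p.queen = 1, 0
    return col


def molerat_seed(
    source: Colony,
    mcfg: MetapopConfig,
    n_colonies: int,
    rng: np.random.Generator,
    tick: int,
) -> Colony | None:
    """Attempt a mole-rat founding: pioneers leave the source colony.

    Pioneers are removed from the source regardless of success; a founding
    with no female pioneer fails (the pioneers are lost).
    """
    if source.size < mcfg.threshold_colony_size:
        return None
    if rng.random() >= founding_probability(n_colonies, mcfg.C_cap, mcfg.w_c):
        return None
    p = source.pop
    living = np.flatnonzero(p.alive[: p.used] == 1)
    n_pioneers = min(mcfg.pioneers_per_event, living.size - 1)
    if n_pioneers < 1:
        return None
    idx = rng.choice(living, size=n_pioneers, replace=False)
    # never draft the source queen into a pioneer party
    idx = idx[idx != p.queen]
    if idx.size == 0:
        return None
    pioneers = [(int(p.sex[i]), int(p.age[i]), int(p.gcode[i])) for i in idx]
    p.alive[idx] = 0
    females = [k for k, (s, _, _) in enumerate(pioneers) if s == 1]
    if not females:
        return None  # all-male party cannot found a colony
    col = _empty_colony(mcfg, p, tick)
    cp = col.pop
    for j, (s, a, g) in enumerate(pioneers):
        cp.alive[j], cp.sex[j], cp.age[j], cp.gcode[j] = 1, s, a, g
    cp.used = len(pioneers)
    queen_slot = int(rng.choice(females))
    cp.queen = queen_slot
    # a pre-mature queen simply waits until maturity to reproduce
    return col


def disaster_check(
    colony: Colony, mcfg: MetapopConfig, rng: np.random.Generator
) -> bool:
    """Mole-rat mode: with p_disaster, kill each member with p_disaster_kill.

    Returns True if a disaster struck.
    """
    if rng.random() >= mcfg.p_disaster:
        return False
    colony.kill_fraction(mcfg.p_disaster_kill, rng)
    return True


def _gamete(gc: int, rng: np.random.Generator) -> int:
    if gc == 0:
        return 0
    if gc == 2:
        return 1
    return int(rng.random() < 0.5)


@dataclass
class MetapopResult:
    outcome: Literal["fixed_A", "fixed_B", "none"]
    extinct: bool
    ticks_elapsed: int
    freqB: np.ndarray
    popsize: np.ndarray
    n_colonies: np.ndarray
    monomorphic_fraction: np.ndarray
    final_ages: np.ndarray
    seed: int


def metapop_run(
    mcfg: MetapopConfig,
    alleleA: Allele,
    alleleB: Allele,
    seed: int = 0,
    init_freq: float = 0.5,
) -> MetapopResult:
    """Run one metapopulation competition to metapopulation-wide fixation.

    Per tick: within-colony linear-mode ticks, ant-mode colony deaths (queen
    death), mole-rat disasters, then dispersal/founding events; colonies that
    end empty (or queenless with no females) collapse.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    _kernel.seed_rng(int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1)))

    cfg = mcfg.colony_cfg()
    template = Population.initialize(cfg, alleleA, alleleB, init_freq, rng)
    colonies: list[Colony] = [Colony(template)]
    for _ in range(mcfg.n_colonies_init - 1):
        pop = Population.initialize(cfg, alleleA, alleleB, init_freq, rng)
        pop.mort = template.mort
        colonies.append(Colony(pop))

    freqs, sizes, ncol, mono = [], [], [], []
    outcome, extinct, t = "none", False, 0
    for t in range(1, mcfg.max_ticks + 1):
        for col in colonies:
            col.pop.tick(seed=-1, n_ticks=1, sperm_code=col.sperm_code)

        survivors: list[Colony] = []
        for col in colonies:
            if mcfg.mode == "ant" and col.queenless:
                continue  # the colony dies with its queen
            if mcfg.mode == "molerat":
                disaster_check(col, mcfg, rng)
            n_alive = col.size
            if n_alive == 0:
                continue
            if col.queenless:
                p = col.pop
                has_female = np.any(
                    (p.alive[: p.used] == 1) & (p.sex[: p.used] == 1)
                )
                if not has_female:
                    continue  # no queen can ever be recruited
            survivors.append(col)
        colonies = survivors

        if mcfg.mode == "ant":
            dispersing = [
                c for c in colonies
                if c.size >= mcfg.threshold_colony_size and not c.queenless
            ]
            pool = (
                np.concatenate([c.mature_male_codes() for c in dispersing])
                if dispersing
                else np.empty(0, np.uint8)
            )
            for col in list(dispersing):
                new = ant_found_colony(col, mcfg, len(colonies), pool, rng, t)
                if new is not None:
                    colonies.append(new)
        else:
            for col in list(colonies):
                new = molerat_seed(col, mcfg, len(colonies), rng, t)
                if new is not None:
                    colonies.append(new)

        nA = nB = 0
        n_tot = 0
        n_mono = 0
        for col in colonies:
            a, b = col.pop.allele_counts()
            nA += a
            nB += b
            n_tot += col.size
            n_mono += col.monomorphic()
        ncol.append(len(colonies))
        sizes.append(n_tot)
        mono.append(n_mono / len(colonies) if colonies else np.nan)
        freqs.append(nB / (nA + nB) if nA + nB else np.nan)
        if n_tot == 0:
            extinct = True
            break
        if nB == 0:
            outcome = "fixed_A"
            break
        if nA == 0:
            outcome = "fixed_B"
            break

    ages = (
        np.concatenate([c.pop.ages() for c in colonies])
        if colonies
        else np.empty(0, np.int64)
    )
    return MetapopResult(
        outcome=outcome,
        extinct=extinct,
        ticks_elapsed=t,
        freqB=np.array(freqs),
        popsize=np.array(sizes),
        n_colonies=np.array(ncol),
        monomorphic_fraction=np.array(mono),
        final_ages=ages,
        seed=seed,
    )


def colony_fixation_experiment(
    mcfg: MetapopConfig,
    alleleA: Allele,
    alleleB: Allele,
    n_reps: int,
    seed: int = 0,
    init_freq: float = 0.5,
    keep_results: bool = False,
) -> ExperimentSummary:
    """Replicate :func:`metapop_run` and summarize fixation statistics."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = [
        metapop_run(mcfg, alleleA, alleleB, replicate_seed(seed, rep), init_freq)
        for rep in range(n_reps)
    ]
    summary = summarize_experiment(
        [r.outcome for r in results],
        labels=(alleleA.label, alleleB.label),
        seed=seed,
        final_sizes=[int(r.popsize[-1]) if len(r.popsize) else 0 for r in results],
        pooled_ages=np.concatenate([r.final_ages for r in results]),
        mean_sizes=[float(np.mean(r.popsize)) if len(r.popsize) else 0.0 for r in results],
    )
    if keep_results:
        summary.results = results
    return summary
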