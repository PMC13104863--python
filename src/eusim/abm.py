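"""Agent-based diploid simulator for allele competition (the "NMR model").

Individuals are diploid, male or female, and age in discrete ticks.  A single
biallelic locus carries a Vitality allele and a Longevity allele; the
phenotype (V, L) maps to Gompertz parameters (gamma = 0: the age-independent
mortality role is played by resource limitation).  Per tick each individual
dies with probability ``1 - (1 - D_age)(1 - d(N))`` where ``D_age`` is the
Gompertz death probability for its phenotype and ``d(N) = 1/(1+exp(-(N-K)/w))``
is logistic density-dependent mortality.  Reproduction is either
*exponential* (every mature female reproduces with probability ``p_repro``
per tick, mating with a random mature male) or *linear* (eusocial: only the
queen reproduces; on her death a replacement is drawn uniformly from the
living mature females).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import _kernel
from .gompertz import Allele, MappingConfig, allele_to_gompertz, death_probability
from .reporting import ExperimentSummary, replicate_seed, summarize_experiment

__all__ = [
    "PopulationConfig",
    "Population",
    "Individual",
    "SimResult",
    "phenotype",
    "mendelian_offspring",
    "density_mortality",
    "mortality_probability",
    "mortality_table",
    "run_competition",
    "fixation_experiment",
]

_OUTCOME_NAMES = {
    _kernel.OUTCOME_UNDECIDED: "none",
    _kernel.OUTCOME_FIXED_A: "fixed_A",
    _kernel.OUTCOME_FIXED_B: "fixed_B",
    _kernel.OUTCOME_EXTINCT: "none",
}


@dataclass(frozen=True)
class PopulationConfig:
    """Life-history and resource-limitation parameters of one population.

    ``K`` is the logistic density-mortality midpoint (the population size at
    which crowding kills half the individuals per tick) and ``w`` its width.
    ``queen_delay`` is the number of ticks a linear population stays
    queenless before a replacement is promoted (0 = immediate; -1 = never,
    used by ant-mode colonies that die with their queen).
    """

    mode: Literal["linear", "exponential"] = "linear"
    maturity_age: int = 4
    p_repro: float = 0.5
    litter_size: int = 3
    K: float = 2400.0
    w: float = 240.0
    dominance: Literal["dominant_recessive", "codominant"] = "dominant_recessive"
    queen_delay: int = 0
    max_ticks: int = 30_000
    init_size: int | None = None
    init_age_max: int = 8
    mapping: MappingConfig = field(default_factory=MappingConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "exponential"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.p_repro <= 1.0:
            raise ValueError("p_repro must be in [0, 1]")
        if self.litter_size < 1:
            raise ValueError("litter_size must be >= 1")
        if not self.K > 0 or not self.w > 0:
            raise ValueError("density parameters K and w must be positive")
        if self.maturity_age < 0 or self.max_ticks < 1:
            raise ValueError("maturity_age must be >= 0 and max_ticks >= 1")
        if self.dominance not in ("dominant_recessive", "codominant"):
            raise ValueError(f"unknown dominance rule {self.dominance!r}")

    @property
    def mode_code(self) -> int:
        return _kernel.MODE_LINEAR if self.mode == "linear" else _kernel.MODE_EXPONENTIAL

    def default_init_size(self) -> int:
        if self.init_size is not None:
            return self.init_size
        return 64 if self.mode == "linear" else max(8, int(round(0.6 * self.K)))

    def with_(self, **kw) -> "PopulationConfig":
        return replace(self, **kw)


def phenotype(
    genotype: tuple[Allele, Allele], rule: str = "dominant_recessive"
) -> tuple[float, float]:
    """(V, L) expressed by an unordered allele pair.

    Homozygotes express their allele.  Heterozygotes express the allele
    flagged ``dominant`` under the dominant/recessive rule (exactly one of
    the pair must be flagged), or the arithmetic mean of V and of L under
    the codominant rule.
    """
    a, b = genotype
    if a.label == b.label:
        return a.V, a.L
    if rule == "codominant":
        return (a.V + b.V) / 2.0, (a.L + b.L) / 2.0
    if rule != "dominant_recessive":
        raise ValueError(f"unknown dominance rule {rule!r}")
    if a.dominant == b.dominant:
        raise ValueError(
            "dominant_recessive rule needs exactly one dominant allele in "
            f"the pair ({a.label!r}, {b.label!r})"
        )
    return (a.V, a.L) if a.dominant else (b.V, b.L)


def mendelian_offspring(
    mother: tuple[Allele, Allele],
    father: tuple[Allele, Allele],
    rng: np.random.Generator,
) -> tuple[tuple[Allele, Allele], str]:
    """One offspring: a uniform allele from each parent, sex 50/50."""
    gm = mother[int(rng.integers(2))]
    gf = father[int(rng.integers(2))]
    sex = "female" if rng.random() < 0.5 else "male"
    return (gm, gf), sex


def density_mortality(N: float, K: float, w: float) -> float:
    """Logistic crowding mortality d(N) = 1 / (1 + exp(-(N - K)/w))."""
    z = (N - K) / w
    if z > 35.0:
        return 1.0
    if z < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-z))


def mortality_probability(ind: "Individual", N: int, cfg: PopulationConfig) -> float:
    """Per-tick death probability: independent Gompertz and density risks.

    ``p = 1 - (1 - D_age)(1 - d(N))`` with gamma = 0 in the Gompertz part.
    """
    V, L = phenotype(ind.genotype, cfg.dominance)
    params = allele_to_gompertz(Allele("pheno", V, L), cfg.mapping, gamma=0.0)
    D = float(death_probability(params, ind.age, dt=1.0))
    d = density_mortality(N, cfg.K, cfg.w)
    return 1.0 - (1.0 - D) * (1.0 - d)


def mortality_table(
    alleleA: Allele, alleleB: Allele, cfg: PopulationConfig, amax: int | None = None
) -> np.ndarray:
    """Death probability by (genotype code, age); genotype code = B-allele count."""
    genos = [(alleleA, alleleA), (alleleA, alleleB), (alleleB, alleleB)]
    params = []
    for g in genos:
        V, L = phenotype(g, cfg.dominance)
        params.append(allele_to_gompertz(Allele("pheno", V, L), cfg.mapping, gamma=0.0))
    if amax is None:
        # cap the age axis where every genotype's one-tick death is ~ certain
        amax = 64
        while amax < 4096:
            if all(death_probability(p, amax - 1) > 1.0 - 1e-12 for p in params):
                break
            amax *= 2
    ages = np.arange(amax, dtype=float)
    return np.vstack([np.asarray(death_probability(p, ages)) for p in params])


@dataclass
class Individual:
    """One diploid agent; used for fixtures and small-scale API-level tests."""

    id: int
    sex: Literal["male", "female"]
    age: int
    genotype: tuple[Allele, Allele]
    alive: bool = True
    is_queen: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")


class Population:
    """Structure-of-arrays population bound to an allele pair and a config."""

    def __init__(
        self,
        cfg: PopulationConfig,
        alleleA: Allele,
        alleleB: Allele,
        capacity: int | None = None,
        mort: np.ndarray | None = None,
    ):
        self.cfg = cfg
        self.alleleA = alleleA
        self.alleleB = alleleB
        if capacity is None:
            headroom = cfg.K + 8.0 * cfg.w + 4 * cfg.default_init_size() + 64
            capacity = int(headroom * (cfg.litter_size + 1))
        self.alive = np.zeros(capacity, np.uint8)
        self.sex = np.zeros(capacity, np.uint8)
        self.age = np.zeros(capacity, np.int64)
        self.gcode = np.zeros(capacity, np.uint8)
        self.used = 0
        self.queen = -1
        self.queenless = 0
        self.mort = mort if mort is not None else mortality_table(alleleA, alleleB, cfg)

    # -- construction -----------------------------------------------------
    @classmethod
    def initialize(
        cls,
        cfg: PopulationConfig,
        alleleA: Allele,
        alleleB: Allele,
        init_freq: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> "Population":
        """Founding population: homozygotes at exact frequency, balanced sexes."""
        rng = rng or np.random.default_rng()
        n = cfg.default_init_size()
        pop = cls(cfg, alleleA, alleleB)
        nB = int(round(n * init_freq))
        g = np.array([2] * nB + [0] * (n - nB), np.uint8)
        rng.shuffle(g)
        s = np.array([1] * (n // 2) + [0] * (n - n // 2), np.uint8)
        rng.shuffle(s)
        pop.alive[:n] = 1
        pop.sex[:n] = s
        pop.age[:n] = rng.integers(0, cfg.init_age_max + 1, n)
        pop.gcode[:n] = g
        pop.used = n
        if cfg.mode == "linear":
            pop._elect_queen(rng)
        return pop

    @classmethod
    def from_individuals(
        cls,
        cfg: PopulationConfig,
        alleleA: Allele,
        alleleB: Allele,
        individuals: Sequence[Individual],
    ) -> "Population":
        pop = cls(cfg, alleleA, alleleB, capacity=max(64, 8 * (len(individuals) + 8)))
        code = {alleleA.label: 0, alleleB.label: 1}
        for i, ind in enumerate(individuals):
            pop.alive[i] = 1 if ind.alive else 0
            pop.sex[i] = 1 if ind.sex == "female" else 0
            pop.age[i] = ind.age
            try:
                pop.gcode[i] = code[ind.genotype[0].label] + code[ind.genotype[1].label]
            except KeyError as e:  # genotype not drawn from this allele pair
                raise ValueError(f"unknown allele label {e.args[0]!r}") from None
            if ind.is_queen:
                pop.queen = i
        pop.used = len(individuals)
        return pop

    def _elect_queen(self, rng: np.random.Generator) -> None:
        mat = np.flatnonzero(
            (self.alive[: self.used] == 1)
            & (self.sex[: self.used] == 1)
            & (self.age[: self.used] >= self.cfg.maturity_age)
        )
        self.queen = int(rng.choice(mat)) if len(mat) else -1

    # -- bookkeeping -------------------------------------------------------
    @property
    def size(self) -> int:
        return int(self.alive[: self.used].sum())

    def allele_counts(self) -> tuple[int, int]:
        """(copies of A, copies of B) among the living."""
        m = self.alive[: self.used] == 1
        b = int(self.gcode[: self.used][m].astype(np.int64).sum())
        return 2 * int(m.sum()) - b, b

    def ages(self) -> np.ndarray:
        return self.age[: self.used][self.alive[: self.used] == 1].copy()

    def freqB(self) -> float:
        a, b = self.allele_counts()
        return b / (a + b) if a + b else float("nan")

    # -- dynamics ----------------------------------------------------------
    def tick(
        self,
        seed: int = -1,
        n_ticks: int = 1,
        stop_on_fix: bool = False,
        sperm_code: int = -1,
    ):
        """Advance ``n_ticks`` ticks in place; returns (outcome, ticks_done).

        ``seed >= 0`` reseeds the simulation RNG; -1 continues the current
        stream (the caller must have seeded it once).  ``sperm_code >= 0``
        fixes the father genotype of queen matings (ant-mode stored sperm).
        """
        cfg = self.cfg
        freq = np.empty(n_ticks)
        nn = np.empty(n_ticks, np.int64)
        ma = np.empty(n_ticks)
        out, t_done, self.used, self.queen, self.queenless = _kernel.run_ticks(
            self.alive, self.sex, self.age, self.gcode,
            self.used, self.queen, self.queenless,
            cfg.mode_code, cfg.maturity_age, cfg.p_repro, cfg.litter_size,
            cfg.K, cfg.w, self.mort, cfg.queen_delay,
            sperm_code, n_ticks, 1 if stop_on_fix else 0,
            freq, nn, ma, seed,
        )
        self._last_series = (freq[:t_done], nn[:t_done], ma[:t_done])
        return out, t_done


@dataclass
class SimResult:
    """Outcome and per-tick series of a single competition run."""

    outcome: Literal["fixed_A", "fixed_B", "none"]
    extinct: bool
    ticks_elapsed: int
    freqB: np.ndarray  # allele-B (second allele) frequency per tick
    popsize: np.ndarray
    mean_age: np.ndarray
    final_ages: np.ndarray
    seed: int

    @property
    def winner(self) -> str | None:
        return {"fixed_A": "A", "fixed_B": "B"}.get(self.outcome)


def run_competition(
    cfg: PopulationConfig,
    alleleA: Allele,
    alleleB: Allele,
    init_freq: float = 0.5,
    seed: int = 0,
) -> SimResult:
    """Run one competition from ``init_freq`` B-allele frequency to fixation.

    The run stops when either allele reaches frequency 1, the population
    goes extinct, or ``cfg.max_ticks`` elapses (outcome ``none``).
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    pop = Population.initialize(cfg, alleleA, alleleB, init_freq, rng)
    a0, b0 = pop.allele_counts()
    if b0 == 0 or a0 == 0:
        outcome = "fixed_A" if b0 == 0 else "fixed_B"
        empty = np.empty(0)
        return SimResult(outcome, False, 0, empty, np.empty(0, np.int64), empty,
                         pop.ages(), seed)
    kseed = int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))
    out, t_done = pop.tick(seed=kseed, n_ticks=cfg.max_ticks, stop_on_fix=True)
    freq, nn, ma = pop._last_series
    return SimResult(
        outcome=_OUTCOME_NAMES[out],
        extinct=out == _kernel.OUTCOME_EXTINCT,
        ticks_elapsed=t_done,
        freqB=freq,
        popsize=nn,
        mean_age=ma,
        final_ages=pop.ages(),
        seed=seed,
    )


def fixation_experiment(
    cfg: PopulationConfig,
    alleleA: Allele,
    alleleB: Allele,
    n_reps: int,
    seed: int = 0,
    init_freq: float = 0.5,
    keep_results: bool = False,
) -> ExperimentSummary:
    """Replicate :func:`run_competition` and summarize fixation statistics.

    Per-replicate seeds expand from the global seed by a counter-based
    scheme, so any replicate can be re-run in isolation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = []
    for rep in range(n_reps):
        results.append(
            run_competition(cfg, alleleA, alleleB, init_freq, replicate_seed(seed, rep))
        )
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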