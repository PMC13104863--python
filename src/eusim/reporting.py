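"""Experiment statistics, seed bookkeeping, fixtures and config I/O."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "wald_ci",
    "replicate_seed",
    "ExperimentSummary",
    "summarize_experiment",
    "summarize_run",
    "make_fixture_population",
    "config_hash",
    "load_config",
    "save_config",
]


def wald_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation (Wald) CI for a binomial proportion, clipped to [0,1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = k / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def variance_effective_size(freq: np.ndarray, dt: int = 1) -> float:
    """Variance-effective population size from allele-frequency fluctuations.

    Pools per-step increments of a frequency series: with drift alone,
    E[(p_{t+dt} - p_t)^2] = p_t (1 - p_t) dt / (2 Ne), so
    Ne = dt * sum p(1-p) / (2 sum (dp)^2).  The estimate is per simulation
    tick (not per generation) and is downward-biased when selection also
    moves the frequency; it is reported as a drift-scale diagnostic only.
    """
    p = np.asarray(freq, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 2:
        raise ValueError("need at least two frequency observations")
    dp2 = np.diff(p) ** 2
    het = (p * (1.0 - p))[:-1]
    denom = 2.0 * dp2.sum()
    if denom == 0:
        return float("inf")
    return float(dt * het.sum() / denom)


def replicate_seed(master: int, rep: int) -> int:
    """Counter-based per-replicate seed (< 2**31), reproducible in isolation."""
    ss = np.random.SeedSequence(master, spawn_key=(rep,))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))


@dataclass
class ExperimentSummary:
    """Cross-replicate fixation statistics with 95% Wald intervals.

    Proportions are reported both over all replicates and over decided
    (fixed) replicates; undecided runs (max-ticks cap or extinction) are
    their own category.
    """

    labels: tuple[str, str]
    n_reps: int
    n_fixed: tuple[int, int]
    n_undecided: int
    seed: int
    prop_all: tuple[float, float] = (0.0, 0.0)
    prop_decided: tuple[float, float] = (0.0, 0.0)
    ci_all: tuple[tuple[float, float], tuple[float, float]] = ((0, 0), (0, 0))
    ci_decided: tuple[tuple[float, float], tuple[float, float]] = ((0, 0), (0, 0))
    mean_population_size: float = float("nan")
    pooled_ages: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    final_sizes: list[int] = field(default_factory=list)
    config_hash: str | None = None
    results: list | None = None

    def __post_init__(self) -> None:
        if sum(self.n_fixed) + self.n_undecided != self.n_reps:
            raise ValueError("fixation counts and undecided must sum to n_reps")
        ndec = sum(self.n_fixed)
        self.prop_all = tuple(k / self.n_reps for k in self.n_fixed)
        self.ci_all = tuple(wald_ci(k, self.n_reps) for k in self.n_fixed)
        if ndec:
            self.prop_decided = tuple(k / ndec for k in self.n_fixed)
            self.ci_decided = tuple(wald_ci(k, ndec) for k in self.n_fixed)
        else:
            self.prop_decided = (float("nan"), float("nan"))
            self.ci_decided = ((float("nan"),) * 2, (float("nan"),) * 2)

    def rows(self) -> list[dict]:
        out = []
        for i, lab in enumerate(self.labels):
            out.append(
                {
                    "allele": lab,
                    "n_fixed": self.n_fixed[i],
                    "n_reps": self.n_reps,
                    "proportion": self.prop_all[i],
                    "ci_low": self.ci_all[i][0],
                    "ci_high": self.ci_all[i][1],
                    "proportion_decided": self.prop_decided[i],
                }
            )
        out.append(
            {
                "allele": "(undecided)",
                "n_fixed": self.n_undecided,
                "n_reps": self.n_reps,
                "proportion": self.n_undecided / self.n_reps,
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "proportion_decided": float("nan"),
            }
        )
        return out


def summarize_experiment(
    outcomes: Sequence[str],
    labels: tuple[str, str],
    seed: int,
    final_sizes: Sequence[int] = (),
    pooled_ages: np.ndarray | None = None,
    mean_sizes: Sequence[float] = (),
    config_hash: str | None = None,
) -> ExperimentSummary:
    kA = sum(1 for o in outcomes if o == "fixed_A")
    kB = sum(1 for o in outcomes if o == "fixed_B")
    return ExperimentSummary(
        labels=labels,
        n_reps=len(outcomes),
        n_fixed=(kA, kB),
        n_undecided=len(outcomes) - kA - kB,
        seed=seed,
        mean_population_size=float(np.mean(mean_sizes)) if len(mean_sizes) else float("nan"),
        pooled_ages=np.asarray(pooled_ages if pooled_ages is not None else [], np.int64),
        final_sizes=list(final_sizes),
        config_hash=config_hash,
    )


def summarize_run(ages, sizes, outcome: str = "none", ticks: int | None = None) -> dict:
    """Deterministic per-run summary: age and size statistics, fixation tick."""
    ages = np.asarray(ages, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if ages.size == 0 or sizes.size == 0:
        raise ValueError("summarize_run needs nonempty series")
    return {
        "mean_age": float(np.mean(ages)),
        "median_age": float(np.median(ages)),
        "mean_size": float(np.mean(sizes)),
        "outcome": outcome,
        "fixation_tick": ticks if outcome in ("fixed_A", "fixed_B") else None,
    }


def make_fixture_population(spec, cfg, alleleA, alleleB):
    """Deterministic population from a list of (count, sex, age, genotype) rows.

    ``genotype`` is a two-letter string over {"A", "B"}, e.g. "AA" or "AB".
    The queen, if any, is marked with sex "queen" (a mature female).
    """
    from .abm import Individual, Population  # local import: abm imports reporting

    geno = {"A": alleleA, "B": alleleB}
    individuals = []
    next_id = 0
    for count, sex, age, gstr in spec:
        if len(gstr) != 2 or any(c not in geno for c in gstr):
            raise ValueError(f"invalid genotype label {gstr!r}")
        is_queen = sex == "queen"
        sx = "female" if is_queen else sex
        if sx not in ("male", "female"):
            raise ValueError(f"invalid sex {sex!r}")
        for _ in range(count):
            individuals.append(
                Individual(
                    id=next_id,
                    sex=sx,
                    age=age,
                    genotype=(geno[gstr[0]], geno[gstr[1]]),
                    is_queen=is_queen,
                )
            )
            is_queen = False  # only one queen even if count > 1
            next_id += 1
    return Population.from_individuals(cfg, alleleA, alleleB, individuals)


# -- config files ---------------------------------------------------------

def config_hash(d: dict) -> str:
    """Stable hash of an effective configuration (canonical JSON, sha256)."""
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"), default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _config_dict(cfg) -> dict:
    m = cfg.mapping
    return {
        "mode": cfg.mode,
        "maturity_age": cfg.maturity_age,
        "p_repro": cfg.p_repro,
        "litter_size": cfg.litter_size,
        "density": {"K": cfg.K, "w": cfg.w},
        "dominance": cfg.dominance,
        "queen_delay": cfg.queen_delay,
        "max_ticks": cfg.max_ticks,
        "init_size": cfg.init_size,
        "init_age_max": cfg.init_age_max,
        "mapping": {"alpha_ref": m.alpha_ref, "V_ref": m.V_ref, "rule": m.rule,
                    "gamma": m.gamma},
    }


def save_config(cfg, path) -> str:
    """Write a PopulationConfig as YAML; returns its hash."""
    import yaml

    d = _config_dict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
    return config_hash(d)


def load_config(path):
    """Read a YAML config written by :func:`save_config`."""
    import yaml

    from .abm import PopulationConfig
    from .gompertz import MappingConfig

    with open(path) as fh:
        d = yaml.safe_load(fh)
    dens = d.pop("density", {})
    mp = d.pop("mapping", {})
    cfg = PopulationConfig(
        K=dens.get("K", 2400.0),
        w=dens.get("w", 240.0),
        mapping=MappingConfig(
            alpha_ref=mp.get("alpha_ref", 0.002),
            V_ref=mp.get("V_ref", 1000.0),
            gamma=mp.get("gamma", 0.0),
            rule=mp.get("rule", "inverse"),
        ),
        **d,
    )
    return cfg, config_hash(_config_dict(cfg))
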