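# Methods

`eusim` asks a single question in several ways: when a heritable tradeoff
exists between *vitality* (the baseline Gompertz hazard, `alpha`) and
*longevity* (the exponential hazard-growth rate, `beta`), which side does
selection favor under eusocial (linear, single-queen) reproduction versus
ordinary (exponential, all-females) reproduction?

## Mortality model

Hazard follows the Gompertz–Makeham law `h(n) = alpha * exp(beta*n) + gamma`
with age `n` in ticks.  The per-tick death probability integrates the hazard
in closed form:

    D_n = 1 - exp( -(alpha/beta) e^{beta n} (e^{beta dt} - 1) - gamma dt ),

with an explicit `beta = 0` branch `1 - exp(-(alpha+gamma) dt)` (no small-
beta approximation).  Ticks are the unit of time throughout (`dt = 1`).

Alleles carry a Vitality score `V` (dimensionless) and a Longevity score `L`
(time units).  The mapping to Gompertz parameters is pluggable; the default
rule is

* `beta = ln(2) / L` — `L` is the mortality-doubling half-life, so the
  human-like value `L = 9` gives a hazard that doubles every 9 ticks;
* `alpha = alpha_ref * V_ref / V` — vitality inversely proportional to the
  baseline hazard, anchored at `V_ref = 1000 -> alpha_ref`.

`alpha_ref` is the one genuinely free constant of the mapping (the V-scale
and the hazard scale are not tied to each other by any printed value).  The
default `alpha_ref = 0.002` was calibrated once so that the reference
competition below reproduces the reference linear-mode fixation rate of
~58%; it implies a median lifespan of ~43 ticks for the (V=1000, L=9)
phenotype.  The analytical examples and the queen-effects experiments pin
`alpha_ref = 0.005` in their own configs (shorter lifespans make those
computations cheaper without changing their logic).
The hazard curves of the standard vitality allele (V=1000, L=9) and
longevity allele (V=900, L=10) cross at age `ln(1000/900)/(beta_V - beta_L)
~ 14` ticks: younger animals die less often under the vitality allele,
older animals under the longevity allele.  Everything downstream is a
tug-of-war over how much population-level weight lies on each side of that
crossover.

## Analytical competition model

Two alleles A and B with death probabilities `D_n`, `d_n` share an
age-structured population updated in discrete time: survivors shift one age
class per step, newborns enter at age 0 according to a growth law.  For any
birth law of the form `X_i = p_i * H(A, B)` (both alleles passing through
the same bottleneck `H`), coexistence is impossible and the sign of

    dF = sum_{n>=1} prod_{k<n}(1 - D_k)  -  sum_{n>=1} prod_{k<n}(1 - d_k)

decides the winner (positive: A excludes B).  Each series is a sum of
survivorships — an expected-lifetime measure.  Because the one-step
survival factors telescope into `exp(-cumulative hazard)`, the series is
evaluated in closed form per term and truncated when survivorship falls
below 1e-12; the discarded tail is bounded by a geometric series with ratio
below the last survival factor and is far below double-precision noise
(terms decay superexponentially).

Growth laws:

* linear — `A0 = g A/(A+B)`, `B0 = g B/(A+B)`: a queen's constant `g`
  offspring per tick, split by allele frequency (paternal transmission,
  random mating);
* exponential — `X_i = g * S(N) * i/(2N)` with the saturation function
  `S(x) = Ns x / (Ns + x - 2)`, which leaves a two-individual population
  unconstrained (`S(2) = 2`) and caps the effective female count at `Ns`.

Single-allele steady states have every age class at `X * S(n)`, so the
total is `X (1 + F)` with `F` the survivorship sum; for the linear law
`T = g (1 + F)` and for the exponential law `T = g Ns (1+F)/2 - Ns + 2`.
`steady_state()` iterates the update to a fixed point and is checked
against these closed forms; `match_gamma()` root-solves (Brent) for the
Makeham term `gamma'` that gives the exponential population the same
carrying capacity as the linear one.  Matching always leaves the
exponential population younger: the extra age-independent hazard compresses
the age pyramid.

Nullclines: for a tradeoff point `(x, y)` the competitor's hazard is
`(1-x) alpha e^{(1-y) beta n} + gamma`.  `dF` is monotone in `y`, so for
each `x` the root in `y` is bracketed by a sign change and refined with
Brent's method; a bracket without a sign change is reported as a missing
point, never fabricated.  The linear population's nullcline is computed at
the baseline `gamma`, the exponential one at `gamma'`; the latter is
steeper at the origin because the added age-independent hazard shifts
survivorship weight to young ages, where `alpha` (not `beta`) controls
survival.  Defaults for the analytical stack (`g = 2`, `Ns = 50`) keep the
two carrying capacities in a range where `gamma'` exists; with a shared
`g > 2` the matched exponential population is strongly age-compressed,
which is the regime of interest.

## Colony-site dynamics

Colonies of type A or B occupy sites on a landscape of `M` sites, seed
empty sites at per-colony rate `k_i * r` (`r = M - A - B` free sites) and
collapse at per-colony rate `D_i`:

    dA/dt = A (kA r - DA),      dB/dt = B (kB r - DB).

Fixed points are the empty landscape and the two exclusion states
`r* = D_i / k_i`; the exclusion state with the lower `r*` is stable (higher
`r*` is invadable).  Integration is explicit Euler with step halving on
negativity — the system is two-dimensional and non-stiff at these scales —
and `r` is computed as `M - A - B` so site conservation holds identically.
Ties `rA = rB` are reported as neutral rather than broken arbitrarily.
Because the within-colony steady population grows with the survivorship sum
`F`, any monotone map from colony size to higher `k` and lower `D` hands
the site competition to the same allele that wins within colonies.

## Agent-based model

Diploid agents with one biallelic locus; sex ratio 1:2 at birth; Mendelian
transmission.  Heterozygotes express the allele flagged dominant, or the
arithmetic mean of `(V, L)` under the codominant option.  Per tick, in
order:

1. deaths — each agent dies with `p = 1 - (1 - D_age)(1 - d(N))`, the
   independent-risk combination of its Gompertz term (`gamma = 0`; the
   age-independent role is played by crowding) and logistic density
   mortality `d(N) = 1/(1 + exp(-(N - K)/w))`;
2. queen replacement (linear mode) — a dead queen is replaced by a
   uniformly random living mature female, after a configurable queenless
   delay (0 in the individual model);
3. births — exponential mode: every mature female reproduces with
   probability `p_repro`, mating with a uniformly random living mature
   male; linear mode: only the queen reproduces.  A litter has
   `litter_size` offspring with one father;
4. aging — survivors gain one tick of age; newborns stay at age 0 and
   neither die nor reproduce in their birth tick.

The update order is a modeling choice (nothing forces deaths before
births); it guarantees that a tick's births come from the survivors of that
tick and that per-tick linear-mode growth is bounded by `litter_size`.

Defaults (shared by both modes, so mode is the only difference in the
reference competition): `maturity_age = 4`, `p_repro = 0.5`,
`litter_size = 3`, `K = 2400`, `w = K/10`, founding size 64 (linear),
vitality allele dominant.  `K` and `alpha_ref` are the two constants
calibrated against the reference fixation rates; all are config-exposed.
Linear populations equilibrate
near `g / mean-mortality ~ 65` agents (far below `K`, so crowding is
negligible and the age pyramid is senescence-shaped), while exponential
populations sit just below `K` with crowding as the dominant cause of
death, hence much larger and much younger — the two mechanisms (age
structure and resource pressure) that favor longevity under linear
reproduction.  Drift strength is reported through a variance-effective
size estimated from allele-frequency increments
(`reporting.variance_effective_size`, labeled per tick: pooled
`sum p(1-p) / (2 sum dp^2)`).  Per tick the two modes look similar, but
generations differ enormously (queen tenure of tens of ticks versus ~4 ticks of
exponential turnover), so per generation the queen bottleneck leaves the
linear population roughly an order of magnitude more drift-dominated —
which is why the favored longevity allele wins a modest majority of
linear-mode competitions rather than all of them.

Replicate seeds derive from one experiment seed through
`SeedSequence(seed, spawn_key=(rep,))`, so any replicate can be reproduced
in isolation; runs are bit-reproducible given a seed.  The inner loop is
compiled with numba; population state is a compacted structure-of-arrays.

## Colony reproduction (Ant and Mole-rat modes)

Colonies run the linear-mode rules internally with a per-colony density cap
(`K = 144`), kept high enough that crowding rarely outweighs senescence
inside a colony — an early finding during development was that a tight
per-colony cap reintroduces exactly the young-death regime that favors
vitality and masks the colony-level effects under study.  The
metapopulation layer adds:

* founding logistic — a founding attempt succeeds with probability
  `1/(1 + exp((C - C_cap)/w_c))` in the current colony count `C`
  (defaults `C_cap = 18`, `w_c = 2`).  The long-run colony count
  equilibrates where founding balances collapse, typically a few logistic
  widths above `C_cap`.  `C_cap` sets the metapopulation's effective size
  and thereby how cleanly weak allele differences resolve against
  colony-level drift;
* Ant mode — colonies at `threshold_colony_size` release new queens
  (offspring genotypes) that mate during the flight with a male genotype
  drawn from reproductive males across all dispersing colonies, store that
  sperm for life, and found one-queen colonies.  A colony dies with its
  queen (`queen_delay = -1`);
* Mole-rat mode — queens mate within the colony and are replaced from
  colony females after `ticks_to_queen_replacement = 6` (an interregnum
  long enough that losing a queen early genuinely costs the colony
  reproduction, which is how queen lifespan becomes visible to
  colony-level selection); colonies at
  threshold send `pioneers_per_event = 10` random members (an all-male
  party founds nothing and is lost; the queen never leaves); each colony
  suffers a disaster with probability 0.045 per tick in which each member
  dies with probability 0.9.  Colonies collapse when empty or queenless
  with no females left.

`threshold_colony_size = 24` and the founding parameters are calibration
constants.  Within-colony fixation is fast relative to colony turnover, so
most colonies are monomorphic well before the metapopulation fixes — the
premise under which the colony-site ODE treats colonies as allele-typed
units.

## Queen-effects isolation

Linear and exponential populations differ in three coupled ways: age
structure, resource pressure, and the queen bottleneck.  To isolate the
bottleneck, `match_populations()` equalizes the first two: both modes get
the same environment (`K = 150`, `w = 8` by default in the experiments),
the linear queen's fecundity (`litter_size`, then `p_repro` as the fine
knob) is tuned until mean sizes agree within 5%, and the exponential
per-female reproduction probability is tuned until the pooled age
distributions agree to sup (two-sample Kolmogorov–Smirnov) distance below
0.05 — slowing exponential turnover ages the population while its
equilibrium size stays pinned near `K`, so the two knobs decouple.  Match
quality is measured on probe seeds distinct from the experiment seeds, and
ages are pooled over several spaced snapshots per probe so the 0.05
threshold is meaningful.

An invasion experiment then burns a monomorphic resident population to
demographic steady state (10x the maximum observed lifespan in ticks — a
deliberately conservative, unsophisticated criterion) and introduces a few
homozygous invaders whose ages and sexes are *resampled from the standing
population*.  The resampling matters: a neutral invader must be
demographically exchangeable with the residents, or the fixation bias
`FB = f/p0 - 1` (`f` the Monte Carlo fixation probability, `p0` the census
frequency at introduction) picks up a reproductive-value artifact.
Introducing invaders as fresh adults, for instance, credits them with
having already survived juvenility and biases FB upward by a
mode-dependent amount large enough to mask the effect under study; with
exchangeable introduction, self-invasion FB is statistically
indistinguishable from zero in both modes at 8000 replicates.  FB = 0 for
a neutral invader regardless of effective population size, which is what
makes the statistic comparable across modes with wildly different drift.

The matched experiments are run at moderate fecundity (linear litter ~4-5
per tick, exponential reproduction tuned down to match), which keeps both
populations below the density zone so that senescence, not crowding,
limits lifespan.  This is deliberate: when crowding dominates, queen
tenure is genotype-blind and the queen channel carries no signal.
Scanning the invader's vitality advantage at fixed longevity loss and
interpolating the FB sign change yields the neutral threshold: the
exponential mode's crossing sits near the analytical dF = 0 advantage
(~0.17 at these parameters, against 0.20 for the pure lifetime
calculation), while the linear mode requires more than twice the vitality
advantage (~0.4) — the queen effect.  The linear FB curve is visibly
flatter (drift), so resolving its crossing takes a few thousand replicates
per grid point against a few hundred in exponential mode.

## Problem sizes and numerical choices

* Analytical series truncation at survivorship 1e-12; root solves use
  `scipy.optimize.brentq` with certified sign-change brackets.
* The reference ABM competition uses 1000 replicates (the acceptance
  script's default); colony-mode and invasion experiments in the test
  suite run dozens-to-hundreds of replicates per scenario, sized so the
  directional claims they check are resolved a few standard errors clear
  of 50%.
* Mortality-by-age lookup tables are truncated at the age where the
  one-tick death probability reaches 1 - 1e-12; older agents reuse the
  last entry.
* Age-0 agents are appended after the aging step, so the first hazard an
  agent faces is `D_0`.

## What the simulations do and do not show

All populations here are closed, panmictic (within their unit), one-locus,
mutation-free caricatures.  The synthetic data generator *is* the study
system: results demonstrate the direction and rough magnitude of selection
pressures arising purely from reproductive topology, age structure, and
resource limitation.  They do not model real naked mole-rat or ant
demography, sperm storage physiology, worker effects on queen fecundity
(explicitly out of scope), multi-locus genetics, or environmental
sheltering.  The (V=900, L=9.2) "near-neutral" allele deserves a caveat:
with the default mapping its expected lifetime is slightly below the
vitality allele's (`dF = +0.63` at `gamma = 0`), so it loses slightly under
linear reproduction and more clearly under colony reproduction, where the
larger effective population size lets weak selection act.  Whether that
allele is exactly neutral depends on the unresolved V-to-alpha calibration,
not on any structural feature of the models; the pair's hazard curves cross
near age 63, beyond the lifespans any calibration consistent with the
headline results produces.
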