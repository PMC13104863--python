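# eusim

Eusocial animals — naked mole-rats, ants, bees, termites — funnel all
reproduction through a single queen, and they are spectacularly long-lived
compared to their solitary relatives.  `eusim` is a modeling toolkit for a
population-genetic explanation: the *reproductive topology itself* selects
for longevity.  It is written for evolutionary biologists and life-history
theorists who want to dissect how reproductive structure, age structure and
resource limitation shape selection on the two components of the
Gompertz–Makeham mortality law

    h(n) = α e^{βn} + γ,

where α is the baseline hazard (its inverse is "Vitality", V), β the
age-related rise (its inverse is "Longevity", L — the mortality-doubling
half-life), and γ an age-independent term.  Alleles carry antagonistically
pleiotropic (V, L) pairs: more vitality costs longevity and vice versa.

The package implements, end to end:

* **Analytical competition** — an age-structured discrete-time two-allele
  model whose fitness function is the difference of summed survivorship
  series, `ΔF = Σₙ Πₖ(1−Dₖ) − Σₙ Πₖ(1−dₖ)`; its sign decides competitive
  exclusion.  Includes fitness nullclines in tradeoff space (`ΔF = 0`),
  and carrying-capacity matching via the Makeham term γ′.
* **Colony-site dynamics** — an ODE for allele-typed colonies competing
  for sites (`dA/dt = A(k_A r − D_A)`), with competitive-exclusion steady
  states `r* = D/k` and stability by lowest `r*`.
* **An agent-based diploid simulator** — Mendelian genetics, Gompertz plus
  logistic density mortality, linear (single-queen) vs. exponential
  (all-females) reproduction; numba-compiled, bit-reproducible per seed.
* **Colony reproduction** — Ant mode (mating flights, stored sperm, colony
  dies with its queen) and Mole-rat mode (within-colony mating, queen
  replacement, pioneer dispersal, disasters) superimposed on linear
  within-colony reproduction.
* **Queen-effects isolation** — invasion experiments on populations matched
  in size and age structure across modes, scored by the fixation bias
  `FB = f/p₀ − 1` and the vitality advantage at which FB changes sign.

## Worked example

The reference competition pits a dominant vitality allele (V=1000, L=9)
against a recessive longevity allele (V=900, L=10).  The longevity allele
has the larger expected lifetime at γ = 0:

```sh
$ eusim delta-f
alleleA   alleleB    gamma  deltaF               winner
vitality  longevity  0.0    -1.8199625530756478  longevity
```

ΔF < 0 means the longevity allele excludes the vitality allele in the
deterministic model.  In the stochastic agent-based model the outcome is
probabilistic; a replicated linear-mode (single-queen) experiment:

```sh
$ eusim experiment --mode linear --n-reps 300 --seed 7
allele      n_fixed  n_reps  proportion  ci_low  ci_high  proportion_decided
vitality    135      300     0.45        0.3937  0.5063   0.45
longevity   165      300     0.55        0.4937  0.6063   0.55
(undecided) 0        300     0.0
```

(A config hash and the seed accompany every row for provenance.)  The
longevity allele fixes in ~55-58% of linear-mode populations — a modest
majority because the queen bottleneck makes drift strong — while in
exponential populations (`--mode exponential`) it fixes in well under half:
crowding kills the young regardless of genotype, so the vitality allele's
early-life advantage dominates.  Nullclines quantify the same asymmetry in
the analytical model (`eusim nullcline`, `eusim match-gamma`), colony
dynamics in `eusim colony-ode` and `eusim colony-sim`, and the queen
effect in `eusim queen-effects`.

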