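# redqueen

How long do Red Queen oscillations survive genetic drift? `redqueen`
implements five stochastic, individual-based host–parasite coevolution
models under the matching-alleles infection scheme and measures the
robustness of their negative frequency-dependent selection (NFDS)
cycles by the **extinction time**: the first time any genotype from the
initial standing variation is lost from either population. The package
is for theoretical ecologists and evolutionary modellers who want to
compare how population-size regulation — fixed size by design, a
carrying capacity, or none at all — changes the lifetime of
coevolutionary polymorphism.

## Models

All models share the matching-alleles game: a parasite of genotype *i*
gains α from a host of the same genotype and β otherwise (zero-sum: the
host loses what the parasite gains), with payoffs mapped to fitness via
the selection intensity *w*: f = 1 − w + w·π.

| model | population size | update rule | deterministic limit |
|---|---|---|---|
| `EvoPlus` (and `dtEvoPlus`) | constant | Moran: birth ∝ f / f̄ (global competition) | adjusted replicator — attracting point |
| `Evo` (and `dtEvo`) | constant | pairwise comparison: ½ + ½(f₁−f₂)/max Δπ | replicator — neutral cycles |
| `Hybrid` | self-balancing | game-driven host death / parasite birth, rates balanced per species | replicator — neutral cycles |
| `EcoEvo` | free | Lotka–Volterra reactions: host birth b_H, parasite death d_P, matched encounters at λ | Lotka–Volterra — neutral centre |
| `EcoEvoPlus` | carrying capacity K = b_H/μ | EcoEvo + host competition deaths at μ | logistic LV — attracting point |

Continuous-time models run on an exact Gillespie engine (compiled
kernels); the two discrete-time processes update host and parasite
simultaneously each step and additionally admit **exact** mean
extinction times via a sparse absorbing-Markov-chain solve of
(I − Q)τ = 1. Cyclic nearest-neighbour mutation (genotype *i* → *i*±1
at rate μ/2 each) can be switched on for the ecological and Hybrid
models to revive extinct genotypes.

## Worked example

```python
import redqueen as rq

fig1 = rq.load_preset("fig1")          # N_H=50, N_P=150, w_H=0.5, w_P=1, λ=4/100, K=100
init = rq.equal_split(50, 150, 2)      # equal genotype abundances
stop = rq.StopCondition(t_max=1e9, n_max=10**7)

for model in ("EvoPlus", "EcoEvoPlus"):
    s = rq.extinction_ensemble(model, 2, fig1["params"], init, n_reps=300, seed=21, stop=stop)
    print(f"{model:12s} mean extinction time {s.mean:8.1f}  (SEM {s.sem:.1f})")
```

prints:

```
EvoPlus      mean extinction time   3366.4  (SEM 152.6)
EcoEvoPlus   mean extinction time      7.5  (SEM 0.3)
```

i.e. with identical interior equilibria (25, 25 | 75, 75) the
constant-size Moran-type model keeps both genotypes for roughly 500×
longer than the eco-evolutionary model whose population size may
change — population-size change, not just population size, accelerates
genotype loss. The exact discrete-time solver provides an independent
check of the simulation engine:

```python
params = rq.ModelParams(w_H=0.5, w_P=1.0)
tau = rq.exact_mean_extinction_time("dtEvoPlus", params, 6, 6)
print(tau[3, 3])   # 13.4670  — expected steps to first loss from (3,3)
```

A Monte-Carlo ensemble of `simulate_discrete` runs reproduces this
within its standard error (13.61 ± 0.09 over 10⁴ replicates).

There is also a small CLI (`redqueen ensemble --preset fig1 --model
EcoEvoPlus --reps 100 --seed 7`, `redqueen exact-dt`, `redqueen ode`,
`redqueen sweep`, `redqueen diversity`, `redqueen preset-list`); every
run writes a tidy CSV plus a JSON sidecar with the fully resolved
configuration.

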