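# Methods

## The models

All five models describe two well-mixed haploid asexual populations —
hosts and parasites — with `n` genotypes each, coupled by the
matching-alleles game. The interaction matrix has the match payoff
`alpha` on the diagonal and the mismatch payoff `beta` elsewhere
(defaults 1 and 0). Parasite payoff is `pi_P,i = sum_j A[i,j] h_j`;
for the host we use the zero-sum complement
`pi_H,i = (alpha + beta) - sum_j A[i,j] p_j`, which keeps fitness
`f = 1 - w + w pi` non-negative for any selection intensity
`w in [0, 1]` and makes the Hybrid model's host death rate
`d_H,i = 1 - w_H + w_H (alpha P_i + beta P_j)/N_P` the exact mirror of
host fitness. With this convention the Hybrid model's frequency drift
equals the replicator equation identically (not merely to leading
order), which we exploit in the mean-field consistency tests.

**Constant-size (game-theoretic) processes.** `EvoPlus` is a
two-species Moran process: per update a uniformly chosen individual
dies and a same-species individual reproduces with probability
proportional to `f_i / f_mean` — normalisation by the population mean
fitness is a global intraspecific competition. `Evo` replaces the
Moran factor by the pairwise-comparison form
`1/2 + 1/2 (f_1 - f_2) / (w (alpha - beta))`: only the fitness
difference of a sampled pair matters, so competition is local.
Both exist in discrete time (`dtEvoPlus`, `dtEvo`; host and parasite
drawn simultaneously from the pre-step state, `dt = 1` per paired
update) and as continuous-time reaction systems whose rates are the
same expressions (one species updated per event). Discrete- and
continuous-time extinction times are reported in their own units and
are not directly comparable; nor are `Evo` and `EvoPlus` times across
models, since the pairwise rule runs a slower event clock (its
replacement rates carry an extra factor `~ 1/(w(alpha - beta))`).

**Ecological processes.** `EcoEvo` is the individual-based
Lotka–Volterra system: host births at `b_H H_i`, parasite deaths at
`d_P P_i`, and matched encounters firing two independent channels at
rate `lam H_i P_i` each — one killing the host, one reproducing the
parasite. (The alternative single channel doing both would leave the
drift, and hence all equilibria, unchanged; we use two independent
channels, reading the event description literally as "death **or**
birth".) `EcoEvoPlus` adds competition deaths at
`comp_rate * H_i * N_H`; self-pairing is included so the host-only
equilibrium equals the carrying capacity `K = b_H / comp_rate`
exactly. The `Hybrid` model takes its host-death and parasite-birth
rates from the game and balances each species' opposite rate
dynamically (host births at `H_i * (sum_k H_k d_H,k) / N_H`, parasite
deaths symmetrically), distributing the balancing rate uniformly per
capita — the simplest scheme that equalises total birth and death
rates at every state; it keeps sizes constant in expectation only.

**Mutation.** For the ecological and Hybrid models, cyclic
nearest-neighbour conversion `i -> (i +- 1) mod n` at rate `mut/2` per
direction per individual models mutation/recombination re-introducing
lost genotypes. The constant-size models do not support it (their
paired replacement reactions have no conversion analogue at fixed
size).

## Parameters

| name | meaning | default / typical |
|---|---|---|
| `w_H`, `w_P` | selection intensities, dimensionless in [0,1] | 0.5, 1.0 |
| `alpha`, `beta` | match / mismatch payoff | 1, 0 |
| `b_H` | host birth rate (per capita per time) | 6 |
| `d_P` | parasite death rate (per capita per time) | 1 |
| `lam` | encounter rate per host–parasite pair; `lam = lam0 / K` | 0.04 (fig1) |
| `comp_rate` | host competition rate per pair; `b_H / K` | 0.06 (fig1) |
| `K` | host carrying capacity | 100 (fig1) |
| `mut_H`, `mut_P` | conversion rates per capita | 0.005, 0.01 (fig4) |

The asymmetric defaults `w_P = 1 > w_H = 0.5` mirror the ecological
models' structure: the obligate parasite reproduces only through the
interaction, while hosts are also regulated by competition. The
sources use one symbol for both the competition and the mutation rate;
they are distinct parameters here. Derived parameters resolve at
construction (`lam` from `lam0/K`, `comp_rate` from `b_H/K`) with
explicit values winning and inconsistencies rejected; `K` given
together with `comp_rate = 0` is allowed and only scales `lam0`
(used by the sweep preset's EcoEvo arm).

Shipped presets: `fig1` (two genotypes, equilibrium N_H = 50,
N_P = 150), `fig3` (sweep axes; N_H = 250, K = 500, paired `b_H` grids
so both ecological models cover target N_P = 30…200), `fig4` (five
genotypes, mutation, equilibrium N_H = 300, N_P = 900).

## Simulation engine

Continuous-time models run the direct-method Gillespie algorithm:
exponential waiting time at the total rate, reaction chosen
proportionally to its rate. The five built-in models execute in
compiled (numba) kernels; arbitrary `ReactionSystem` objects with
Python propensity callables run the identical algorithm in a reference
Python loop, which the tests use as an independent cross-check of the
kernels (rate-vector equality on random states, and distributional
agreement of extinction times). Trajectories are recorded on a fixed
time grid (the state *holding at* each grid time) to bound memory;
extinction detection always uses exact event states. Each replicate of
an ensemble gets an independent child stream of the master seed
(`numpy` `SeedSequence.spawn`), so results are reproducible and
independent of execution order. Self-replacement events in the
discrete-time processes consume a time step.

## Exact extinction times

For the two-genotype discrete-time processes the paired update is a
product of two independent per-species step distributions evaluated at
the pre-step state, so the chain on `(H_1, P_1)` has at most nine
nonzeros per row. States with any genotype at 0 or at the species
total are absorbing. Mean first-loss times solve `(I - Q) tau = 1`
over the interior states (sparse LU; state space guarded at 2.5e5
states). Enumeration is row-major in `(H_1, P_1)` — test oracles index
identically. A dense brute-force enumeration of the same chain, built
from the user-facing step-distribution API, serves as the oracle for
the sparse path.

## Deterministic limits and stability

Frequency models integrate the (adjusted) replicator equations written
with the intensity-bearing fitness `f`; ecological models the
Lotka–Volterra equations `dH_i = H_i (b_H - comp_rate N_H - lam P_i)`,
`dP_i = P_i (lam H_i - d_P)`. Interior fixed points are closed-form:
uniform `1/n` for frequency models, `H_i* = d_P/lam`,
`P_i* = (b_H - comp_rate n H_i*)/lam` for ecological ones (fig1:
25/75 per genotype; fig4: 60/180).

A subtlety governs stability classification: at the interior point the
genotype-composition (oscillation) mode is **linearly neutral in every
model**. For the adjusted replicator the Jacobian at the fixed point
is the plain replicator Jacobian scaled by `1/f_mean` (the gradient of
the normalisation vanishes where the selection term does), hence
purely imaginary; in `EcoEvoPlus` the host-antisymmetric mode
decouples from the damped total-size mode and is likewise purely
imaginary. The damping that separates the global-competition (+)
models from the neutral ones is a genuinely nonlinear effect, and
convergence is correspondingly algebraic (amplitude ~ t^(-1/2)), not
exponential. `classify_fixed_point` therefore proceeds in two stages:
the numerical Jacobian (restricted, for frequency models, to the
tangent space of the two simplices; eigenvalue tolerance 1e-8) decides
clear cases, and a spectrally neutral point is disambiguated by the
per-period contraction of a test orbit displaced 10% along the
composition mode — contraction/expansion beyond 1e-4 per period
classifies attracting/repelling, anything closer is neutral. At fig1
parameters the measured ratios are ~0.991 (`EvoPlus`) and ~0.9995
(`EcoEvoPlus`) against 1 ± 2e-6 for the three neutral models, so the
margin is four orders of magnitude. Orbit periods are detected by
first return to a Poincaré section (the fastest-moving coordinate
crossing its initial value in its initial direction), never an assumed
formula. Integration uses DOP853 at rtol 1e-10 (1e-12 for
orbit-closure measurements); frequency sums stay within 1e-8 over all
tested horizons.

Degenerate and edge inputs: `w = 0` or `alpha = beta` make every
process neutral (verified as flat payoffs, symmetric step triples and
vanishing replicator fields); boundary states are absorbing with
degenerate step distributions; empty species zero all propensities
that consume them.

## Experiments and problem sizes

The extinction-time experiments use equal genotype splits of the
preset sizes, with ecological models started at the rounded
deterministic equilibrium so all models share fixed points. Ensemble
means cover uncensored replicates only, with censored counts reported
alongside (the Moran-type models at large sizes can exceed any
practical horizon; censored runs are excluded, never imputed). The
shipped comparisons use 300 replicates per model at the fig1 preset
and 100 per cell on a three-point sweep (target N_P = 30/50/70) —
sizes at which the constant-vs-changing ordering is separated by >2
pooled standard errors while the whole suite stays desk-scale. Sweep
target sizes for the ecological models are always computed from the
equilibrium formula, never assumed; sweep points whose equilibrium
rounds below one individual per genotype are flagged infeasible and
kept in the table.

The diversity experiment uses `EcoEvoPlus` with 20 genotypes at
`b_H = 6, d_P = 1, K = 1000, lam0 = 40` (equilibrium 25 hosts and 75
parasites per genotype — large enough that early dynamics are not
dominated by immediate single-genotype collapse, small enough that 100
replicates over 60 time units run in seconds). Mean diversity is fit
by least squares on a log scale over the decay window, from t = 0
until mean diversity first drops below 2, excluding the terminal
plateau. The mutation-regime run uses the fig4 preset over
`t_max = 50` (about 14 oscillation periods); revivals (a genotype
count leaving zero) are logged event-exactly.

A caution on the fig4 regime: the stochastic system is only weakly
(nonlinearly) attracted to its equilibrium, and its excursions are
strongly right-skewed; time-averaged population sizes conditional on
parasite survival sit 10–25% *below* the deterministic point
(300, 900) at this horizon, drifting lower the longer the run, and
whole-population collapse typically occurs by t ~ 40–130 even with
mutation. Mutation revives genotypes and restarts oscillations — every
tested seed shows revivals — but it does not pin the averages to the
deterministic equilibrium.

## What the generator does and does not emulate

The simulations are the study conditions themselves (there is no
external data): well-mixed populations, haploid asexual reproduction,
a purely symmetric matching-alleles interaction, static genotypes, and
demographic stochasticity only. Passing tests therefore say nothing
about spatial structure, dosage/partial resistance, gene-for-gene
interactions, environmental noise, or diploid sexual hosts — all
deliberately out of scope. Extinction-time *orderings* across models
proved robust to replicate count and seed; absolute extinction times
at a given size should be read as model-specific quantities in
model-specific time units.

## Known limitations

- The discrete-time machinery (simulation and exact solver) is
  two-genotype only; multi-genotype questions go through the
  continuous-time models.
- The exact solver's state-space guard (2.5e5 states) limits it to
  population sizes of a few hundred.
- No tau-leaping: very large populations with fast clocks are
  expensive by construction.
- Fixation probabilities, quasi-stationary distributions and analytic
  noise approximations of extinction times are not implemented.
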