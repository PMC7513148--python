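# trajent

**Random trajectory entropy as a stability measure for finite population
processes.**

`trajent` answers a recurring question in evolutionary game theory: of the
several equilibria a finite population can settle near, *which one is the
most stable*, and how does that depend on the mutation rate μ, the strength
of selection β, and the population size N? It is written for researchers in
population dynamics and stochastic processes who work with birth–death
chains on the simplex, but the core machinery applies to any irreducible
finite Markov chain.

## The idea

For an irreducible chain with transition matrix T and stationary
distribution s, the entropy rate

&nbsp;&nbsp;&nbsp;&nbsp;H(X) = −Σᵢⱼ s(vᵢ) T(vᵢ,vⱼ) log T(vᵢ,vⱼ)

measures the inherent per-step randomness of the process. The **random
trajectory entropy** (RTE) of a state v is the Shannon entropy of the
probability distribution over *first-return trajectories* from v back to
itself (paths that revisit v only at the end). It admits a closed form:

&nbsp;&nbsp;&nbsp;&nbsp;H_v = H(X) / s(v).

A small RTE means return excursions from v are short and predictable — the
state is dynamically *stable*. Because H_v is an order-reversing function
of s(v), local maxima of the stationary distribution are exactly local
minima of the RTE, so the RTE ranks equilibria of one process and — unlike
s itself — compares equilibria *across* processes (different β, μ, or even
different N, after normalizing by the state count C(N+n−1, n−1)).

The package applies this to the **Moran process with mutation**: n types in
a population of size N; each step one individual reproduces
fitness-proportionately (fitness f = G·ā from a game matrix G, with either
linear weights ā·f or Fermi weights ā·exp(βf)), the offspring mutates per a
uniform mutation matrix, and a uniformly random individual dies. It also
ships the classical small-mutation theory: fixation probabilities
ρ_A = (1−r⁻¹)/(1−r⁻ᴺ), ρ_B = (1−r)/(1−rᴺ), the μ→0 corner-state stationary
distribution (ρ_A : ρ_B), and the limiting corner RTE ratio
H₍₀,ₙ₎/H₍ₙ,₀₎ = ρ_A/ρ_B = r^(N−1).

## Worked example

The Hawk–Dove game G = [[1,2],[2,1]] favors a mixed population. With
N = 30, μ = 1/30 and Fermi selection β = 1:

```python
import trajent as tj

res = tj.MoranModel.from_preset("hawkdove", 30, beta=1.0).fit()
print(res.summary())
```

```
Moran process stability analysis (random trajectory entropy)
==============================================================
types n:              2
population size N:    30   (states: 31)
mutation rate mu:     0.0333333
selection beta:       1   kernel: fermi
solver:               power_iteration (residual 9.872e-13, iterations 1319)
--------------------------------------------------------------
entropy rate H(X):    1.019771 nats/step
global stationary max: 15,15  (s = 0.101837, RTE = 10.0138)
local maxima:         ['15,15']
local minima:         ['0,30', '30,0']
ties:                 0 state(s)
--------------------------------------------------------------
most stable states (ascending RTE):
             15,15  s = 0.101837  RTE = 10.0138
             14,16  s = 0.098546  RTE = 10.3482
             16,14  s = 0.098546  RTE = 10.3482
             13,17  s = 0.0893015  RTE = 11.4194
             17,13  s = 0.0893015  RTE = 11.4194
```

Reading the output: the chain has 31 states (0…30 hawks); the unique
stationary maximum is the half-and-half state (15,15), which is also the
RTE minimum — excursions away from it carry about 10 nats of uncertainty,
versus thousands for the unstable all-hawk corner. Sweeping β
(`tj.run_sweep(..., param="beta", ...)`) shows s(15,15) rising and its RTE
falling monotonically: stronger selection stabilizes the mixed equilibrium.

The same objects drive multi-type analyses, e.g.
`tj.MoranModel.from_preset("threetype", 42).fit()` classifies the ten
coexisting extrema (corners, edge midpoints, center) of the symmetric
three-type game, and `tj.symmetry_check(tj.rps_matrix(), ...)` verifies the
cyclic symmetry that makes rock–paper–scissors stationary distributions
constant on permutation orbits.

A command-line interface mirrors the library:

```bash
trajent extrema --matrix hawkdove --N 30 --beta 1 --format json
trajent sweep --matrix threetype --N 42 --param mu --values 0.005,0.01,0.02,0.05
trajent fixation --r 2 --N 10
```

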