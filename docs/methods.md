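# Methods

## Model

The package analyzes stationary stability of irreducible finite Markov
chains through the random trajectory entropy (RTE), with the Moran process
with mutation as the primary application.

**Chain.** A population of N individuals of n types is a lattice point
a = (a₁,…,aₙ), Σaᵢ = N, of the discrete simplex; there are C(N+n−1, n−1)
states. One step = one birth plus one death:

- selection weights φ(ā): linear kernel φᵢ = āᵢ fᵢ(ā) or Fermi kernel
  φᵢ = āᵢ exp(β fᵢ(ā)), with fitness f(ā) = G ā from an n×n payoff
  matrix G;
- the reproducing type passes through the mutation matrix M, giving birth
  probabilities pᵢ = Σₖ φₖ Mₖᵢ / Σₖ φₖ;
- a uniformly random individual dies, so
  T(a → a + i_{u,w}) = p_u(ā) · ā_w for u ≠ w, and the diagonal is the
  complement (equal to p·ā).

The shipped mutation model is the uniform matrix (diagonal 1−μ,
off-diagonal μ/(n−1)); a per-state hook accepts state-dependent mutation.
With μ > 0 every chain is irreducible; μ = 0 chains can be built (their
corners absorb) but stationary and entropy operations reject them and the
small-mutation module handles that regime analytically.

**Entropy quantities.** The entropy rate is
H(X) = −Σᵢⱼ s(vᵢ)T(vᵢ,vⱼ) log T(vᵢ,vⱼ) with 0·log 0 := 0; the RTE of a
state is H_v = H(X)/s(v), the entropy of the first-return trajectory
distribution. All logarithms are natural (a single module constant governs
the base). Since s(v) ≤ 1, H_v ≥ H(X) for every state; a chain of
deterministic rows has H(X) = 0 and the RTE ranking is then flagged
degenerate rather than reported.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| μ | per-birth mutation probability | 1/N | the conventional scaling; keeps the chain irreducible with a mutation pressure that vanishes as N grows |
| β | selection intensity (Fermi) | 1.0 | order-one selection; β = 0 recovers the neutral chain |
| kernel | linear or fermi | fermi | defined for any payoff sign; linear requires positive fitness |
| tol | L1 residual ‖sT − s‖₁ of the stationary solve | 1e-12 | far below the stationary-probability gaps that extremum classification compares |
| max_iter | power-iteration cap | 10⁶ | generous for the mixing times encountered at the sizes studied |

## Numerical choices

**Stationary solving.** Power iteration starts from the uniform vector,
renormalizes each step, and stops when the L1 residual of the current
iterate is ≤ tol; it refuses reducible chains up front (strong connectivity
of the support graph) and raises after max_iter without convergence
(periodic chains with non-uniform stationary distributions genuinely
oscillate). For two-type birth–death chains an exact product-form solver is
available: s_k ∝ Π_{j<k} T(j→j+1)/T(j+1→j), accumulated in log space, which
satisfies detailed balance to machine precision. For n ≥ 3 no
reversibility is assumed and power iteration is the only route; the two
solvers agree within 1e-8 on all two-type chains tested. Eigensolver or
linear-system routes are deliberately out of scope.

**Truncated first-return oracle.** The closed form H_v = H(X)/s(v) is
validated against an exhaustive sum of −Pr(V) log Pr(V) over first-return
paths of length ≤ L. Rather than materializing the exponentially many
paths, the implementation propagates per length the total mass and the
Σ p·log p aggregate of path prefixes that have not yet revisited v — an
aggregation that is term-for-term identical to full enumeration. It
reports the captured mass together with a rigorous tail bound (every tail
path of length ℓ has probability ≥ t_min^ℓ, and tail mass decays
geometrically with ratio max_{x≠v}(1 − T(x,v))). Explicit path
enumeration, with an optional prefix-probability floor (default 1e-15), is
kept for small horizons where the trajectory objects themselves are
wanted. At L = 40 on seeded 3-state chains the truncated entropy matches
the closed form within 1e-3 plus that bound for every state.

**Fermi overflow.** Weights āᵢ e^{βfᵢ} are computed unshifted (matching
their definition) unless β·max f exceeds 600, where a common max-shift is
applied; the birth distribution is normalized, so the shift is exact.

**Extremum classification.** A state is a local maximum iff its value
strictly exceeds every one-birth-one-death neighbor's (strict comparison
of solver output, no epsilon: the solver residual is orders of magnitude
below the gaps being compared; an optional ε parameter exists for near-tie
exploration). States blocked from classification only by equality — as on
the constant-probability cycles of rock–paper–scissors landscapes, and on
any exactly uniform distribution — are reported in a dedicated `ties`
field, never silently classified. Global extrema are taken over all states
including the boundary and must be unique, else they join the ties. On
non-lattice chains (seeded fixtures) every other state counts as a
neighbor, so local and global extrema coincide.

**Small-mutation limits.** The classical constant-fitness game
G = [[r,r],[1,1]] makes the two-type chain exactly the textbook Moran
process, with single-mutant fixation probabilities
ρ_A = (1−r⁻¹)/(1−r⁻ᴺ) and ρ_B = (1−r)/(1−rᴺ) (both 1/N at r = 1, to which
the code routes whenever |r−1| < 1e-10 to avoid catastrophic
cancellation). As μ→0 the stationary distribution concentrates on the
corners in the ratio ρ_A : ρ_B — the embedded corner-to-corner chain jumps
at rates μρ — and the corner RTE ratio H₍₀,ₙ₎/H₍ₙ,₀₎ converges to
ρ_A/ρ_B, which simplifies exactly to r^(N−1): the type with the greater
fixation probability owns the more stable corner, and the neutral case
r = 1 makes the corners equally stable. These closed forms are verified in
the tests two independent ways: against absorption probabilities obtained
by solving the first-step linear system of the μ = 0 chain, and against
the full pipeline at μ ∈ {10⁻², 10⁻³, 10⁻⁴}, where the empirical ratio
approaches r^(N−1) monotonically (within 5% at μ = 10⁻⁴ for r = 2,
N = 10). The entropy rate itself decreases strictly toward 0 along the
same μ sequence.

**Sweeps and normalization.** Sweeps over β, μ, or N rebuild the chain at
every grid point (no warm starts, for reproducibility) and tabulate, per
tracked equilibrium, the stationary probability, RTE, and RTE normalized
by the state count C(N+n−1, n−1). The normalization makes RTEs comparable
across population sizes, whose raw RTEs grow with the state space; the
general simplex-lattice count is used for any n. The canonical three-type
tracked equilibria are the corner (N,0,0), edge midpoint (N/2,N/2,0), and
center (N/3,N/3,N/3), which require N divisible by 6.

## Problem sizes

The analyses the package runs as its standard examples are the Hawk–Dove
chain at N = 30 (31 states), the symmetric three-type game at N = 42 and
N = 60 (946 and 1891 states), and rock–paper–scissors at N = 30
(496 states, where the cyclic type permutation leaves the stationary
distribution invariant to ~1e-17 and the RTE constant on each orbit). The
rock–paper–scissors symmetry structure is size-independent, so the N = 30
lattice stands in for arbitrarily larger ones; the same cyclic-equivariance
argument applies verbatim at any N divisible by 3.

## What the synthetic fixtures do and do not show

The seeded fixture chains (strictly positive random rows) exercise the
entropy machinery on dense, aperiodic, rapidly mixing chains — the
easiest regime. They validate the closed form against enumeration and the
ranking duality, but say nothing about metastability: Moran chains at
small μ mix slowly, which is why the power-iteration cap is large and the
small-mutation regime has its own analytic module. The Moran chains
themselves are exact models, not approximations, so passing tests on them
carry over to real parameter studies; what the package does not model at
all are frequency-dependent mutation beyond the per-state hook, asymmetric
(bimatrix) games, Wright–Fisher or pairwise-comparison update rules, and
RTEs between *distinct* origin and terminal states.

## Known limitations

- Power iteration inherits the chain's spectral gap; at μ well below 10⁻⁴
  or very large β the iteration count grows and tighter tolerances may hit
  the iteration cap.
- Extremum classification with exact float comparison will, on symmetric
  landscapes, resolve exactly-tied orbits by solver noise at the ~1e-16
  level when asked for a *global* argmax; the ties field and the ε
  parameter are the honest instruments there.
- The explicit trajectory enumerator is exponential in the horizon and
  meant for horizons of a couple dozen steps at most; the aggregated
  truncated sum is the scalable oracle.
- No closed-form fixation probabilities are provided for n ≥ 3 types or
  state-dependent games; those regimes are reached only numerically at
  μ > 0.
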