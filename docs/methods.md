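# Methods

This note documents the model implemented by `topoclock`, the conventions
and numerical choices behind it, and what the test suite does and does not
establish.

## The model

A single KaiC hexamer is described by a continuous-time Markov chain on
states `(x, y)_s` with `x ∈ [0, Nx]` phosphorylated T-sites,
`y ∈ [0, Ny]` phosphorylated S-sites (default `Nx = Ny = 6`, one T- and one
S-site per monomer; only counts are tracked, not monomer identity), and an
internal compass state `s ∈ {N, E, S, W}` naming the next primed external
move. Intermediate KaiA-bound species are coarse-grained away; the internal
cycle lumps conformational change (A-loop exposure/burial), KaiA catalysis,
KaiB binding/unbinding and nucleotide exchange into a single four-step
priming loop per lattice site.

Transitions:

- **external** (fast chemistry, phosphotransfer): from `(x, y)_s` one
  lattice step in direction `s` (E: x+1, N: y+1, W: x−1, S: y−1) at rate
  γ_ex, landing in internal state `prev(s)` (prev(E)=S, prev(S)=W,
  prev(W)=N, prev(N)=E); reverse at γ_ex′. Hops that would leave the
  lattice are absent *together with their reverses*, keeping the graph
  reversible so that μ = 0 is a genuine equilibrium.
- **internal** (slow priming): `E→N→W→S→E` within a site at γ_in, reverse
  at γ_in′.

The landing convention `prev(s)` makes external plaquette loops clockwise
and internal loops counterclockwise, and forces the boundary walk to pause
for exactly one internal step per non-corner boundary position and two per
corner — producing the 28 bottleneck states and the 52-state boundary cycle
on the 6×6 lattice.

### Parameters

| parameter | meaning | units | default |
| --- | --- | --- | --- |
| μ | thermodynamic force per transition, e^μ = γ_ex/γ_ex′ = γ_in/γ_in′ | k_BT (k_BT = 1 throughout) | — |
| ρ | timescale separation, e^ρ = γ_ex/γ_in | — | — |
| γ_tot | total rate scale, sum of the four rates | 1/time | 1 |
| Nx, Ny | site counts | — | 6 |

The unique rate solution is γ_in′ = γ_tot/((1+e^μ)(1+e^ρ)), with γ_in,
γ_ex′, γ_ex scaled by e^μ, e^ρ, e^{μ+ρ}. Requests with |μ|+|ρ| > 700 are
rejected (IEEE overflow) with an explicit message. ρ > 0 is the
topological regime; all headline analyses assume it, and the phase-diagram
scanner requires an explicit opt-in for ρ ≤ 0.

## Spectral observables

The generator uses the column convention 𝒲ᵢⱼ = rate(j→i), diagonal
closing each column to zero. The steady state solves 𝒲p = 0 with the
normalization row substituted for the last equation; strong connectivity is
checked first and reducibility reported with the component memberships.

The slowest oscillatory mode λ₁ = −λ_R + iλ_I is the non-zero eigenvalue
of smallest |Re|. The zero eigenvalue is identified scale-aware
(|Re|, |Im| < 1e-9·max|𝒲ᵢᵢ|); ties in |Re| resolve toward the largest
imaginary part (the oscillatory member is the object of study), and of a
conjugate pair the Im ≥ 0 member is reported. Coherence ℛ = λ_I/λ_R;
period 𝒯 = 2π/λ_I, reported infinite (with ℛ = 0) for purely
relaxational modes. A dense eigensolver is used throughout: the default
state space is 196 states, far below the size at which sparse/iterative
methods pay off.

Validation uses two independent routes: the circulant closed forms of the
uniform unicycle (λ₁, ℛ = cot(π/N)tanh(𝒜/2N), ΔS = 2πμ/sin(2π/N),
matched to 1e-9 relative) and a time-domain check that fits an order-2
linear recurrence to the phosphorylation-level relaxation signal and
recovers λ_R and λ_I from its characteristic roots to within 2%.

## Entropy production and the cost–precision diagram

ΔS per period = (𝒯/2) Σᵢⱼ (pⱼ𝒲ᵢⱼ − pᵢ𝒲ⱼᵢ) ln(pⱼ𝒲ᵢⱼ/pᵢ𝒲ⱼᵢ), in k_B;
with rates expressed in units of γ_tot this number is invariant under
rescaling the overall timescale, which the tests verify. Pairs with both
fluxes zero contribute nothing; a one-way edge raises an error (the model
never produces one by construction). At equilibrium the period is infinite
but the rate is zero; that limit is reported as exactly ΔS = 0 when the
rate falls below 1e-12·γ_tot.

The edge/bulk split assigns a transition to the edge iff *both* endpoint
states lie on the geometric boundary (x ∈ {0, Nx} or y ∈ {0, Ny});
transitions with one boundary endpoint count as bulk. This binary rule was
chosen over 50/50 splitting for testability; the parts sum to the total
exactly.

The phase diagram is scanned on rectangular (μ, ρ) grids; each cell costs
one 196×196 eigendecomposition plus one linear solve (~12 ms), so the
headline 101×70 grid at step 0.1 runs in about 90 s on one CPU. Cells with
λ_I = 0 (μ = 0) are flagged with infinite cost–precision and excluded from
the optimum with a warning.

**Flatness of the optimum basin.** The global minimum of ΔS/ℛ on the
step-0.1 grid sits in a basin flat to better than 0.01% across neighboring
cells (the two best cells, (6.4, 4.1) and (6.5, 4.1), differ by 7·10⁻⁵ in
relative value). The argmin is therefore meaningful only to about one grid
step, and the test suite asserts the location to that resolution.

## Thermodynamic bounds

The coherence bound ℛ ≤ max_κ cot(π/N_κ)tanh(𝒜_κ/2N_κ) and the spectral
ellipse (center −w₀, semi-axes w₀ and w₀·tanh(𝒜_C/2N_C), after rescaling
the generator so min 𝒲ᵢᵢ = −1) are conjectures in the literature; the
package treats them as test oracles, not theorems. No general simple-cycle
enumeration is attempted (exponential in the state count): for the lattice
model every edge has forward/backward ratio e^μ, so every cycle's affinity
per state is ≤ μ and the maximization reduces to maximizing cycle length,
achieved by the constructed boundary cycle (N = 2(Nx+Ny) + perimeter
internal steps; 52 for 6×6). The two rescaling conventions in circulation
(max|𝒲ᵢᵢ| = 1 vs min 𝒲ᵢᵢ = −1) coincide for a generator; the latter is
implemented. Ellipse membership is tested in rescaled coordinates with
tolerance 1e-8 on the quadratic form.

## Reciprocal space

The bulk model is translation-invariant with a 4-state unit cell, giving
4×4 Bloch matrices 𝒲(k) with external hops carrying e^{−ik·d} and a
k-independent diagonal −γ_tot. Band gaps Δ_I, Δ_R are computed from
pointwise-sorted branches on a ≥101×101 k-grid as min(top band) − max(second
band), negative if the bands overlap.

The 2D Zak phase is the pair of Wilson-loop phases of the *steady-state
band* — the band continuously connected to the zero eigenvalue at k = 0 —
along straight loops in k_x and k_y. Because 𝒲(k) is not normal, the loop
uses biorthogonal left/right eigenvectors (left rows taken from V⁻¹, so
normalization is exact) and tracks the band by maximal overlap continuity,
erroring out with the k-point if tracking becomes ambiguous. The product of
consecutive overlaps is gauge invariant; the phase is reduced mod 2π and
snapped to {0, π} with the pre-snap deviation reported (observed ~1e-15 at
n_k = 200, far below the 1e-3 quantization tolerance). The loop is
evaluated at two fixed transverse momenta and circularly averaged; the
quantized results agree. Which band carries the invariant is a genuine
convention choice; the steady-state band is the physically occupied one and
reproduces the expected (0,0)/(π,π) jump at ρ = 0, where the minimum
inter-band distance closes.

## Stochastic simulation

Exact Gillespie sampling with per-state cumulative transition tables and
block-drawn random numbers (~2 s per 10⁶ steps). The "random initial
condition" is uniform over all states, seed-controlled; no burn-in is
applied by default, matching the occupancy estimator that uses the full
trajectory. Occupancy is time-weighted, not visit-counted. Desk-scale
budgets are used throughout: the total-variation check against the
algebraic steady state uses 10⁶ steps (TV < 0.02 at μ=1, ρ=2), a
deliberate scale-down from the 10⁸-step runs used for production-quality
distribution estimates; TV decreases roughly diffusively with length, so
longer runs only tighten the comparison.

Edge-current chirality is quantified by winding counts of the polar angle
about the lattice center, with 2π-hysteresis (a loop registers only after a
full net excursion) and exclusion of lattice positions within radius 2 of
the center — a hop past the center flips the angle by ~π with arbitrary
sign and would otherwise register spurious half-loops. At strong driving
(μ = 2) negative loops are < 5% of all loops; at weak driving (μ = 1)
bulk excursions still blur the count and only net-positive winding is
asserted.

## Comparison models

Both baselines are *reconstructions* from structural descriptions, built
behind the same generator interface; quantitative claims about them are
property-based (bounds, orderings), never exact values.

- **MWC-type ring** (2(n_sites+1) = 14 states): concerted conformational
  state × phosphorylation level, phosphorylating up in one conformation,
  dephosphorylating down in the other, switching at the ends. State
  energies tilt each conformation linearly in phosphorylation level with
  amplitude E; each of the 12 chemical steps carries driving η/2 and the
  two switches are energetically balanced, so the single cycle has affinity
  6η and the maximum affinity per state is exactly (3/7)η, with η = 0 an
  equilibrium. Sampling ranges γ ∈ [3,7], E ∈ [5,15], η ∈ [0, 70/3] map
  the force per state onto [0, 10].
- **Bilayer lattice** (2·49 = 98 states): free-KaiC layer phosphorylates
  (x+1, y+1 moves), KaiB-bound layer dephosphorylates, layer switches run
  at the internal rates with KaiB binding forward-favored strictly above
  the anti-diagonal x + y = (Nx+Ny)/2 and unbinding forward-favored on and
  below it. Every edge has ratio e^μ, so μ = 0 is detailed balance and the
  longest uniformly forward cycle (26 states) carries the maximal affinity
  per state μ.

The random-parameter comparison samples μ ∈ [0,10], ρ ∈ [0,7] uniformly
for the lattice models and the MWC ranges above, with a fixed seed for
reproducibility.

## Known limitations

- Single-molecule description only: population-level synchronization,
  KaiA sequestration feedback and multi-hexamer exchange are out of scope.
- The comparison models are minimal reconstructions; conclusions about
  them are qualitative by design.
- The coherence bound and spectral ellipse are unproven conjectures used
  as oracles; a counterexample elsewhere would not invalidate this
  implementation, but the corresponding tests encode the conjectured
  inequalities.
- Mapping μ to experimental ATP/ADP levels (and hence ΔS to measured ADP
  consumption) requires a calibration that is not part of the model.
- The synthetic trajectories emulate the model's own dynamics, not
  experimental noise sources (photobleaching, hexamer heterogeneity,
  monomer exchange); passing simulation tests shows estimator consistency,
  not biological realism.
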