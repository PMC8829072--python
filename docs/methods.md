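# Methods

This note documents the modelling choices behind `isvor`: the equations,
the discrete chain and its contact semantics, the stability machinery, the
synthetic experiment designs, and the numerical decisions that a user
extending or auditing the package needs to know.

## Mean-field system and its two variants

The five densities I, S, V, O, R evolve under degree-k mass action.  The
package ships two right-hand sides:

* **`as_printed`** keeps the forgetting outflow as −θ·O·(S+V+O+R) in dO/dt
  while crediting dR/dt with +θ·O.  On the unit simplex the components
  then sum to θ·O·I exactly — a symbolic identity the test suite asserts at
  1e−12 on random simplex points — so the flow leaks density whenever both
  oysters and ignorants are present.
* **`conserving`** (default for all experiments) treats forgetting as
  spontaneous on both sides (−θO, +θO), making the sum identically zero.
  This matches the verbal definition of forgetting as an individual
  process, not a contact process.

Related readings resolved the same way: the O→S resuscitation term in
dS/dt is β₁·O (no factor k), consistent with the dO/dt equation and the
Jacobian; the forgetting gain in dR/dt is θ·O with constant θ.  The
ignorant-to-recovery contact probability ε is defined in the process rules
but absent from the equations; it defaults to 0 and both the integrator
and the chain accept an explicit opt-in flag that adds −kεIS / +kεIS.
The γ transition is implemented as S→V (the +γS term in dV/dt), not as
the S→O reading its verbal gloss suggests: the equations win.

## Equilibria and stability

Setting the conserving RHS to zero: any state with S=V=O=0 is stationary,
giving the one-parameter rumor-free family E₁ = (I₁, 0, 0, 0, 1−I₁).
Candidates with active compartments are infeasible — summing the
stationarity conditions forces μ₁kS + μ₂kV + θO = 0, impossible for
positive compartments; with I > 0 as well, dI = 0 adds αkIS + λkIV = 0.
If every rate is zero the flow vanishes and the enumeration flags the
degeneracy instead.

The reduced (S, V, O) Jacobian at E₁ is

```
[ U1   0    β1 ]         U1 = μ1·k·(I1−1) − ξ1 − γ + α·k·I1
[ γ    U2   β2 ]   with  U2 = μ2·k·(I1−1) − ξ2 + λ·k·I1
[ ξ1   ξ2   B  ]         B  = θ·I1 − (β1+β2)
```

Two conventions coexist for the (3,3) entry: the published B above, and
the direct linearization of the as-printed dO/dt, which gives
θI₁ − θ − (β₁+β₂).  `stability_report` computes both and flags sign
disagreements (`b_sign_flip`); the published convention populates the
matrix.

**Hurwitz vs eigenvalues.**  The characteristic cubic used for the
Routh–Hurwitz determinants, χ³ − (U₁+U₂+B)χ² + [(U₁+U₂)B + U₁U₂]χ −
U₁U₂B, is the polynomial of the *triangular approximation* with roots U₁,
U₂, B.  The actual matrix is Metzler with nonzero couplings γ, ξ₁, ξ₂,
β₁, β₂, which shift the true spectrum — to first order the B-eigenvalue
moves by ξ₁β₁/(B−U₁) + ξ₂β₂/(B−U₂), always upward.  On uniform random
rate draws (k=10), about 6% of draws are Hurwitz-positive yet have a
positive eigenvalue real part, concentrated where B is small.  The
numerical eigenvalues are therefore authoritative everywhere in the
package; the determinants Δ₁ = −(U₁+U₂+B), Δ₂ = −(U₁+U₂+B)[(U₁+U₂)B +
U₁U₂] − U₁U₂B, Δ₃ = −U₁U₂B are reported as printed with a concordance
flag, and the discordance rate is itself one of the quantities
`scripts/acceptance.py` measures.

For the closed-form threshold candidates, solving U₂ = 0 gives
(μ₂k + ξ₂)/(μ₂k + λk); the published two-case bound instead contains
(μ₂k + ξ₁ + γ)/(μ₂k + λk), which the package reports as a comparison
value (`u2_crossing_printed_comparison`) since U₂ is the quantity that
actually enters the conditions.  `stability_interval` does not rely on
any closed form: it sign-scans the spectral abscissa over I₁ ∈ [0, 1] on
a fine grid and refines boundaries by bisection to 1e−12.

## The discrete chain

Updates are synchronous: each node's next role is a function of the
time-t configuration, so the per-node next-role distributions are
conditionally independent and the exact one-step law on a small graph is
the product of per-node marginals (`exact_one_step`, the test oracle).
Within a node, candidate transitions are Bernoulli trials with
short-circuit: contact-driven trials first, in uniformly random order
over the node's contact-trial multiset, then spontaneous trials in a
fixed documented order (S: γ then ξ₁; V: ξ₂; O: θ then β₁ then β₂).
Because contact trials are exchangeable, the first success is of a given
type with probability proportional to that type's success count; the
vectorized sampler draws per-type counts (binomial) and a categorical
winner, which samples the sequential semantics exactly at O(edges) per
step via sparse adjacency products.

**Contact semantics.**  Two readings of "when in contact with X, the node
transitions with probability p" are implemented:

* `aggregate` (default): one trial at probability p per step when at
  least one qualifying neighbor exists.  Per-step transition
  probabilities then stay on the scale of the nominal rates regardless of
  degree.
* `per_contact`: one independent trial per qualifying neighbor, so
  expected transition counts scale with degree like the k-multiplied
  mass-action terms.

The default matters.  At the default rates (μ's and ξ's near 0.5) on
mean-degree-10 graphs, per-contact compounding drives removal
probabilities to 1 − (1−μ)^deg ≈ 1, so spreaders are annihilated the
moment the epidemic saturates, the variation and oyster compartments
never exceed a few percent, and the μ₂/ξ₂ interventions have no
measurable effect on the diffuser peak.  That regime contradicts the
phenomena this model exists to study (substantial V and O waves, visible
intervention responses), and the verbal process rules read naturally as
per-individual probabilities conditional on contact.  `aggregate` is
therefore the default; `per_contact` remains available and is the right
mode wherever the mean-field correspondence is the point (below).  The
enumeration oracle and the Monte-Carlo sampler implement both modes and
are cross-checked against each other in both.

Other chain conventions: λ defaults to the contact reading (I→V per
variation contact, matching the kλIV term); a `fraction_of_infections`
mode implements the alternative gloss (each fresh I→S conversion is
redirected to V with probability λ).  θ defaults to spontaneous
forgetting, with a contact mode mirroring the as-printed −θO(S+V+O+R)
term.  Runs start from one uniformly placed spreader (configurable),
default horizon 100 steps, and stop early at the absorbing set S=V=O=0.
R has no outflow and I no inflow, so R is non-decreasing and I
non-increasing in every run; role counts are integers summing to n at
every step.  Reproducibility: one root seed; per-rep streams are spawned
via `numpy.random.SeedSequence`, and graph seeds / run seeds are derived
non-destructively so sweeps can replay identical streams per rep.

**Mean-field correspondence.**  On a complete 500-node graph with
per-contact semantics, contact rates rescaled by k/(n−1) and all rates
slowed by a factor c = 0.02 (so per-step probabilities are small and the
discrete chain approximates the continuous flow), 10-rep ensemble means
track the conserving mean-field solution within 0.05 sup-norm over all
five compartments (measured ≈ 0.02).  The initial spreader fraction is
5% — large enough that stochastic takeoff-timing jitter does not smear
the ensemble mean.  This is a sanity link, not a convergence theorem; the
0.05 tolerance is an engineering choice.

## Baselines

SIR, SEIR and Twin-SIR run on the same synchronous machinery and default
to the same aggregate contact semantics so that differences are model
structure, not simulation conventions.  Only the SIR rates are fixed by
the study design (α = 0.5, μ₁ = 0.5 matched to the five-role model); the
SEIR incubation probability (0.5) and the Twin-SIR dispeller parameters
are documented reconstructions.  The dispeller conversion probability
defaults to α; its entry delay defaults to 2 steps because the rumor peak
arrives at step ≈ 5 at these rates — a later dispeller cannot affect the
peak at all, which would make the comparison vacuous.  Both are
configurable, and `dispeller_delay=None` reduces Twin-SIR to SIR exactly.

## Experiment designs and what the synthetic runs do (not) show

The packaged designs mirror the study conditions: N = 2000 nodes,
Watts–Strogatz (k = 10, p = 0.4) and Barabási–Albert (m = 5, star-seeded)
substrates, default rates α=0.5, λ=0.2, η=0.5, γ=0.3, μ₁=μ₂=0.5,
ξ₁=ξ₂=0.5, θ=0.25, β₁=β₂=0.1, one initial spreader, 50 replicates (rep
count is not fixed by the study; 50 gives ≈ 0.002 standard error on
ensemble densities; the CI scale uses N = 300 and 10 reps).  Sweeps use
common random numbers — per replicate, the same graph, initial spreader
and RNG stream across all grid values — so paired per-rep tests isolate
the parameter effect; a fresh graph is drawn per replicate by default,
with a flag to pin one instance.  "Threshold" values quoted for late-time
curves are operationalized as the density at the absorbing time (or the
horizon).

Measured at full scale, the diffuser peak falls strictly in both μ₂ and
ξ₂ (paired p < 1e−4), the variation peak grows and arrives earlier as α
rises, and the scale-free peak exceeds the small-world peak — though that
last margin is small (≈ 0.004 ± 0.003 across seeds) because aggregate
contact semantics cap the per-step infection probability at α for any
degree, leaving hubs to act only through network reach.  Two measured
results go against the narrative the model is often used to support,
and the corresponding checks are deliberately left failing rather than
adjusted: raising ξ₂ does *not* cut the peak more than raising μ₂
(silenced variations resuscitate back into the diffuser pool at rate
β₁+β₂ while immunized ones are gone for good), and Hurwitz positivity
does not certify stability on ≈ 6% of random draws (couplings, above).

The synthetic networks emulate size, mean degree and degree heterogeneity
only.  They have no community structure, no degree correlations, no edge
weights or directionality, and the chain has no user heterogeneity,
memory, or content dynamics — so passing tests show internal consistency
of the model and reproducibility of its qualitative orderings on these
substrates, not predictions about any real social platform.

## Numerical choices

Adaptive integration: SciPy RK45, rtol 1e−8 / atol 1e−10; a fixed-step
explicit Euler mode (default dt = 1) mirrors the discrete-time
probability semantics.  Peak statistics break ties to the earliest time.
Verdict tolerance on eigenvalue real parts: 1e−9 (|Re| below it is
"marginal").  Bootstrap CIs in the intervention comparison: 2000
resamples of per-rep paired deltas, percentile method.  Trajectory CSVs
round-trip float64 exactly (`%.17g` on write, round-trip parsing on
read).  Degenerate inputs: all-zero rate sets are flagged rather than
analyzed; empty grids, odd lattice degrees, out-of-simplex states and
malformed edge lists raise typed errors naming the offending input.
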