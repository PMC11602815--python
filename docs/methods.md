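# Methods

## Model and assumptions

The package models isotope-enrichment dynamics on a directed weighted
graph G = (N, E) whose edges are partitioned into labeled inputs E_L,
unlabeled inputs E_U, exits E_V, and internal reactions E_W. Assumptions
baked into the construction:

* **Metabolic steady state.** Total concentrations are constant, so influx
  equals efflux at every node (`M f = 0`). This both constrains the fluxes
  (removing N of R parameters; the incidence matrix has full row rank for
  any label-connected graph) and makes the enrichment ODE autonomous.
* **Unit stoichiometry, linear kinetics of label transport.** Each edge
  moves material with a constant flux; the unlabeled share of an outgoing
  flux equals the source pool's current unlabeled fraction. The resulting
  system is linear.
* **Diagonal external-edge structure.** At most one labeled input, one
  unlabeled input, and one exit per node, so the external-edge matrices
  are diagonal. Parallel external inputs must be pre-summed by the user.
  A node may carry both a labeled and an unlabeled external input.
* **Label connectivity.** Every node is reachable from a labeled-input
  target through internal edges; unreachable nodes can never acquire
  label and are rejected by validation rather than silently carried.
* **Self-loops rejected** — a within-node recycling flux is invisible to
  enrichment and would conflate in- and out-degree.

Scaling by pool sizes gives `dx̄/dt = K(B − I)x̄ + Kα`, `x̄(0) = 1`, with
turnover rates k_i = F_i / x_i^T (1/time), and dimensionless influx
proportions α_i (external unlabeled) and β_{i,j} (from metabolite j).
α and β are computable from fluxes alone; K additionally needs pool sizes,
so the concentration-free workflow carries (B, α) and treats K as free
parameters to estimate.

## Parameter reduction

For every node without a labeled input, Σ_j β_{i,j} + α_i = 1. The package
substitutes away the β of **lowest source-node index** in each such row
(the rule needs a fixed, documented tie-break to be reproducible; lowest
column index is the natural reading). Free parameters are then all N
turnover rates, one α per unlabeled input, and the surviving betas:
R − |E_V| in total, which equals the minimal count R − N exactly when
every node has an exit. Nodes *without* an exit induce the constraint
F_i = Σ_j β_{j,i} F_j over node i's outgoing internal fluxes. It is solved
symbolically (sympy) for one of i's free outgoing betas if any survive
reduction, else for k_i, and returned — never auto-applied — because the
solution reintroduces pool-size ratios xT_j/xT_i that the
concentration-free workflow does not have. A node with neither an exit nor
an outgoing internal edge forces F_i = 0 and is reported as a modeling
error: no metabolic steady state with positive throughput exists.

Admissibility of a parameter set requires every proportion — including
each substituted β = 1 − α − Σ later β — to lie in [0, 1], every k > 0,
and a strictly positive labeled influx share at labeled nodes.

## Steady state and identifiability

The isotopic steady state solves (I − B) x̄ˢˢ = α by a dense direct solve
(pathway-scale N makes sparse machinery pointless). Existence and
uniqueness follow from weak chained diagonal dominance of (I − B): rows of
B sum to ≤ 1 (to < 1 at labeled nodes), and every weakly dominant row is
connected to a strictly dominant one through the graph of B. The package
verifies this per parameter set and returns a breadth-first chain witness
per non-strict row; a failure indicates inadmissible parameters, not a
broken theorem.

Because K cancels from the steady-state equation, turnover rates are
invisible to steady-state-only data. Counting the proportional parameters
after reduction (|E_L| + |E_U| + |E_W| − N) against the N measurable
steady states gives the necessary condition
|E_L| + |E_U| + |E_W| ≤ 2N. It is reported as **necessary only**, with the
two known degeneracies flagged (all-labeled input, i.e. α ≡ 0; and a node
fed by exactly one parent with no external input, which duplicates its
parent's steady state). No general algebraic-observability test is
attempted. On an arborescence the α's are recovered in closed form from
the steady state (root: α = x̄ˢˢ; elsewhere α_i = (x̄_i − x̄_j)/(1 − x̄_j)
with j the unique parent), guarded against a parent at exactly 1.

## Dynamics and the fast–slow dichotomy

Trajectories use the exact solution
x̄(t) = x̄ˢˢ + e^{K(B−I)t}(1 − x̄ˢˢ), evaluated by eigendecomposition with
a scaling-and-squaring `expm` fallback when the eigenvector basis is ill
conditioned (condition number > 1e8). Exactness removes integrator
tolerances from every downstream computation; an adaptive integrator
survives only as an independent oracle in the tests. The t = 0 value is
set to the initial condition exactly.

The fast–slow report nondimensionalizes around the pool with the largest
turnover rate: separation ε = k_second/k_fast, slow-manifold residual
Σ_i (B − I)_{n,i} + α_n at x̄ = 1, and the fast-subsystem equilibrium
α_n + Σ β_{n,i}. The residual is an algebraic identity (zero whenever the
fast node lacks a labeled input), so its tolerance is 1e−12. The report is
diagnostic only — fitting always uses the full linear solve, which is
exact at any stiffness. Only a single fast variable is treated; the
package does not attempt multi-fast singular perturbation. No threshold on
ε is imposed; the report states it and leaves interpretation to the user.

## Synthetic data generator

The generator emulates the standard simulated-experiment protocol: 3
technical replicates at 3, 5, or 10 equally spaced time points; Gaussian
noise with standard deviation equal to 2.5, 5, or 10 % of the **true**
value; all pools fully unlabeled at t = 0. Observations are deliberately
*not* clipped to [0, 1]. Two windows are provided: `transient` spaces
points on (0, T] with default horizon T = 5 / min_i k_i (five slowest
turnover times expose both the decay and the plateau; t = 0 is excluded
because its value is deterministic), and `steady_state_only` starts at the
first time on a coarse grid (5001 points out to 50 / min k) where the
sup-norm deviation from x̄ˢˢ is ≤ 1e−4, then uses the same spacing. A
truth of exactly zero receives a standard-deviation floor of 1e−6. The
horizon is a declared package convention, stated here because real
protocols fix their own grids.

What passing tests on generated data do **not** show: robustness to
mass-spectrometry artifacts (isotopologue envelopes, natural-abundance
correction, heteroscedasticity beyond the proportional model), to
non-Gaussian noise, or to model misspecification of the graph itself.

## Bayesian estimation

* **Likelihood**: independent Gaussians; by default (`generator` policy)
  the per-observation sd is noise_frac × |model prediction|, floored at
  1e−3 — self-consistent with the generator. An `inferred` policy instead
  estimates a single global sd with a U(1e−4, 0.5) prior.
* **Priors**: U(0, 1) for α and β (they are proportions), U(0, 3) for
  turnover rates. The posterior is −∞ outside the box or the
  admissibility region.
* **Sampler**: affine-invariant ensemble, 32 walkers × 4,000 steps, first
  half discarded, thinned to ~4,000 retained draws; walkers initialized
  uniformly over prior ∩ admissibility from a fixed seed. The chain length
  was chosen as the shortest that passes split-R̂ < 1.05 and bulk
  ESS > 400 on the identifiable parameters of the reference problems;
  structurally non-identifiable parameters (e.g. turnover rates under
  steady-state-only sampling) can be excluded from the convergence verdict
  but their draws, R̂ and ESS are always reported.
* **Point estimate**: mode of a Gaussian KDE (Silverman bandwidth,
  512-point grid over the prior support) per marginal; equal-tailed
  credible intervals (default 95%) computed independently of the mode.
* **Reproducibility**: one top-level seed, split deterministically
  (SeedSequence) between generator and sampler; the full
  generate → fit → summarize pipeline is bit-reproducible under a fixed
  seed on a fixed platform.

Non-identifiability is surfaced, not smoothed over: wide intervals for
turnover rates under steady-state sampling, the α₁/β₁,₂ ridge of the
reversible model (exposed as an explicit line object with perpendicular
sample distances), and the hidden fast rate in the slow-fast regime.

## Problem sizes and test design

All reference computations run on two- and three-metabolite pathways with
10-point, 3-replicate datasets — the scale the framework targets — and
randomized property tests use 2–4-node graphs with Dirichlet-distributed
admissible proportions. MCMC-backed tests use one fit per claim at the
default sampler settings with seeds fixed by a uniform convention.

## Known limitations

* Linear (isomeric-equivalent) kinetics only; no nonlinear rate laws.
* One label state per metabolite (labeled/unlabeled); no isotopologue
  resolution or multi-tracer ensembles.
* Non-autonomous variants (drifting total concentrations) are out of scope.
* The steady-state counting condition is necessary, not sufficient; no
  differential-algebra identifiability analysis is attempted.
* Graph structure is taken as given; inferring it from data is not
  supported.
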